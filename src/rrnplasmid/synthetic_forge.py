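"""Synthetic multi-replicon genomes with planted ground truth.

Every structure the downstream analysis assumes can be planted here:
rrn operons (rrs-trnI-trnA-rrl-rrf) on chromosomes or plasmids, Rep
replication-initiator genes encoding panel peptides exactly in frame,
essential single-copy marker genes, tandem tRNA clusters, codon-usage
bias in highly expressed genes, and short reads at chosen per-replicon
molar ratios. Background sequence is i.i.d. uniform over {A,C,G,T};
planted genes reuse fixed template sequences so homology search and
full-length checks are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_io import CANONICAL_RRNA_LENGTH, Contig, GeneFeature, GenomeRecord

TRAPS = (
    "none",
    "rrn_contig_too_long",
    "rrn_contig_has_marker",
    "two_rrn_contigs",
    "rrn_contig_no_rep",
)

_TRNA_LENGTH = 76

# deterministic template sequences for planted genes
_TEMPLATE_SEED = 20240917
_BASES = np.array(list("ACGT"))


def _random_dna(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _make_templates():
    rng = np.random.default_rng(_TEMPLATE_SEED)
    t = {k: _random_dna(rng, n) for k, n in CANONICAL_RRNA_LENGTH.items()}
    t["tRNA"] = _random_dna(rng, _TRNA_LENGTH)
    return t


_TEMPLATES = _make_templates()

# codon machinery (bacterial table 11; start-codon special-casing not used)
_TABLE = CodonTable.unambiguous_dna_by_id[11]
_SYNONYMS: dict = {}
for _codon, _aa in _TABLE.forward_table.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMS:
    _SYNONYMS[_aa].sort()
_AA20 = sorted(_SYNONYMS)

#: two-codon pyrimidine-ending families scored by the codon-bias S statistic
S_FAMILIES = {
    "Phe": ("TTC", "TTT"),
    "Ile": ("ATC", "ATT"),
    "Tyr": ("TAC", "TAT"),
    "Asn": ("AAC", "AAT"),
}
_S_AA1 = {"Phe": "F", "Ile": "I", "Tyr": "Y", "Asn": "N"}


def reverse_translate(peptide: str) -> str:
    """Encode a peptide with the lexicographically first synonymous codons."""
    return "".join(_SYNONYMS[aa][0] for aa in peptide)


@dataclass
class PlasmidSpec:
    length: int
    rep_family: str | None = "Rep_3"
    rrn_operon_count: int = 0
    copy_number: float = 1.0
    has_parAB: bool = False
    marker_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.copy_number <= 0:
            raise ValueError("copy_number must be > 0")
        if self.rrn_operon_count < 0:
            raise ValueError("rrn_operon_count must be >= 0")


@dataclass
class ScenarioSpec:
    """Blueprint for one synthetic genome."""

    genome_id: str = "synthetic"
    chromosome_length: int = 200_000
    chromosomal_rrn_count: int = 0
    plasmids: list = field(default_factory=list)
    marker_ids: list = field(default_factory=lambda: [f"bac120_{i:04d}" for i in range(10)])
    trna_cluster_plan: list = field(default_factory=list)  # [{"size": k, "spacing": nt}]
    he_gene_count: int = 40
    he_fold_change: float = 1.0  # C- vs U-ending odds multiplier in HE genes
    background_cds_count: int = 20
    trap: str = "none"

    def __post_init__(self):
        if self.trap not in TRAPS:
            raise ValueError(f"unknown trap {self.trap!r}")
        if self.chromosomal_rrn_count < 0:
            raise ValueError("chromosomal_rrn_count must be >= 0")
        for p in self.plasmids:
            if p.length >= self.chromosome_length:
                raise ValueError("plasmid length must be < chromosome length")


@dataclass
class TruthLabels:
    genome_id: str
    is_plasmid_only_rrn: bool
    rrn_contig_ids: list
    copy_numbers: dict  # contig_id -> true copy number
    cluster_sizes: list  # planted tRNA cluster sizes, chromosome only


# --------------------------------------------------------------------------
# Rep panel (synthetic stand-in for a published replication-initiator panel)

REP_FAMILIES = ("Rep_3", "Rep_1", "RepA_N", "Rep_trans")


@dataclass
class RepPanelEntry:
    protein_id: str
    peptide: str
    family: str


def default_rep_panel(entries_per_family: int = 1, length: int = 80):
    """A small synthetic Rep protein panel with one deterministic random
    peptide per (family, index); a stand-in for curated Rep panels, adequate
    for exercising translated homology search on forged genomes."""
    rng = np.random.default_rng(_TEMPLATE_SEED + 1)
    aa = np.array(_AA20)
    panel = []
    for fam in REP_FAMILIES:
        for i in range(entries_per_family):
            pep = "".join(aa[rng.integers(0, 20, length)])
            panel.append(RepPanelEntry(f"{fam}_syn{i}", pep, fam))
    return panel


# --------------------------------------------------------------------------
# sequence assembly helpers


class _Builder:
    """Accumulates sequence segments and features for one contig."""

    def __init__(self, contig_id: str, rng):
        self.contig_id = contig_id
        self.rng = rng
        self.parts: list = []
        self.pos = 0
        self.features: list = []

    def spacer(self, n: int):
        self.parts.append(_random_dna(self.rng, n))
        self.pos += n

    def add(self, seq: str, kind: str | None, strand: str = "+", attrs=None):
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        if kind is not None:
            self.features.append(
                GeneFeature(self.contig_id, start, self.pos, strand, kind, attrs or {})
            )

    def finish(self, total_length: int, topology: str) -> Contig:
        if self.pos > total_length:
            raise ValueError(
                f"planted features need {self.pos} nt but {self.contig_id} "
                f"is only {total_length} nt"
            )
        self.spacer(total_length - self.pos)
        return Contig(self.contig_id, "".join(self.parts), topology)


def _emit_operon(b: _Builder, with_trnas: bool = True):
    """One rrn operon in transcription order: rrs-(trnI-trnA)-rrl-rrf."""
    b.add(_TEMPLATES["rRNA_16S"], "rRNA_16S", attrs={"product": "16S ribosomal RNA"})
    b.spacer(30)
    if with_trnas:
        b.add(
            _TEMPLATES["tRNA"],
            "tRNA",
            attrs={"product": "tRNA-Ile", "isotype": "Ile", "anticodon": "GAT"},
        )
        b.spacer(15)
        b.add(
            _TEMPLATES["tRNA"],
            "tRNA",
            attrs={"product": "tRNA-Ala", "isotype": "Ala", "anticodon": "TGC"},
        )
        b.spacer(30)
    b.add(_TEMPLATES["rRNA_23S"], "rRNA_23S", attrs={"product": "23S ribosomal RNA"})
    b.spacer(40)
    b.add(_TEMPLATES["rRNA_5S"], "rRNA_5S", attrs={"product": "5S ribosomal RNA"})


def _emit_marker(b: _Builder, marker_id: str, rng):
    # uniform synonymous-codon usage so markers do not skew the genome
    # background against which codon bias is measured
    b.add(
        _sample_cds(rng, 100, 1.0),
        "marker_gene",
        attrs={"marker_id": marker_id, "product": "single-copy marker protein"},
    )


_TRNA_POOL = [
    ("Gly", "GCC"), ("Gly", "TCC"), ("Glu", "TTC"), ("Asp", "GTC"),
    ("Val", "TAC"), ("Leu", "TAG"), ("Lys", "TTT"), ("Arg", "ACG"),
    ("Ser", "GGA"), ("Thr", "TGT"), ("Pro", "TGG"), ("Met", "CAT"),
]


def _emit_trna(b: _Builder, isotype: str, anticodon: str):
    b.add(
        _TEMPLATES["tRNA"],
        "tRNA",
        attrs={"product": f"tRNA-{isotype}", "isotype": isotype, "anticodon": anticodon},
    )


def _emit_trna_cluster(b: _Builder, size: int, spacing: int, rng):
    for i in range(size):
        if i > 0:
            b.spacer(spacing)
        iso, anti = _TRNA_POOL[int(rng.integers(0, len(_TRNA_POOL)))]
        _emit_trna(b, iso, anti)


def _sample_cds(rng, n_codons: int, c_fold: float) -> str:
    """A CDS with given C-ending odds in the four S families; other amino
    acids draw synonymous codons uniformly."""
    p_c = c_fold / (c_fold + 1.0)
    codons = ["ATG"]
    # amino-acid pool enriched for the S-family residues so usage counts
    # are informative even in short genes
    pool = _AA20 + list(_S_AA1.values()) * 4
    for _ in range(n_codons - 1):
        aa = pool[int(rng.integers(0, len(pool)))]
        fam = next((f for f, a in _S_AA1.items() if a == aa), None)
        if fam is not None:
            c_codon, u_codon = S_FAMILIES[fam]
            codons.append(c_codon if rng.random() < p_c else u_codon)
        else:
            syn = _SYNONYMS[aa]
            codons.append(syn[int(rng.integers(0, len(syn)))])
    return "".join(codons) + "TAA"


_HE_PRODUCTS = (
    ["50S ribosomal protein L%d" % i for i in range(1, 25)]
    + ["30S ribosomal protein S%d" % i for i in range(1, 22)]
    + ["elongation factor Tu", "elongation factor G"]
)


def forge_genome(spec: ScenarioSpec, seed: int):
    """Build one genome from a scenario; deterministic given (spec, seed).

    Returns (GenomeRecord, TruthLabels); the label is recomputed from the
    emitted annotation, never asserted from the scenario.
    """
    rng = np.random.default_rng(seed)
    contigs, features = [], []

    # ---- chromosome
    b = _Builder(f"{spec.genome_id}_chr", rng)
    b.spacer(200)
    for mid in spec.marker_ids:
        _emit_marker(b, mid, rng)
        b.spacer(int(rng.integers(50, 150)))
    for i in range(spec.he_gene_count):
        product = _HE_PRODUCTS[i % len(_HE_PRODUCTS)]
        b.add(
            _sample_cds(rng, 150, spec.he_fold_change),
            "CDS",
            attrs={"product": product},
        )
        b.spacer(int(rng.integers(50, 150)))
    for _ in range(spec.background_cds_count):
        b.add(_sample_cds(rng, 150, 1.0), "CDS", attrs={"product": "hypothetical protein"})
        b.spacer(int(rng.integers(50, 150)))
    cluster_sizes = []
    for plan in spec.trna_cluster_plan:
        flank = plan.get("flanker_gap")  # e.g. 600: lone tRNAs just beyond 500 bp
        if flank:
            _emit_trna(b, *_TRNA_POOL[int(rng.integers(0, len(_TRNA_POOL)))])
            b.spacer(flank)
        _emit_trna_cluster(b, plan["size"], plan["spacing"], rng)
        cluster_sizes.append(plan["size"])
        if flank:
            b.spacer(flank)
            _emit_trna(b, *_TRNA_POOL[int(rng.integers(0, len(_TRNA_POOL)))])
        b.spacer(700)  # keep planted clusters separate at the 500-bp rule
    for _ in range(spec.chromosomal_rrn_count):
        _emit_operon(b)
        b.spacer(300)
    contigs.append(b.finish(spec.chromosome_length, "circular"))
    features.extend(b.features)
    copy_numbers = {b.contig_id: 1.0}

    # ---- plasmids
    panel = {e.family: e for e in default_rep_panel()}
    for i, p in enumerate(spec.plasmids):
        pb = _Builder(f"{spec.genome_id}_p{i + 1}", rng)
        pb.spacer(100)
        if p.rep_family is not None:
            entry = panel[p.rep_family]
            pb.add(
                reverse_translate(entry.peptide) + "TAA",
                "rep_gene",
                strand="+" if rng.random() < 0.5 else "-",
                attrs={
                    "rep_family": p.rep_family,
                    "product": "replication initiator protein",
                },
            )
            pb.spacer(150)
        if p.has_parAB:
            for gene in ("parA", "parB"):
                pb.add(
                    _sample_cds(rng, 120, 1.0),
                    "CDS",
                    attrs={"product": f"plasmid partition protein {gene.capitalize()}"},
                )
                pb.spacer(60)
        for j in range(p.rrn_operon_count):
            if j > 0:
                pb.spacer(150)
            _emit_operon(pb)
        for mid in p.marker_ids:
            pb.spacer(120)
            _emit_marker(pb, mid, rng)
        contigs.append(pb.finish(p.length, "circular"))
        features.extend(pb.features)
        copy_numbers[pb.contig_id] = p.copy_number

    record = GenomeRecord(spec.genome_id, contigs, features, "complete")
    label = _label_from_record(record, spec, copy_numbers, cluster_sizes)
    return record, label


def _label_from_record(record, spec, copy_numbers, cluster_sizes) -> TruthLabels:
    """Recompute the screen-semantics truth label from the annotation."""
    rrna_kinds = set(CANONICAL_RRNA_LENGTH)
    rrn_contigs = sorted(
        {f.contig_id for f in record.features if f.kind in rrna_kinds}
    )
    ok = len(rrn_contigs) == 1
    if ok:
        cid = rrn_contigs[0]
        contig = record.contig(cid)
        full = [
            f
            for f in record.features_on(cid)
            if f.kind in rrna_kinds
            and f.length >= 0.9 * CANONICAL_RRNA_LENGTH[f.kind]
        ]
        ok = (
            len(full) >= 2
            and any(f.kind == "rep_gene" for f in record.features_on(cid))
            and contig.length < 35_000
            and not any(
                f.kind == "marker_gene"
                and f.attrs.get("marker_id") in set(spec.marker_ids)
                for f in record.features_on(cid)
            )
            and cid != f"{spec.genome_id}_chr"
        )
    return TruthLabels(
        record.genome_id, ok, rrn_contigs, copy_numbers, cluster_sizes
    )


# --------------------------------------------------------------------------
# trap / scenario factories


def positive_scenario(genome_id="pos", chromosome_length=50_000, operons=2, copy_number=8.0):
    return ScenarioSpec(
        genome_id=genome_id,
        chromosome_length=chromosome_length,
        chromosomal_rrn_count=0,
        plasmids=[PlasmidSpec(25_000, "Rep_3", operons, copy_number)],
        he_gene_count=5,
        background_cds_count=5,
    )


def trap_scenario(trap: str, genome_id=None, chromosome_length=50_000):
    """One negative genome per exclusion rule of the screen."""
    gid = genome_id or f"trap_{trap}"
    base = dict(
        genome_id=gid,
        chromosome_length=chromosome_length,
        he_gene_count=5,
        background_cds_count=5,
        trap=trap,
    )
    if trap == "none":  # ordinary chromosomal-rrn negative
        return ScenarioSpec(chromosomal_rrn_count=2, plasmids=[], **base)
    if trap == "rrn_contig_too_long":
        return ScenarioSpec(
            plasmids=[PlasmidSpec(36_500, "Rep_3", 2, 8.0)], **base
        )
    if trap == "rrn_contig_has_marker":
        return ScenarioSpec(
            plasmids=[PlasmidSpec(25_000, "Rep_3", 2, 8.0, marker_ids=["bac120_0000"])],
            marker_ids=["bac120_0000"] + [f"bac120_{i:04d}" for i in range(1, 10)],
            **base,
        )
    if trap == "two_rrn_contigs":
        return ScenarioSpec(
            plasmids=[
                PlasmidSpec(25_000, "Rep_3", 2, 8.0),
                PlasmidSpec(15_000, "Rep_3", 1, 4.0),
            ],
            **base,
        )
    if trap == "rrn_contig_no_rep":
        return ScenarioSpec(plasmids=[PlasmidSpec(25_000, None, 2, 8.0)], **base)
    raise ValueError(f"unknown trap {trap!r}")


def forge_cohort(n: int, scenario_mix, seed: int):
    """n genomes apportioned to scenarios by largest-remainder rounding.

    scenario_mix: list of (scenario factory taking genome_id, proportion).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    props = [p for _, p in scenario_mix]
    if abs(sum(props) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    quotas = [n * p for p in props]
    counts = [int(q) for q in quotas]
    rema = sorted(
        range(len(quotas)), key=lambda i: quotas[i] - counts[i], reverse=True
    )
    for i in rema[: n - sum(counts)]:
        counts[i] += 1

    out = []
    k = 0
    for (factory, _), c in zip(scenario_mix, counts):
        for _ in range(c):
            spec = factory(f"g{k:03d}")
            out.append(forge_genome(spec, (seed * 100_003 + k) % 2**31))
            k += 1
    return out


# --------------------------------------------------------------------------
# read simulation


def simulate_reads(
    record: GenomeRecord,
    copy_numbers: dict,
    base_depth: float,
    read_len: int,
    error_rate: float,
    seed: int,
    fastq_path,
    sam_path,
):
    """Uniform error-free-or-substitution short reads at per-replicon molar
    ratios; expected per-contig depth = base_depth x copy_number. A truth SAM
    records every read's true origin.
    """
    if base_depth <= 0:
        raise ValueError("base_depth must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0,1)")
    for c in record.contigs:
        if read_len >= c.length:
            raise ValueError(f"read_len {read_len} >= contig {c.id} length")

    rng = np.random.default_rng(seed)
    qual = "I" * read_len
    n_reads_total = 0
    with open(fastq_path, "w") as fq, open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:unsorted\n")
        for c in record.contigs:
            sam.write(f"@SQ\tSN:{c.id}\tLN:{c.length}\n")
        for c in record.contigs:
            cn = copy_numbers.get(c.id, 1.0)
            n_reads = int(round(c.length * cn * base_depth / read_len))
            starts = rng.integers(0, c.length - read_len + 1, n_reads)
            rev = rng.random(n_reads) < 0.5
            for i in range(n_reads):
                s = int(starts[i])
                seq = c.sequence[s : s + read_len]
                if error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                    hits = np.nonzero(rng.random(read_len) < error_rate)[0]
                    for h in hits:
                        cur = arr[h].decode()
                        choices = [x for x in "ACGT" if x != cur]
                        arr[h] = choices[int(rng.integers(0, 3))].encode()
                    seq = arr.tobytes().decode()
                name = f"{c.id}_r{i}"
                flag = 16 if rev[i] else 0
                out_seq = str(Seq(seq).reverse_complement()) if rev[i] else seq
                fq.write(f"@{name}\n{out_seq}\n+\n{qual}\n")
                # SAM stores the forward-strand sequence per convention
                sam.write(
                    f"{name}\t{flag}\t{c.id}\t{s + 1}\t60\t{read_len}M\t*\t0\t0\t{seq}\t{qual}\n"
                )
            n_reads_total += n_reads
    return n_reads_total
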