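"""tRNA gene clusters, isoacceptor/isodecoder tallies and codon-usage bias.

The codon-bias statistic S is the Sharp-type log-ratio of C- over
U-ending codon usage in highly expressed genes relative to the genome
background, over the four two-codon pyrimidine families Phe (TTC/TTT),
Ile (ATC/ATT), Tyr (TAC/TAT) and Asn (AAC/AAT):

    S_aa = ln[ (C_HE+pc)/(U_HE+pc) / ((C_BG+pc)/(U_BG+pc)) ]
    S    = sum(w_aa * S_aa) / sum(w_aa),  w_aa = C_HE + U_HE

with pseudocount pc (default 0.5) keeping S finite on sparse gene sets.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.Seq import Seq
from scipy import stats

from .genome_io import GenomeRecord
from .synthetic_forge import S_FAMILIES

_CODING_KINDS = ("CDS", "rep_gene", "marker_gene")


@dataclass
class TrnaCluster:
    contig_id: str
    members: list  # tRNA GeneFeatures in genomic order
    span: tuple

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CodonBiasResult:
    s_aa: dict  # family -> log-ratio
    weights: dict  # family -> HE family codon total
    S: float
    he_gene_products: list
    dropped_families: list = field(default_factory=list)


def detect_trna_clusters(record: GenomeRecord, max_gap: int = 500):
    """Single-linkage chaining of tRNA genes with end-to-start distance
    <= max_gap, strand-blind; singletons are clusters of size 1. The
    clusters partition each contig's tRNA genes."""
    clusters = []
    for contig in record.contigs:
        trnas = record.features_on(contig.id, "tRNA")
        current = []
        for f in trnas:
            if current and f.start - current[-1].end > max_gap:
                clusters.append(
                    TrnaCluster(contig.id, current, (current[0].start, current[-1].end))
                )
                current = []
            current.append(f)
        if current:
            clusters.append(
                TrnaCluster(contig.id, current, (current[0].start, current[-1].end))
            )
    return clusters


def tally_trna_genes(record: GenomeRecord, chromosome_ids):
    """Isoacceptor (per isotype) and isodecoder (per anticodon) tallies,
    split into chromosomal vs plasmid columns.

    tRNAs lacking an anticodon attribute still count in the isotype table
    and are flagged in the qc_no_anticodon column. An isotype annotated
    e.g. 'Ile2' is kept distinct from 'Ile'.
    """
    chromosome_ids = set(chromosome_ids)
    iso = defaultdict(lambda: {"chromosome": 0, "plasmid": 0, "qc_no_anticodon": 0})
    deco = defaultdict(lambda: {"chromosome": 0, "plasmid": 0})
    for f in record.features:
        if f.kind != "tRNA":
            continue
        where = "chromosome" if f.contig_id in chromosome_ids else "plasmid"
        isotype = f.attrs.get("isotype", "Unknown")
        iso[isotype][where] += 1
        anticodon = f.attrs.get("anticodon")
        if anticodon:
            deco[(isotype, anticodon)][where] += 1
        else:
            iso[isotype]["qc_no_anticodon"] += 1
    isoacceptor = pd.DataFrame.from_dict(iso, orient="index").sort_index()
    isodecoder = pd.DataFrame.from_dict(deco, orient="index").sort_index()
    if not isodecoder.empty:
        isodecoder.index = pd.MultiIndex.from_tuples(
            isodecoder.index, names=["isotype", "anticodon"]
        )
    return isoacceptor, isodecoder


def aa_composition(record: GenomeRecord):
    """Amino-acid frequencies over all CDS translations (stops excluded).

    Returns (freqs keyed by one-letter amino acid, n_skipped) where
    skipped counts CDSs whose length is not a codon multiple.
    """
    counts = Counter()
    skipped = 0
    for f in record.features:
        if f.kind not in _CODING_KINDS:
            continue
        seq = record.feature_sequence(f)
        if len(seq) % 3 != 0:
            skipped += 1
            continue
        for aa in str(Seq(seq).translate()):
            if aa not in "*X":
                counts[aa] += 1
    if not counts:
        raise ValueError("no translatable CDS features")
    if skipped:
        warnings.warn(f"skipped {skipped} CDSs with length not a codon multiple")
    total = sum(counts.values())
    return {aa: counts.get(aa, 0) / total for aa in "ACDEFGHIKLMNPQRSTVWY"}, skipped


def _isotype_to_aa(isotype: str) -> str | None:
    base = isotype.rstrip("0123456789")
    try:
        return protein_letters_3to1[base.capitalize()]
    except KeyError:
        return None


def trna_aa_correlation(isoacceptor_counts: dict, aa_freqs: dict):
    """Spearman correlation (average-rank ties) between per-amino-acid
    tRNA gene counts and proteome amino-acid frequencies.

    isoacceptor_counts is keyed by isotype (three-letter, isodecoder
    suffixes like Ile2 merge into their amino acid); aa_freqs by
    one-letter code. Zero variance in either vector yields (nan, nan).
    """
    per_aa = defaultdict(float)
    for isotype, n in isoacceptor_counts.items():
        aa = _isotype_to_aa(str(isotype))
        if aa is not None:
            per_aa[aa] += n
    aas = sorted(aa_freqs)
    x = [per_aa.get(a, 0.0) for a in aas]
    y = [aa_freqs[a] for a in aas]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


#: keyword ranking used to pick highly expressed genes from annotations
HE_KEYWORDS = ("ribosomal protein", "elongation factor")


def select_highly_expressed(record: GenomeRecord, n: int = 40):
    """Pick n highly expressed CDSs by ranked product keywords
    (ribosomal proteins first, then elongation factors), breaking ties by
    genomic order. Returns (features, n_found); a shortfall is reported
    through a warning, never silently padded."""
    ranked = []
    for idx, f in enumerate(record.features):
        if f.kind not in _CODING_KINDS:
            continue
        product = f.attrs.get("product", "").lower()
        for rank, kw in enumerate(HE_KEYWORDS):
            if kw in product:
                ranked.append((rank, idx, f))
                break
    ranked.sort(key=lambda t: (t[0], t[1]))
    feats = [f for _, _, f in ranked[:n]]
    if len(feats) < n:
        warnings.warn(
            f"only {len(feats)} highly-expressed gene candidates found (wanted {n})"
        )
    return feats, len(feats)


def codon_usage(record: GenomeRecord, features) -> Counter:
    """Codon counts over the given coding features (coding strand)."""
    counts = Counter()
    for f in features:
        seq = record.feature_sequence(f)
        for i in range(0, len(seq) - len(seq) % 3, 3):
            counts[seq[i : i + 3]] += 1
    return counts


def codon_bias_S(
    he_usage: Counter,
    background_usage: Counter,
    pseudocount: float = 0.5,
    equal_weights: bool = False,
) -> CodonBiasResult:
    """Sharp-type codon bias S from HE-gene vs background codon usage."""
    s_aa, weights, dropped = {}, {}, []
    for fam, (c_codon, u_codon) in S_FAMILIES.items():
        c_he, u_he = he_usage.get(c_codon, 0), he_usage.get(u_codon, 0)
        c_bg, u_bg = background_usage.get(c_codon, 0), background_usage.get(u_codon, 0)
        if c_he + u_he == 0:
            dropped.append(fam)
            continue
        s_aa[fam] = math.log(
            ((c_he + pseudocount) / (u_he + pseudocount))
            / ((c_bg + pseudocount) / (u_bg + pseudocount))
        )
        weights[fam] = 1.0 if equal_weights else float(c_he + u_he)
    if not s_aa:
        raise ValueError("no S family observed in the highly expressed genes")
    if dropped:
        warnings.warn(f"S families absent from HE genes: {','.join(dropped)}")
    wsum = sum(weights.values())
    S = sum(weights[f] * s_aa[f] for f in s_aa) / wsum
    return CodonBiasResult(s_aa, weights, S, [], dropped)


def codon_bias_from_record(
    record: GenomeRecord, n_he: int = 40, pseudocount: float = 0.5
) -> CodonBiasResult:
    """Convenience wrapper: select HE genes, tabulate usage against the
    whole-genome background, and compute S."""
    he, _ = select_highly_expressed(record, n_he)
    he_set = {id(f) for f in he}
    bg = [f for f in record.features if f.kind in _CODING_KINDS and id(f) not in he_set]
    res = codon_bias_S(codon_usage(record, he), codon_usage(record, bg), pseudocount)
    res.he_gene_products = [f.attrs.get("product", "") for f in he]
    return res
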