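"""Genome data model and FASTA/GFF3/SAM I/O.

All coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive, as the format requires. Features never span the origin of a
circular contig: replicons are serialized from a fixed origin and the
loader rejects coordinates outside the contig.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = (
    "rRNA_16S",
    "rRNA_23S",
    "rRNA_5S",
    "tRNA",
    "CDS",
    "rep_gene",
    "marker_gene",
)

#: product keywords used to assign an rRNA subtype when the GFF type column
#: only says "rRNA"; first match wins, case-insensitive.
DEFAULT_RRNA_KEYWORDS = {
    "16S": "rRNA_16S",
    "23S": "rRNA_23S",
    "5S": "rRNA_5S",
}

#: canonical full lengths (nt) of the three rRNA classes in bacteria.
CANONICAL_RRNA_LENGTH = {"rRNA_16S": 1500, "rRNA_23S": 2900, "rRNA_5S": 120}


@dataclass
class Contig:
    """A single replicon or assembly contig."""

    id: str
    sequence: str
    topology: str = "linear"  # or "circular"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has an empty sequence")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"bad topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneFeature:
    """A typed annotation interval on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str
    kind: str
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad interval [{self.start},{self.end}) on {self.contig_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """A genome: contigs plus typed features, the unit every stage consumes."""

    genome_id: str
    contigs: list
    features: list
    assembly_level: str = "complete"

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids")
        self._by_id = {c.id: c for c in self.contigs}
        for f in self.features:
            c = self._by_id.get(f.contig_id)
            if c is None:
                raise ValueError(
                    f"feature on unknown contig {f.contig_id!r} "
                    f"([{f.start},{f.end}) {f.kind})"
                )
            if f.end > c.length:
                raise ValueError(
                    f"feature [{f.start},{f.end}) exceeds contig "
                    f"{c.id!r} length {c.length}"
                )
        self.features.sort(key=lambda f: (f.contig_id, f.start, f.end))

    def contig(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def features_on(self, contig_id: str, kind: str | None = None):
        return [
            f
            for f in self.features
            if f.contig_id == contig_id and (kind is None or f.kind == kind)
        ]

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Stranded nucleotide sequence of a feature."""
        seq = self._by_id[feat.contig_id].sequence[feat.start : feat.end]
        if feat.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class ContigDepth:
    aligned_bases: int
    mean_depth: float
    breadth: float


@dataclass
class DepthProfile:
    """Per-contig read-depth summary from a SAM alignment."""

    contigs: dict  # contig_id -> ContigDepth
    lengths: dict  # contig_id -> int


# --------------------------------------------------------------------------
# GFF3 <-> feature kind mapping

_GFF_TYPE_FOR_KIND = {
    "rRNA_16S": "rRNA",
    "rRNA_23S": "rRNA",
    "rRNA_5S": "rRNA",
    "tRNA": "tRNA",
    "CDS": "CDS",
    "rep_gene": "CDS",
    "marker_gene": "CDS",
}


def _classify(gff_type: str, attrs: dict, rrna_keywords: dict) -> str:
    if gff_type == "tRNA":
        return "tRNA"
    if gff_type == "rRNA":
        product = attrs.get("product", "")
        for kw, kind in rrna_keywords.items():
            if kw.lower() in product.lower():
                return kind
        raise ValueError(
            f"cannot assign an rRNA subtype from product {product!r}"
        )
    if gff_type == "CDS":
        if "rep_family" in attrs:
            return "rep_gene"
        if "marker_id" in attrs:
            return "marker_gene"
        return "CDS"
    raise ValueError(f"unsupported GFF feature type {gff_type!r}")


def _parse_attrs(col9: str) -> dict:
    attrs = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed GFF attribute {item!r}")
        k, v = item.split("=", 1)
        attrs[urllib.parse.unquote(k)] = urllib.parse.unquote(v)
    return attrs


def _format_attrs(attrs: dict) -> str:
    if not attrs:
        return "."
    quote = lambda s: urllib.parse.quote(str(s), safe=" :/()'+.-_")
    return ";".join(f"{quote(k)}={quote(v)}" for k, v in attrs.items())


def read_genome(
    fasta_path,
    gff_path,
    genome_id: str | None = None,
    assembly_level: str = "complete",
    rrna_keywords: dict = DEFAULT_RRNA_KEYWORDS,
) -> GenomeRecord:
    """Load a genome from FASTA sequences and GFF3 annotations.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention. The GFF type column and the ``product``,
    ``rep_family`` and ``marker_id`` attributes determine the feature kind.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    contigs = []
    topo = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        is_circ = "circular" in rec.description.lower()
        contigs.append(
            Contig(rec.id, str(rec.seq).upper(), "circular" if is_circ else "linear")
        )
        topo[rec.id] = is_circ
    contig_ids = {c.id for c in contigs}

    features = []
    seen_ids = set()
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _src, gtype, start, end, _score, strand, _phase, col9 = cols
            attrs = _parse_attrs(col9)
            if seqid not in contig_ids:
                raise ValueError(
                    f"{gff_path}:{lineno}: feature "
                    f"{attrs.get('ID', gtype)!r} references unknown seqid "
                    f"{seqid!r}"
                )
            fid = attrs.get("ID")
            if fid is not None:
                if fid in seen_ids:
                    raise ValueError(
                        f"{gff_path}:{lineno}: duplicate feature ID {fid!r}"
                    )
                seen_ids.add(fid)
            kind = _classify(gtype, attrs, rrna_keywords)
            features.append(
                GeneFeature(seqid, int(start) - 1, int(end), strand, kind, attrs)
            )

    if genome_id is None:
        genome_id = fasta_path.stem
    return GenomeRecord(genome_id, contigs, features, assembly_level)


def write_genome(record: GenomeRecord, fasta_path, gff_path, line_width: int = 70):
    """Emit FASTA (fixed wrap) and GFF3 (1-based inclusive) deterministically."""
    seq_records = [
        SeqRecord(
            Seq(c.sequence),
            id=c.id,
            description="circular" if c.topology == "circular" else "",
        )
        for c in record.contigs
    ]
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(seq_records)
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in record.contigs:
            fh.write(f"##sequence-region {c.id} 1 {c.length}\n")
        for f in record.features:
            fh.write(
                "\t".join(
                    [
                        f.contig_id,
                        "rrnplasmid",
                        _GFF_TYPE_FOR_KIND[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        _format_attrs(f.attrs),
                    ]
                )
                + "\n"
            )


def depth_from_sam(sam_path, record: GenomeRecord) -> DepthProfile:
    """Per-contig mean depth and breadth from primary mapped SAM alignments.

    mean_depth = aligned reference bases (CIGAR M/=/X) / contig length;
    secondary and supplementary alignments are excluded to avoid double
    counting.
    """
    lengths = {c.id: c.length for c in record.contigs}
    covered = {cid: np.zeros(n, dtype=bool) for cid, n in lengths.items()}
    aligned = {cid: 0 for cid in lengths}

    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in lengths:
                raise ValueError(f"SAM contig {ref!r} absent from genome record")
        for i, read in enumerate(sam):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            cid = read.reference_name
            blocks = read.get_blocks()  # M/=/X reference intervals
            if not blocks:
                raise ValueError(f"alignment record {i + 1}: no aligned bases")
            for s, e in blocks:
                aligned[cid] += e - s
                covered[cid][s:e] = True

    per_contig = {
        cid: ContigDepth(
            aligned_bases=aligned[cid],
            mean_depth=aligned[cid] / lengths[cid],
            breadth=float(covered[cid].mean()),
        )
        for cid in lengths
    }
    return DepthProfile(per_contig, lengths)


def depth_table(profile: DepthProfile):
    """DepthProfile as a tidy table (contig, length, aligned, depth, breadth)."""
    import pandas as pd

    rows = [
        {
            "contig_id": cid,
            "length": profile.lengths[cid],
            "aligned_bases": d.aligned_bases,
            "mean_depth": d.mean_depth,
            "breadth": d.breadth,
        }
        for cid, d in profile.contigs.items()
    ]
    return pd.DataFrame(rows)
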