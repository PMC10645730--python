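"""Rep-family gene detection by six-frame translated local alignment.

Contigs are translated in all six frames and searched against a panel of
replication-initiator (Rep) proteins with an affine-gap Smith-Waterman
alignment scored by BLOSUM62; significance uses the Karlin-Altschul
formula E = K*m*n*exp(-lambda*S) with the raw search space m*n. Hits
below the configured E-value threshold assign the panel entry's Rep
family to the contig. External tabular hits (12-column format) can be
ingested instead.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from numba import njit

from .genome_io import GenomeRecord
from .synthetic_forge import RepPanelEntry

_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}


def _blosum62_matrix() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(_ALPHABET), len(_ALPHABET)), dtype=np.int32)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            out[i, j] = int(m[a][b])
    # X (undetermined residue, e.g. from N-containing codons) is neutral
    x = _AA_INDEX["X"]
    out[x, :] = 0
    out[:, x] = 0
    return out


_BLOSUM62 = _blosum62_matrix()


@dataclass
class AlignmentParams:
    """Scoring and significance parameters for the translated search.

    Gap of length L costs gap_open + L*gap_extend (BLAST convention).
    lam/K are gapped Karlin-Altschul parameters for BLOSUM62 11/1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    e_threshold: float = 1e-5

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lam and K must be positive")
        if self.e_threshold <= 0:
            raise ValueError("e_threshold must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")


@dataclass
class RepHit:
    contig_id: str
    frame: int  # +1,+2,+3,-1,-2,-3
    protein_id: str
    family: str
    score: float
    evalue: float
    subject_interval: tuple  # 0-based half-open on the frame peptide


# --------------------------------------------------------------------------
# translation


def six_frame_translate(dna: str):
    """All six translation frames of a DNA string.

    Plain standard-code translation (no start-codon handling); trailing
    partial codons are dropped; codons containing N translate to X.
    Returns a list of (frame, peptide) with frame in +1..+3, -1..-3.
    """
    if not dna:
        raise ValueError("empty input sequence")
    dna = dna.upper()
    if set(dna) - set("ACGTN"):
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    rc = str(Seq(dna).reverse_complement())
    out = []
    for frame in (1, 2, 3):
        for src, sign in ((dna, 1), (rc, -1)):
            sub = src[frame - 1 :]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            out.append((sign * frame, pep))
    out.sort(key=lambda t: (-np.sign(t[0]), abs(t[0])))
    return out


def _encode(peptide: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in peptide], dtype=np.int32)
    except KeyError as e:
        raise ValueError(f"residue {e.args[0]!r} outside the matrix alphabet")


# --------------------------------------------------------------------------
# affine-gap Smith-Waterman (Gotoh)


@njit(cache=True)
def _gotoh_score(q, s, mat, open_cost, ext_cost):  # pragma: no cover - jit
    m, n = len(q), len(s)
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, -10**9, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    first = open_cost + ext_cost
    for i in range(1, m + 1):
        diag = H[0]
        H[0] = 0
        F = -10**9
        for j in range(1, n + 1):
            E[j] = max(H[j] - first, E[j] - ext_cost)
            F = max(H[j - 1] - first, F - ext_cost)
            h = diag + mat[q[i - 1], s[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


def local_align(query: str, subject: str, params: AlignmentParams | None = None):
    """Affine-gap local alignment score and aligned intervals.

    Returns (score, (qstart, qend), (sstart, send)) with 0-based half-open
    intervals; the empty alignment scores 0 and reports empty intervals.
    """
    params = params or AlignmentParams()
    if not query or not subject:
        raise ValueError("peptides must be non-empty")
    q, s = _encode(query), _encode(subject)
    score, bi, bj = _gotoh_score(q, s, _BLOSUM62, params.gap_open, params.gap_extend)
    if score == 0:
        return 0, (0, 0), (0, 0)
    # find the alignment start by aligning the reversed prefixes ending at
    # the best cell; the reversed problem's best end gives the start offset
    rs, ri, rj = _gotoh_score(
        q[:bi][::-1].copy(), s[:bj][::-1].copy(), _BLOSUM62,
        params.gap_open, params.gap_extend,
    )
    return int(score), (bi - ri, bi), (bj - rj, bj)


def evalue(score: float, m: int, n: int, params: AlignmentParams | None = None) -> float:
    """Karlin-Altschul expected hit count E = K*m*n*exp(-lambda*S)."""
    params = params or AlignmentParams()
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return params.K * m * n * math.exp(-params.lam * score)


# --------------------------------------------------------------------------
# panel search


def search_rep(record: GenomeRecord, panel, params: AlignmentParams | None = None):
    """Best hit per contig x panel entry x frame; retain hits with
    E < e_threshold. n in the E-value is the translated frame length."""
    params = params or AlignmentParams()
    if not panel:
        raise ValueError("empty Rep panel")
    hits = []
    for contig in record.contigs:
        frames = six_frame_translate(contig.sequence)
        for frame, pep in frames:
            if not pep:
                continue
            s = _encode(pep)
            for entry in panel:
                q = _encode(entry.peptide)
                score, bi, bj = _gotoh_score(
                    q, s, _BLOSUM62, params.gap_open, params.gap_extend
                )
                if score <= 0:
                    continue
                E = evalue(score, len(entry.peptide), len(pep), params)
                if E < params.e_threshold:
                    rs, ri, rj = _gotoh_score(
                        q[:bi][::-1].copy(), s[:bj][::-1].copy(), _BLOSUM62,
                        params.gap_open, params.gap_extend,
                    )
                    hits.append(
                        RepHit(
                            contig.id,
                            frame,
                            entry.protein_id,
                            entry.family,
                            float(score),
                            E,
                            (bj - rj, bj),
                        )
                    )
    hits.sort(key=lambda h: (h.contig_id, h.evalue))
    return hits


def load_panel(fasta_path, family_map_path):
    """Read a Rep protein panel: protein FASTA plus a protein_id->family TSV."""
    fam = {}
    with open(family_map_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            fam[row[0]] = row[1]
    panel = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in fam:
            raise ValueError(f"panel protein {rec.id!r} missing from family map")
        panel.append(RepPanelEntry(rec.id, str(rec.seq), fam[rec.id]))
    if not panel:
        raise ValueError("empty Rep panel")
    return panel


def save_panel(panel, fasta_path, family_map_path):
    with open(fasta_path, "w") as fh:
        for e in panel:
            fh.write(f">{e.protein_id}\n{e.peptide}\n")
    with open(family_map_path, "w") as fh:
        for e in panel:
            fh.write(f"{e.protein_id}\t{e.family}\n")


def ingest_hits(tabular_path, family_map: dict, params: AlignmentParams | None = None):
    """RepHits from the 12-column tabular hit format (query, subject, %id,
    length, mismatches, gaps, qstart, qend, sstart, send, evalue, bitscore);
    rows at or above the E-value threshold are dropped."""
    params = params or AlignmentParams()
    hits = []
    with open(tabular_path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 12:
                raise ValueError(f"{tabular_path}:{lineno}: expected 12 columns")
            qid, sid = row[0], row[1]
            if qid not in family_map:
                raise ValueError(f"unknown query id {qid!r} in family map")
            sstart, send = int(row[8]), int(row[9])
            E = float(row[10])
            if E >= params.e_threshold:
                continue
            frame = 1 if sstart <= send else -1
            lo, hi = (sstart, send) if sstart <= send else (send, sstart)
            hits.append(
                RepHit(
                    sid, frame, qid, family_map[qid],
                    float(row[11]), E, (lo - 1, hi),
                )
            )
    return hits
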