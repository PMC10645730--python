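"""Contingency and rank statistics for the plasmid/rrn association analyses.

Chi-square independence (no continuity correction by default), Fisher's
exact test by hypergeometric enumeration, and the Mann-Whitney U test
with full enumeration for small untied samples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list
    col_labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match table shape")


@dataclass
class TestResult:
    statistic: float
    p: float
    alternative: str
    method: str
    df: int | None = None


def build_rep_rrn_table(contig_entries, ambiguous: str = "rep3") -> ContingencyTable:
    """Cross-tabulate plasmid-like contigs: (Rep_3 vs other Rep family) x
    (rRNA present vs absent).

    contig_entries: iterable of (contig_id, rep_families, rrn_present).
    Contigs carrying Rep_3 alongside another family count in the Rep_3 row
    (ambiguous='rep3', the default) or are dropped (ambiguous='drop').
    Contigs with no Rep family are ignored.
    """
    entries = list(contig_entries)
    if not entries:
        raise ValueError("no contigs to tabulate")
    ids = [e[0] for e in entries]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dup}")
    table = np.zeros((2, 2), dtype=int)
    for _cid, families, rrn in entries:
        families = set(families)
        if not families:
            continue
        if "Rep_3" in families:
            if len(families) > 1 and ambiguous == "drop":
                continue
            row = 0
        else:
            row = 1
        table[row, 0 if rrn else 1] += 1
    return ContingencyTable(table, ["Rep_3", "other_Rep"], ["rrn_present", "rrn_absent"])


def chi_square_independence(
    table: ContingencyTable, yates: bool = False
) -> TestResult:
    """Pearson chi-square test of independence on an RxC table."""
    t = table.counts
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column sum; test undefined")
    chi2, p, df, _ = stats.chi2_contingency(t, correction=yates)
    return TestResult(float(chi2), float(p), "two-sided", "asymptotic", int(df))


def fisher_exact(table: ContingencyTable, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table by hypergeometric enumeration.

    Two-sided p sums the probabilities of all tables (with the observed
    margins) no more probable than the observed one. 'greater' tests for
    enrichment of the [0,0] cell.
    """
    t = table.counts
    if t.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    a = t[0, 0]
    r1, c1, n = t[0].sum(), t[:, 0].sum(), t.sum()
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    if alternative == "two-sided":
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return TestResult(float(a), min(p, 1.0), alternative, "exact")


def _u_statistic(x, y) -> float:
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney_u(
    x, y, alternative: str = "two-sided", exact_limit: int = 12
) -> TestResult:
    """Mann-Whitney U for x over y.

    Exact p by full enumeration of label assignments when the pooled
    sample is small (n_x + n_y <= exact_limit) and tie-free; otherwise
    the normal approximation with tie correction. Fully tied data give
    p = 1 with a warning.
    """
    x, y = list(x), list(y)
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = x + y
    if len(set(pooled)) == 1:
        warnings.warn("all values tied across both groups")
        return TestResult(_u_statistic(x, y), 1.0, alternative, "degenerate")
    u_obs = _u_statistic(x, y)
    n, nx = len(pooled), len(x)
    no_ties = len(set(pooled)) == n
    if n <= exact_limit and no_ties:
        us = [
            _u_statistic(
                [pooled[i] for i in comb],
                [pooled[i] for i in range(n) if i not in set(comb)],
            )
            for comb in itertools.combinations(range(n), nx)
        ]
        us = np.array(us)
        p_greater = float((us >= u_obs).mean())
        p_less = float((us <= u_obs).mean())
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2 * min(p_greater, p_less))
        return TestResult(u_obs, p, alternative, "exact")
    res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), alternative, "asymptotic")
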