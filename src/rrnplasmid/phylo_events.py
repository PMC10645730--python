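"""Relative-rate divergence dating and ancestral gene-content events.

Dating follows the relative-rate (RelTime-style, branch-lengths-only)
framework: sister lineages are assumed to have separated from their
common ancestor for equal elapsed times, so their rates are set
proportional to their mean root-to-tip path lengths. Relative node times
(root = 1, tips = 0) are rate-corrected path lengths; calibrations scale
them to absolute ages. Confidence intervals are out of scope.

Gene gains and losses are read off ancestral presence/absence states
reconstructed either by Sankoff parsimony (configurable gain/loss costs,
ties resolved to absence) or by a two-state continuous-time Markov model
with marginal posterior states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

RATE_FLOOR = 1e-9


# --------------------------------------------------------------------------
# tree plumbing


def _label(node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted newick tree with branch lengths.

    Internal node labels are kept for calibration anchoring; unlabeled
    internal nodes get stable preorder labels N0, N1, ... Duplicate tip
    labels or missing branch lengths raise; polytomies are accepted here
    but flagged (dating requires a bifurcating tree)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as e:  # normalize dendropy reader errors
        if "ultiple occurrences" in str(e) or "uplicate" in str(e):
            raise ValueError("duplicate tip labels") from e
        raise
    tips = [t.label for t in tree.taxon_namespace]
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels")
    k = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            node.label = f"N{k}"
            k += 1
        if node.parent_node is not None and node.edge.length is None:
            raise ValueError(f"missing branch length on edge above {_label(node)!r}")
    tree.is_polytomous = any(
        len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()
    )
    return tree


def emit_tree(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class TimeTree:
    tree: dendropy.Tree
    rel_time: dict  # node label -> relative time in [0,1]
    rates: dict  # node label -> relative rate of the lineage above the node
    abs_time: dict | None = None
    calibrations: list = field(default_factory=list)
    outgroup: str | None = None
    is_relative: bool = True


# --------------------------------------------------------------------------
# relative-rate dating


def reltime_bl(tree: dendropy.Tree, outgroup: str | None = None) -> TimeTree:
    """Branch-specific relative rates and relative node times.

    Post-order, each node's mean lineage length L(u) is the average over
    its two children c of b_c + L(c). Sister lineages get rates in the
    ratio of their lineage lengths (equal elapsed time), propagated from
    a root-lineage rate of 1; node heights are the rate-corrected lengths
    L(u)/r(u), normalized so the root is 1. Rates on the outgroup side of
    the root, if an outgroup tip is designated, are not interpreted.
    """
    if any(len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()):
        raise ValueError("dating requires a fully bifurcating tree")
    L: dict = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            L[node] = 0.0
        else:
            L[node] = sum(c.edge.length + L[c] for c in kids) / len(kids)

    rates: dict = {tree.seed_node: 1.0}
    for node in tree.preorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            continue
        lens = [c.edge.length + L[c] for c in kids]
        denom = sum(lens)
        r_u = rates[node]
        if denom <= 0:
            warnings.warn(
                f"zero-length sister pair below {_label(node)!r}; rate floor applied"
            )
            for c in kids:
                rates[c] = max(r_u, RATE_FLOOR)
        else:
            for c, li in zip(kids, lens):
                rates[c] = max(r_u * len(kids) * li / denom, RATE_FLOOR)

    heights = {node: L[node] / rates[node] for node in tree.preorder_node_iter()}
    root_h = heights[tree.seed_node]
    if root_h <= 0:
        raise ValueError("tree has zero total depth")

    out_side = set()
    if outgroup is not None:
        out_tip = next(
            (n for n in tree.leaf_node_iter() if _label(n) == outgroup), None
        )
        if out_tip is None:
            raise ValueError(f"outgroup tip {outgroup!r} not in tree")
        side = out_tip
        while side.parent_node is not tree.seed_node:
            side = side.parent_node
        out_side = set(side.preorder_iter())
        ingroup_root = next(
            c for c in tree.seed_node.child_nodes() if c not in out_side
        )
        root_h = heights[ingroup_root]
        if root_h <= 0:
            raise ValueError("ingroup has zero depth")

    rel, rate_out = {}, {}
    for node in tree.preorder_node_iter():
        lbl = _label(node)
        if node in out_side:
            rel[lbl] = float("nan")
        else:
            rel[lbl] = min(heights[node] / root_h, 1.0) if node is not tree.seed_node else (
                heights[node] / root_h
            )
        rate_out[lbl] = rates[node]
    return TimeTree(tree, rel, rate_out, outgroup=outgroup)


def apply_calibrations(timetree: TimeTree, calibrations) -> TimeTree:
    """Scale relative times to absolute ages.

    calibrations: list of {node, point} or {node, min, max}. A point
    calibration at node X fixes the global factor at T/t(X); min/max
    constraints intersect to a feasible factor interval whose midpoint is
    used. Contradictory constraints raise, naming a violated pair.
    """
    if not calibrations:
        timetree.abs_time = None
        timetree.is_relative = True
        return timetree
    lo, hi = 0.0, math.inf
    lo_src = hi_src = None
    for cal in calibrations:
        t = timetree.rel_time.get(cal["node"])
        if t is None:
            raise ValueError(f"calibration node {cal['node']!r} not in tree")
        if t <= 0 or math.isnan(t):
            raise ValueError(f"cannot calibrate node {cal['node']!r} at time {t}")
        if "point" in cal:
            c_lo, c_hi = cal["point"] / t, cal["point"] / t
        else:
            c_lo = cal.get("min", 0.0) / t
            c_hi = cal.get("max", math.inf) / t
        if c_lo > lo:
            lo, lo_src = c_lo, cal["node"]
        if c_hi < hi:
            hi, hi_src = c_hi, cal["node"]
        if lo > hi * (1 + 1e-12):
            raise ValueError(
                f"contradictory calibrations: min at {lo_src!r} vs max at {hi_src!r}"
            )
    factor = lo if math.isinf(hi) else (lo + hi) / 2.0
    timetree.abs_time = {
        lbl: factor * t for lbl, t in timetree.rel_time.items()
    }
    timetree.calibrations = list(calibrations)
    timetree.is_relative = False
    return timetree


# --------------------------------------------------------------------------
# presence/absence reconstruction


@dataclass
class EventCounts:
    gains: dict  # branch (child node label) -> int
    losses: dict
    gained_families: dict  # branch -> list of family ids
    lost_families: dict
    node_states: pd.DataFrame  # families x node labels, 0/1


def _check_pam(tree, pam: pd.DataFrame):
    tips = {_label(n) for n in tree.leaf_node_iter()}
    if set(pam.columns) != tips:
        raise ValueError(
            f"presence/absence taxa {sorted(pam.columns)} do not match tree tips"
        )
    vals = set(np.unique(pam.values))
    if not vals <= {0, 1}:
        raise ValueError("presence/absence entries must be 0/1")


def _sankoff_states(tree, tip_states: dict, gain_cost: float, loss_cost: float):
    """Minimal-cost ancestral 0/1 states; ties resolve to absence (0)."""
    INF = math.inf
    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = tip_states[_label(node)]
            cost[node] = [0.0 if s == 0 else INF, 0.0 if s == 1 else INF]
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = cost[child]
                c0 += min(k0, k1 + gain_cost)  # parent absent
                c1 += min(k0 + loss_cost, k1)  # parent present
            cost[node] = [c0, c1]
    states: dict = {}
    root = tree.seed_node
    states[root] = 0 if cost[root][0] <= cost[root][1] else 1
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        p = states[node.parent_node]
        k0, k1 = cost[node]
        stay = k0 if p == 0 else k1
        switch = (k1 + gain_cost) if p == 0 else (k0 + loss_cost)
        states[node] = p if stay <= switch else 1 - p
    total = min(cost[root])
    return {_label(n): s for n, s in states.items()}, total


def _transition_matrix(alpha: float, beta: float, t: float) -> np.ndarray:
    """Two-state CTMC transition probabilities over duration t."""
    s = alpha + beta
    e = math.exp(-s * t)
    pi0, pi1 = beta / s, alpha / s
    return np.array(
        [[pi0 + pi1 * e, pi1 - pi1 * e], [pi0 - pi0 * e, pi1 + pi1 * e]]
    )


def _ml_loglik(tree, patterns: np.ndarray, tip_order, alpha, beta):
    """Pruning-algorithm log-likelihood summed over family patterns."""
    tip_idx = {lbl: i for i, lbl in enumerate(tip_order)}
    s = alpha + beta
    prior = np.array([beta / s, alpha / s])
    total = 0.0
    partial: dict = {}
    nfam = patterns.shape[0]
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            obs = patterns[:, tip_idx[_label(node)]]
            pl = np.zeros((nfam, 2))
            pl[np.arange(nfam), obs] = 1.0
            partial[node] = pl
        else:
            pl = np.ones((nfam, 2))
            for child in node.child_nodes():
                P = _transition_matrix(alpha, beta, max(child.edge.length, 0.0))
                pl *= partial[child] @ P.T
            partial[node] = pl
    root_l = partial[tree.seed_node] @ prior
    total = float(np.sum(np.log(np.maximum(root_l, 1e-300))))
    return total, partial


def _ml_states(tree, pam: pd.DataFrame, alpha, beta):
    """Marginal posterior 0/1 states (argmax, ties to absence)."""
    tip_order = list(pam.columns)
    patterns = pam.values.astype(int)
    _, partial = _ml_loglik(tree, patterns, tip_order, alpha, beta)
    s = alpha + beta
    prior = np.array([beta / s, alpha / s])
    # top-down pass: outside likelihoods
    outside = {tree.seed_node: np.tile(prior, (patterns.shape[0], 1))}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            sibs = np.ones((patterns.shape[0], 2))
            for other in node.child_nodes():
                if other is child:
                    continue
                P_o = _transition_matrix(alpha, beta, max(other.edge.length, 0.0))
                sibs *= partial[other] @ P_o.T
            P_c = _transition_matrix(alpha, beta, max(child.edge.length, 0.0))
            outside[child] = (outside[node] * sibs) @ P_c
    states = {}
    for node in tree.preorder_node_iter():
        post = outside[node] * partial[node]
        post /= post.sum(axis=1, keepdims=True)
        states[_label(node)] = (post[:, 1] > post[:, 0]).astype(int)
    return states


def reconstruct_presence(
    tree: dendropy.Tree,
    pam: pd.DataFrame,
    method: str = "parsimony",
    gain_cost: float = 1.0,
    loss_cost: float = 1.0,
    gain_rate: float | None = None,
    loss_rate: float | None = None,
):
    """Ancestral gene-family states and per-branch gain/loss events.

    pam: families x taxa 0/1 DataFrame, columns matching tree tips.
    method 'parsimony' uses Sankoff costs (gain_cost, loss_cost);
    'ml' a two-state Markov model whose rates are optimized by bounded
    search unless given. Events are parent->child state changes.
    """
    _check_pam(tree, pam)
    labels = [_label(n) for n in tree.preorder_node_iter()]

    if method == "parsimony":
        rows = {}
        for fam, row in pam.iterrows():
            states, _ = _sankoff_states(tree, row.to_dict(), gain_cost, loss_cost)
            rows[fam] = states
        node_states = pd.DataFrame.from_dict(rows, orient="index")[labels]
    elif method == "ml":
        if gain_rate is None or loss_rate is None:
            patterns = pam.values.astype(int)
            tip_order = list(pam.columns)

            def nll(logr):
                a, b = math.exp(logr[0]), math.exp(logr[1])
                return -_ml_loglik(tree, patterns, tip_order, a, b)[0]

            res = minimize(
                nll, x0=[0.0, 0.0], method="L-BFGS-B",
                bounds=[(-12, 6), (-12, 6)],
            )
            gain_rate, loss_rate = math.exp(res.x[0]), math.exp(res.x[1])
        states = _ml_states(tree, pam, gain_rate, loss_rate)
        node_states = pd.DataFrame(
            {lbl: states[lbl] for lbl in labels}, index=pam.index
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    gains, losses = {}, {}
    gained_f, lost_f = {}, {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child, parent = _label(node), _label(node.parent_node)
        delta = node_states[child] - node_states[parent]
        g = list(node_states.index[delta == 1])
        l = list(node_states.index[delta == -1])
        gains[child], losses[child] = len(g), len(l)
        gained_f[child], lost_f[child] = g, l
    return EventCounts(gains, losses, gained_f, lost_f, node_states)


def parsimony_cost(tree, tip_states: dict, gain_cost=1.0, loss_cost=1.0) -> float:
    """Total minimal event cost for one family (exposed for verification)."""
    _, total = _sankoff_states(tree, tip_states, gain_cost, loss_cost)
    return total


def focal_branch_events(events: EventCounts, focal_node: str):
    """Families gained/lost on the branch subtending a focal node."""
    if focal_node not in events.gained_families:
        raise ValueError(f"unknown node {focal_node!r} (or it is the root)")
    return {
        "gained": sorted(events.gained_families[focal_node]),
        "lost": sorted(events.lost_families[focal_node]),
    }


def consistently_gained(events_list, focal_nodes):
    """Families gained on the focal branch in every one of k clades.

    events_list and focal_nodes are parallel; with a single EventCounts
    shared across clades pass it repeated."""
    sets = [
        set(ev.gained_families.get(node, []))
        for ev, node in zip(events_list, focal_nodes)
    ]
    return sorted(set.intersection(*sets)) if sets else []
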