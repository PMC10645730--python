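"""Relative-rate dating and ancestral presence/absence reconstruction."""

import itertools
import math

import pandas as pd
import pytest

import rrnplasmid as rp
from rrnplasmid.phylo_events import _label, parsimony_cost


# ------------------------------------------------------------------ parse


def test_parse_counts_nodes_and_depths():
    t = rp.parse_tree("((A:1,B:1):1,C:2);")
    tips = [l for l in t.leaf_node_iter()]
    assert len(tips) == 3
    assert sum(1 for n in t.preorder_node_iter() if not n.is_leaf()) == 2
    for tip in tips:
        d = 0.0
        n = tip
        while n.parent_node is not None:
            d += n.edge.length
            n = n.parent_node
        assert d == pytest.approx(2.0)


def test_parse_round_trip():
    s = "((A:1.5,B:0.5)N_ab:1,C:2);"
    t1 = rp.parse_tree(s)
    t2 = rp.parse_tree(rp.phylo_events.emit_tree(t1))
    assert {(_label(n)) for n in t1.leaf_node_iter()} == {
        (_label(n)) for n in t2.leaf_node_iter()
    }


def test_missing_branch_length_names_edge():
    with pytest.raises(ValueError, match="branch length"):
        rp.parse_tree("((A:1,B):1,C:2);")


def test_duplicate_tips_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        rp.parse_tree("((A:1,A:1):1,C:2);")


def test_polytomy_flagged_then_refused_by_dating():
    t = rp.parse_tree("(A:1,B:1,C:1);")
    assert t.is_polytomous
    with pytest.raises(ValueError, match="bifurcating"):
        rp.reltime_bl(t)


# ----------------------------------------------------------------- dating


def test_ultrametric_clock_limit():
    tt = rp.reltime_bl(rp.parse_tree("((A:1,B:1)X:1,C:2)R;"))
    assert tt.rel_time["R"] == pytest.approx(1.0, abs=1e-9)
    assert tt.rel_time["X"] == pytest.approx(0.5, abs=1e-9)
    assert all(tt.rel_time[t] == 0.0 for t in "ABC")
    assert all(r == pytest.approx(1.0) for r in tt.rates.values())


def test_larger_ultrametric_tree_times_equal_depths():
    s = "(((A:1,B:1):1,(C:0.5,D:0.5):1.5):2,(E:3,F:3):1)R;"
    tt = rp.reltime_bl(rp.parse_tree(s))
    # node depths / root depth
    t = rp.parse_tree(s)
    depths = {}
    for n in t.postorder_node_iter():
        depths[_label(n)] = 0.0 if n.is_leaf() else (
            n.child_nodes()[0].edge.length + depths[_label(n.child_nodes()[0])]
        )
    for lbl, d in depths.items():
        assert tt.rel_time[lbl] == pytest.approx(d / 4.0, abs=1e-9)


def test_cherry_rates_proportional_to_lengths():
    tt = rp.reltime_bl(rp.parse_tree("((A:1,B:3)X:1,C:2)R;"))
    assert tt.rates["B"] / tt.rates["A"] == pytest.approx(3.0)
    # equal elapsed time: b/r agrees between the sisters
    assert 1 / tt.rates["A"] == pytest.approx(3 / tt.rates["B"])


def test_branch_length_rescaling_leaves_times_invariant():
    s = "(((A:2,B:1):1,C:4):1,D:3)R;"
    tt1 = rp.reltime_bl(rp.parse_tree(s))
    s2 = "(((A:14,B:7):7,C:28):7,D:21)R;"
    tt2 = rp.reltime_bl(rp.parse_tree(s2))
    for lbl in tt1.rel_time:
        assert tt1.rel_time[lbl] == pytest.approx(tt2.rel_time[lbl], abs=1e-12)


def test_times_decrease_root_to_tip():
    t = rp.parse_tree("(((A:2,B:1):1,C:4):1,D:3)R;")
    tt = rp.reltime_bl(t)
    for node in t.preorder_node_iter():
        for child in node.child_nodes():
            assert tt.rel_time[_label(node)] > tt.rel_time[_label(child)]


def test_zero_length_sister_pair_warns():
    with pytest.warns(UserWarning, match="rate floor"):
        rp.reltime_bl(rp.parse_tree("((A:0,B:0):1,C:1);"))


# ------------------------------------------------------------ calibration


def _tt():
    return rp.reltime_bl(rp.parse_tree("((A:1,B:1)X:1,C:2)R;"))


def test_point_calibration_scales_linearly():
    tt = rp.apply_calibrations(_tt(), [{"node": "X", "point": 100}])
    assert tt.abs_time["R"] == pytest.approx(200.0)
    assert tt.abs_time["X"] == pytest.approx(100.0)
    tt2 = rp.apply_calibrations(_tt(), [{"node": "X", "point": 200}])
    assert tt2.abs_time["R"] == pytest.approx(400.0)


def test_no_calibrations_flagged_relative():
    tt = rp.apply_calibrations(_tt(), [])
    assert tt.is_relative and tt.abs_time is None


def test_min_max_interval_midpoint():
    tt = rp.apply_calibrations(_tt(), [{"node": "X", "min": 90, "max": 110}])
    # factor interval [180, 220] -> midpoint 200
    assert tt.abs_time["R"] == pytest.approx(200.0)


def test_contradictory_calibrations_error():
    with pytest.raises(ValueError, match="contradictory"):
        rp.apply_calibrations(
            _tt(),
            [{"node": "X", "min": 300}, {"node": "R", "max": 100}],
        )


def test_outgroup_side_not_interpreted():
    tt = rp.reltime_bl(rp.parse_tree("((A:1,B:1)X:1,C:2)R;"), outgroup="C")
    assert math.isnan(tt.rel_time["C"])
    assert tt.rel_time["X"] == pytest.approx(1.0)


# ------------------------------------------------- presence/absence events


TREE5 = "(((A:1,B:1):1,(C:1,D:1):1):1,E:3)R;"


def _brute_force_min_cost(tree, tip_states, gain=1.0, loss=1.0):
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for combo in itertools.product([0, 1], repeat=len(internals)):
        assign = dict(zip(internals, combo))
        cost = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            p = assign[node.parent_node]
            c = assign[node] if not node.is_leaf() else tip_states[_label(node)]
            if p == 0 and c == 1:
                cost += gain
            elif p == 1 and c == 0:
                cost += loss
        best = min(best, cost)
    return best


@pytest.mark.parametrize("gain,loss", [(1.0, 1.0), (2.0, 1.0), (1.0, 3.0)])
def test_sankoff_matches_exhaustive_all_32_patterns(gain, loss):
    tree = rp.parse_tree(TREE5)
    tips = sorted(_label(n) for n in tree.leaf_node_iter())
    for pattern in itertools.product([0, 1], repeat=5):
        states = dict(zip(tips, pattern))
        assert parsimony_cost(tree, states, gain, loss) == pytest.approx(
            _brute_force_min_cost(tree, states, gain, loss)
        ), (pattern, gain, loss)


def test_all_present_means_no_events():
    tree = rp.parse_tree(TREE5)
    pam = pd.DataFrame([[1] * 5], index=["fam"], columns=list("ABCDE"))
    for method in ("parsimony", "ml"):
        ev = rp.reconstruct_presence(tree, pam, method)
        assert sum(ev.gains.values()) == 0 and sum(ev.losses.values()) == 0
        assert ev.node_states.loc["fam"].eq(1).all()


def test_single_tip_presence_is_one_terminal_gain():
    tree = rp.parse_tree("((A:1,B:1):1,(C:1,D:1):1)R;")
    pam = pd.DataFrame([[1, 0, 0, 0]], index=["fam"], columns=list("ABCD"))
    ev = rp.reconstruct_presence(tree, pam, "parsimony")
    assert ev.gains["A"] == 1
    assert sum(ev.gains.values()) == 1 and sum(ev.losses.values()) == 0


def test_parsimony_ties_resolve_to_absence():
    # (A=1, B=0): ancestor 0 or 1 are both cost 1; absence preferred
    tree = rp.parse_tree("(A:1,B:1)R;")
    pam = pd.DataFrame([[1, 0]], index=["fam"], columns=list("AB"))
    ev = rp.reconstruct_presence(tree, pam, "parsimony")
    assert ev.node_states.loc["fam", "R"] == 0


def test_ml_near_zero_rates_keep_uniform_state():
    tree = rp.parse_tree(TREE5)
    pam = pd.DataFrame([[1] * 5, [0] * 5], index=["f1", "f0"], columns=list("ABCDE"))
    ev = rp.reconstruct_presence(tree, pam, "ml", gain_rate=1e-6, loss_rate=1e-6)
    assert ev.node_states.loc["f1"].eq(1).all()
    assert ev.node_states.loc["f0"].eq(0).all()


def test_ml_long_branches_fall_back_to_stationary_tie_absence():
    tree = rp.parse_tree("((A:500,B:500):500,(C:500,D:500):500)R;")
    pam = pd.DataFrame([[1, 1, 1, 1]], index=["fam"], columns=list("ABCD"))
    ev = rp.reconstruct_presence(tree, pam, "ml", gain_rate=1.0, loss_rate=1.0)
    # posteriors at internal nodes approach the stationary 0.5/0.5; the
    # argmax tie resolves to absence
    for lbl in ("R",):
        assert ev.node_states.loc["fam", lbl] == 0


def test_ml_rate_optimization_recovers_events_on_clear_pattern():
    tree = rp.parse_tree(TREE5)
    pam = pd.DataFrame(
        [[1, 1, 0, 0, 0], [0, 0, 1, 1, 0], [1, 1, 1, 1, 1]],
        index=["fAB", "fCD", "fall"], columns=list("ABCDE"),
    )
    ev = rp.reconstruct_presence(tree, pam, "ml")
    assert ev.node_states.loc["fall"].eq(1).all()
    assert sum(ev.gains.values()) >= 2  # fAB and fCD each need a gain


def test_mismatched_taxa_rejected():
    tree = rp.parse_tree(TREE5)
    pam = pd.DataFrame([[1, 0]], index=["fam"], columns=["A", "Z"])
    with pytest.raises(ValueError, match="tips"):
        rp.reconstruct_presence(tree, pam)


# ----------------------------------------------------------- focal events


def test_focal_branch_and_intersection():
    tree = rp.parse_tree("(((A:1,B:1)X:1,C:2)Y:1,D:3)R;")
    pam = pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [1, 0, 0, 0]],
        index=["rep", "other", "solo"], columns=list("ABCD"),
    )
    ev = rp.reconstruct_presence(tree, pam, "parsimony")
    focal = rp.focal_branch_events(ev, "X")
    assert focal["gained"] == ["other", "rep"]
    assert focal["lost"] == []
    assert rp.focal_branch_events(ev, "A")["gained"] == ["solo"]
    # intersection across clades keeps only universally gained families
    inter = rp.consistently_gained([ev, ev], ["X", "X"])
    assert inter == ["other", "rep"]
    inter2 = rp.consistently_gained([ev, ev], ["X", "A"])
    assert inter2 == []
    with pytest.raises(ValueError, match="unknown node"):
        rp.focal_branch_events(ev, "nope")
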