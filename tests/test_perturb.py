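"""Mutants, edge removals, damage protocols and the double-knockout screen."""

import pytest

from fachkrec.dynamics import trajectory
from fachkrec.model import CCP_FIXED_POINT, novel_interactions
from fachkrec.perturb import (EdgeNotPresentError, Perturbation, Protocol,
                              constitutive, double_mutant_screen, knockout,
                              remove_interaction, remove_novel_interactions,
                              run_protocol)
from fachkrec.rules import Const, parse_expression, semantically_equal

PERSISTENT = Protocol("persistent")
PULSE = Protocol("pulse")


# ---------------------------------------------------------------------------
# clamps
# ---------------------------------------------------------------------------

def test_knockout_holds_node_at_zero_everywhere(fa):
    t = trajectory(fa, {"ICL": 1, "FAcore": 1}, clamps=knockout("FAcore").clamps)
    for s in (*t.transient, *t.attractor.states):
        assert s["FAcore"] == 0


def test_constitutive_equals_persistent_exposure(fa):
    via_clamp = run_protocol(fa, constitutive("ICL"), Protocol("none"))
    via_protocol = run_protocol(fa, Perturbation(), PERSISTENT)
    assert [a.state_values for a, _ in via_clamp] == \
           [a.state_values for a, _ in via_protocol]


def test_combining_overlapping_clamps_rejected():
    with pytest.raises(ValueError):
        knockout("WIP1").combine(constitutive("WIP1"))


# ---------------------------------------------------------------------------
# remove_interaction
# ---------------------------------------------------------------------------

def test_removing_sole_activator_makes_rule_constant_zero(fa):
    rs = remove_interaction(fa, "p53", "p21")
    assert semantically_equal(rs.rules["p21"], Const(0))


def test_removing_negative_regulator_is_permissive(fa):
    rs = remove_interaction(fa, "NUC1", "ICL")
    assert semantically_equal(rs.rules["ICL"], parse_expression("ICL ∧ ¬NUC2"))


def test_removal_leaves_other_rules_untouched(fa):
    rs = remove_interaction(fa, "p53", "p21")
    for node in fa.nodes:
        if node != "p21":
            assert rs.rules[node] == fa.rules[node]


def test_removing_absent_edge_rejected(fa):
    with pytest.raises(EdgeNotPresentError):
        remove_interaction(fa, "WIP1", "p21")


def test_grouped_removal_of_several_regulators_of_one_target(fa):
    # removing both activators of NUC2's conjunction one by one would
    # constant-fold the rule after the first removal
    pert = Perturbation(removed_edges=frozenset({("RNF4", "NUC2"),
                                                 ("PLK1", "NUC2")}))
    rs = pert.apply(fa)
    assert semantically_equal(rs.rules["NUC2"], Const(0))


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

def test_wt_icl_pulse_reaches_strict_ccp_fixed_point(fa):
    [(att, call)] = run_protocol(fa, Perturbation(), PULSE)
    assert att.period == 1
    assert att.states[0] == fa.state(CCP_FIXED_POINT)
    assert call.category == "CCP"


def test_wt_persistent_icl_arrests_without_cycb(fa):
    results = run_protocol(fa, Perturbation(), PERSISTENT)
    for att, call in results:
        assert not att.ever_on("CycB-CDK1")
        assert call.category == "CCA"


@pytest.mark.parametrize("mutant", ["FAcore", "FANCD2I", "NUC1"])
def test_fa_mutants_adapt_to_persistent_damage(fa, mutant):
    results = run_protocol(fa, knockout(mutant), PERSISTENT)
    assert any(call.category == "CCP_DDA" for _, call in results)
    for att, call in results:
        if call.category == "CCP_DDA":
            assert att.ever_on("CycB-CDK1")
            assert any(att.ever_on(d) for d in ("ICL", "DSB", "R-DSB"))


def test_pulse_without_nucleases_keeps_icl_on(fa):
    # with both unhooking routes knocked out ICL's own rule preserves it
    pert = knockout("NUC1").combine(knockout("NUC2"))
    [(att, _)] = run_protocol(fa, pert, PULSE)
    t = trajectory(pert.apply(fa), {"ICL": 1}, clamps=pert.clamps)
    for s in (*t.transient, *t.attractor.states):
        assert s["ICL"] == 1
    assert att.always_on("ICL")


def test_ensemble_mode_returns_basins(fa):
    results = run_protocol(fa, knockout("FAcore"),
                           Protocol("persistent", initial="all"))
    total = sum(att.basin_size for att, _ in results)
    assert total == 2 ** 23  # 25 nodes minus FAcore and ICL clamps


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

CHKREC = ["WIP1", "CDK1-AurA", "PLK1", "CDC25", "CycB-CDK1"]


def test_facore_chkrec_double_knockouts_all_arrest(fa):
    matrix = double_mutant_screen(fa, knockout("FAcore"), CHKREC, PERSISTENT)
    assert sorted(matrix["candidate"]) == sorted(CHKREC)
    assert (matrix["category"] == "CCA").all()
    assert not matrix["cycb_ever_on"].any()


def test_screen_output_invariant_to_candidate_order(fa):
    fwd = double_mutant_screen(fa, knockout("FAcore"), CHKREC, PERSISTENT)
    rev = double_mutant_screen(fa, knockout("FAcore"), CHKREC[::-1], PERSISTENT)
    key = ["candidate", "attractor"]
    assert fwd.sort_values(key).reset_index(drop=True).equals(
        rev.sort_values(key).reset_index(drop=True))


def test_screen_rejects_candidates_clashing_with_background(fa):
    with pytest.raises(ValueError):
        double_mutant_screen(fa, knockout("FAcore"), ["FAcore"], PERSISTENT)


def test_full_screen_is_row_complete(fa):
    candidates = [n for n in fa.nodes if n != "FAcore"]
    matrix = double_mutant_screen(fa, knockout("FAcore"), candidates, PERSISTENT)
    assert set(matrix["candidate"]) == set(candidates)
    assert len(candidates) == 24


def test_empty_candidate_list_gives_empty_matrix(fa):
    matrix = double_mutant_screen(fa, knockout("FAcore"), [], PERSISTENT)
    assert matrix.empty


# ---------------------------------------------------------------------------
# novel-interaction removal
# ---------------------------------------------------------------------------

def test_novel_interaction_removal_changes_exactly_their_targets(fa):
    rs = remove_novel_interactions(fa)
    touched = {e.target for e in novel_interactions()}
    for node in fa.nodes:
        if node not in touched:
            assert rs.rules[node] == fa.rules[node]
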