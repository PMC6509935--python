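"""Synchronous dynamics: stepping, trajectories, and both enumeration engines."""

import numpy as np
import pytest

from fachkrec.dynamics import (Attractor, BudgetExceededError,
                               StateSpaceTooLargeError, enumerate_attractors,
                               step, trajectory)
from fachkrec.model import CCP_FIXED_POINT
from fachkrec.random_nets import RandomNetworkSpec, generate_random_network
from fachkrec.rules import parse_rules


def identity_network(n):
    return parse_rules("\n".join(f"N{i} <- N{i}" for i in range(n)))


# ---------------------------------------------------------------------------
# step
# ---------------------------------------------------------------------------

def test_all_zero_successor_activates_only_cdk1_aura(fa):
    succ = step(fa, 0)
    assert succ.on_nodes() == ("CDK1-AurA",)


def test_ccp_fixed_point_maps_to_itself(fa):
    state = fa.state(CCP_FIXED_POINT)
    assert step(fa, state) == state


def test_clamped_node_ignores_its_rule(fa):
    # ICL's own rule would clear it when NUC1 is active
    state = fa.state({"ICL": 1, "NUC1": 1})
    assert step(fa, state)["ICL"] == 0
    assert step(fa, state, clamps={"ICL": 1})["ICL"] == 1


def test_unknown_clamp_node_rejected(fa):
    with pytest.raises(KeyError):
        step(fa, 0, clamps={"NOPE": 1})


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def test_wild_type_relaxes_to_ccp_fixed_point(fa):
    t = trajectory(fa, 0)
    assert t.attractor.period == 1
    assert t.attractor.states[0] == fa.state(CCP_FIXED_POINT)
    # transient states are distinct and none is the fixed point
    vals = [int(s) for s in t.transient]
    assert len(set(vals)) == len(vals)
    assert int(t.attractor.states[0]) not in vals


def test_identity_network_trajectories_are_trivial():
    rs = identity_network(4)
    for v in range(16):
        t = trajectory(rs, v)
        assert t.transient_length == 0
        assert t.attractor.period == 1
        assert int(t.attractor.states[0]) == v


def test_persistent_icl_clamp_holds_along_whole_trajectory(fa):
    t = trajectory(fa, {"ICL": 1}, clamps={"ICL": 1})
    for s in (*t.transient, *t.attractor.states):
        assert s["ICL"] == 1
    assert not t.attractor.ever_on("CycB-CDK1")


def test_step_budget_error(fa):
    with pytest.raises(BudgetExceededError):
        trajectory(fa, {"ICL": 1}, max_steps=2)


def test_cycle_validity(fa):
    t = trajectory(fa, {"ICL": 1}, clamps={"ICL": 1})
    att = t.attractor
    s = att.states[0]
    for expected in (*att.states[1:], att.states[0]):
        s = step(fa, s, clamps={"ICL": 1})
        assert s == expected


# ---------------------------------------------------------------------------
# enumeration engines
# ---------------------------------------------------------------------------

def test_identity_network_has_all_fixed_points():
    rs = identity_network(6)
    atts = enumerate_attractors(rs)
    assert len(atts) == 64
    assert all(a.period == 1 and a.basin_size == 1 for a in atts)


@pytest.mark.parametrize("n,k,seed", [
    (5, 2, 1), (6, 2, 7), (7, 3, 3), (8, 2, 11), (8, 3, 4), (10, 2, 42),
])
def test_bulk_engine_matches_naive_oracle(n, k, seed):
    rs = generate_random_network(RandomNetworkSpec(n, k, seed))
    bulk = enumerate_attractors(rs, method="bulk")
    naive = enumerate_attractors(rs, method="naive")
    assert [a.state_values for a in bulk] == [a.state_values for a in naive]
    assert [a.basin_size for a in bulk] == [a.basin_size for a in naive]
    assert sum(a.basin_size for a in bulk) == 2 ** n


@pytest.mark.parametrize("seed", [0, 5])
def test_engines_agree_under_clamps_and_pulse(seed):
    rs = generate_random_network(RandomNetworkSpec(7, 2, seed))
    clamps = {"N00": 1, "N03": 0}
    fixed = {"N01": 1}
    bulk = enumerate_attractors(rs, clamps, method="bulk", initial_fixed=fixed)
    naive = enumerate_attractors(rs, clamps, method="naive", initial_fixed=fixed)
    assert [a.state_values for a in bulk] == [a.state_values for a in naive]
    assert [a.basin_size for a in bulk] == [a.basin_size for a in naive]
    # basins partition the restricted initial slice: 2^(7-2-1)
    assert sum(a.basin_size for a in bulk) == 2 ** 4
    # clamped nodes constant along every attractor
    for a in bulk:
        assert a.always_on("N00") and not a.ever_on("N03")


def test_explicit_initial_space_basins_partition_it(fa):
    states = [0, 1, 2, 3, int(fa.state(CCP_FIXED_POINT))]
    atts = enumerate_attractors(fa, initial_space=states)
    assert sum(a.basin_size for a in atts) == len(states)


def test_exhaustive_mode_refuses_oversized_spaces():
    rs = identity_network(8)
    with pytest.raises(StateSpaceTooLargeError):
        enumerate_attractors(rs, max_bits=6)


def test_determinism_repeated_runs_agree():
    rs = generate_random_network(RandomNetworkSpec(6, 2, 9))
    a1 = enumerate_attractors(rs)
    a2 = enumerate_attractors(rs)
    assert a1 == a2


def test_attractor_canonical_rotation():
    att = Attractor.from_cycle(("A", "B"), [3, 1, 2])
    assert att.state_values == (1, 2, 3)
    with pytest.raises(ValueError):
        Attractor.from_cycle(("A",), [1, 1])
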