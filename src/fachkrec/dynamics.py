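"""Synchronous Boolean dynamics: stepping, trajectories, attractor enumeration.

Updating is deterministic and synchronous: every node simultaneously takes
the value of its rule evaluated on the current state; clamped nodes take
their clamp value instead (modelling null / constitutive mutants and
persistent damage).  Because the state space is finite and the map is a
function, every trajectory ends in a cycle (an attractor; period 1 is a
fixed point).

Two enumeration engines are provided:

* ``bulk`` — evaluates the update map over the whole (clamp-reduced) state
  space as vectorized bit operations, then finds the cycles of the resulting
  functional graph by pointer doubling.  This makes exhaustive enumeration
  of a 25-node network (2^25 states) tractable.
* ``naive`` — follows one trajectory per initial state with memoization;
  simple enough to serve as an independent oracle on small networks.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rules import NetworkState, RuleSet, StateLike

__all__ = [
    "Attractor",
    "Trajectory",
    "StateSpaceTooLargeError",
    "BudgetExceededError",
    "step",
    "trajectory",
    "enumerate_attractors",
    "attractor_table",
]

#: Hard ceiling on exhaustive enumeration (free-node count).  Above this the
#: engine refuses rather than silently subsampling.
MAX_EXHAUSTIVE_BITS = 25

_CHUNK_BITS = 20  # bulk evaluation chunk: 2^20 states per block


class StateSpaceTooLargeError(ValueError):
    """Exhaustive enumeration requested over more than 2^25 states."""


class BudgetExceededError(RuntimeError):
    """A trajectory did not close a cycle within the step budget."""


# ---------------------------------------------------------------------------
# Attractors and trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    """A cycle of states closed under the synchronous update map.

    ``state_values`` holds the integer-encoded cycle states in update order,
    rotated so the smallest encoding comes first (the canonical rotation —
    attractor identity is this tuple).  ``basin_size`` counts the initial
    states whose trajectories reach the cycle, when known.
    """

    nodes: tuple[str, ...]
    state_values: tuple[int, ...]
    basin_size: int | None = field(default=None, compare=False)

    @classmethod
    def from_cycle(cls, nodes: tuple[str, ...], values: Iterable[int],
                   basin_size: int | None = None) -> "Attractor":
        vals = tuple(int(v) for v in values)
        if len(set(vals)) != len(vals):
            raise ValueError("cycle states must be distinct")
        k = vals.index(min(vals))
        return cls(nodes, vals[k:] + vals[:k], basin_size)

    @property
    def period(self) -> int:
        return len(self.state_values)

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    @property
    def states(self) -> tuple[NetworkState, ...]:
        return tuple(NetworkState(self.nodes, v) for v in self.state_values)

    def _bit(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def ever_on(self, node: str) -> bool:
        i = self._bit(node)
        return any((v >> i) & 1 for v in self.state_values)

    def always_on(self, node: str) -> bool:
        i = self._bit(node)
        return all((v >> i) & 1 for v in self.state_values)

    def with_basin(self, basin_size: int) -> "Attractor":
        return Attractor(self.nodes, self.state_values, basin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[(v >> i) & 1 for i in range(len(self.nodes))] for v in self.state_values],
            columns=list(self.nodes))

    def __repr__(self):
        basin = f", basin={self.basin_size}" if self.basin_size is not None else ""
        return f"<Attractor period={self.period}{basin} min_state={self.state_values[0]}>"


@dataclass(frozen=True)
class Trajectory:
    """A transient run ending in an attractor.

    Transient states are pairwise distinct and none belongs to the cycle.
    """

    transient: tuple[NetworkState, ...]
    attractor: Attractor

    @property
    def transient_length(self) -> int:
        return len(self.transient)

    def to_frame(self) -> pd.DataFrame:
        nodes = self.attractor.nodes
        rows = [s.as_dict() for s in self.transient] + \
               [s.as_dict() for s in self.attractor.states]
        frame = pd.DataFrame(rows, columns=list(nodes))
        frame.insert(0, "phase", ["transient"] * len(self.transient)
                     + ["attractor"] * self.attractor.period)
        return frame


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _check_clamps(rs: RuleSet, clamps: Mapping[str, int] | None) -> dict[str, int]:
    clamps = dict(clamps or {})
    unknown = set(clamps) - set(rs.nodes)
    if unknown:
        raise KeyError(f"unknown clamp node(s): {sorted(unknown)}")
    return {n: int(bool(v)) for n, v in clamps.items()}


def _project(rs: RuleSet, value: int, clamps: Mapping[str, int]) -> int:
    for node, bit in clamps.items():
        i = rs.index(node)
        value = (value | (1 << i)) if bit else (value & ~(1 << i))
    return value


def _step_int(rs: RuleSet, value: int, clamps: Mapping[str, int]) -> int:
    env = {node: (value >> i) & 1 for i, node in enumerate(rs.nodes)}
    out = 0
    for i, node in enumerate(rs.nodes):
        if node in clamps:
            bit = clamps[node]
        else:
            bit = rs.rules[node](env)
        if bit:
            out |= 1 << i
    return out


def step(rs: RuleSet, state: StateLike,
         clamps: Mapping[str, int] | None = None) -> NetworkState:
    """One synchronous update.  Clamped nodes keep their clamp value."""
    clamps = _check_clamps(rs, clamps)
    value = int(rs.state(state))
    return NetworkState(rs.nodes, _step_int(rs, value, clamps))


def trajectory(rs: RuleSet, state: StateLike,
               clamps: Mapping[str, int] | None = None,
               max_steps: int | None = None) -> Trajectory:
    """Iterate the update map until the trajectory closes a cycle.

    The initial state is projected onto the clamps first.  ``max_steps``
    bounds the number of update steps; exceeding it without closing a cycle
    raises :class:`BudgetExceededError` (by default the budget is unbounded —
    a deterministic finite system always terminates).
    """
    clamps = _check_clamps(rs, clamps)
    x = _project(rs, int(rs.state(state)), clamps)
    seen: dict[int, int] = {}
    path: list[int] = []
    while x not in seen:
        seen[x] = len(path)
        path.append(x)
        if max_steps is not None and len(path) > max_steps:
            raise BudgetExceededError(
                f"no cycle closed within {max_steps} steps")
        x = _step_int(rs, x, clamps)
    first = seen[x]
    att = Attractor.from_cycle(rs.nodes, path[first:])
    transient = tuple(NetworkState(rs.nodes, v) for v in path[:first])
    return Trajectory(transient, att)


# ---------------------------------------------------------------------------
# Bulk (bit-parallel) enumeration
# ---------------------------------------------------------------------------

def _bulk_successors(rs: RuleSet, clamps: Mapping[str, int],
                     free: list[str]) -> np.ndarray:
    """Successor map over the clamp-reduced subspace, as a uint32 array
    indexed by free-node bit patterns."""
    m = len(free)
    total = 1 << m
    succ = np.empty(total, dtype=np.uint32)
    chunk = 1 << min(m, _CHUNK_BITS)
    for start in range(0, total, chunk):
        j = np.arange(start, min(start + chunk, total), dtype=np.uint32)
        env: dict[str, np.ndarray] = {}
        for k, node in enumerate(free):
            env[node] = ((j >> np.uint32(k)) & np.uint32(1)).astype(bool)
        for node, v in clamps.items():
            env[node] = np.bool_(v)
        out = np.zeros(j.shape, dtype=np.uint32)
        for k, node in enumerate(free):
            vals = np.broadcast_to(rs.rules[node].bulk(env), j.shape)
            out |= vals.astype(np.uint32) << np.uint32(k)
        succ[start:start + len(j)] = out
    return succ


def _expand_indices(rs: RuleSet, clamps: Mapping[str, int], free: list[str],
                    sub_values: Iterable[int]) -> list[int]:
    """Subspace indices -> full-network integer encodings."""
    base = 0
    for node, bit in clamps.items():
        if bit:
            base |= 1 << rs.index(node)
    pos = [rs.index(n) for n in free]
    out = []
    for j in sub_values:
        v = base
        for k, p in enumerate(pos):
            if (j >> k) & 1:
                v |= 1 << p
        out.append(v)
    return out


def _bulk_enumerate(rs: RuleSet, clamps: Mapping[str, int],
                    initial_fixed: Mapping[str, int],
                    max_bits: int) -> list[Attractor]:
    free = [n for n in rs.nodes if n not in clamps]
    m = len(free)
    if m > max_bits:
        raise StateSpaceTooLargeError(
            f"{m} free nodes -> 2^{m} states exceeds the exhaustive limit "
            f"(2^{max_bits}); pass an explicit initial_space instead")
    succ = _bulk_successors(rs, clamps, free)

    # succ^(2^m) by pointer doubling: every state lands on its cycle.
    g = succ
    for _ in range(m):
        g = g[g]

    # Initial subspace: all free-bit patterns consistent with initial_fixed
    # (clamped nodes are already projected away).
    fixed = {n: v for n, v in initial_fixed.items() if n in free}
    if fixed:
        rest = [k for k in range(m) if free[k] not in fixed]
        val = np.uint32(0)
        for k, node in enumerate(free):
            if fixed.get(node):
                val |= np.uint32(1 << k)
        i = np.arange(1 << len(rest), dtype=np.uint32)
        subset = np.full(i.shape, val, dtype=np.uint32)
        for t, k in enumerate(rest):
            subset |= ((i >> np.uint32(t)) & np.uint32(1)) << np.uint32(k)
        landing = g[subset]
    else:
        landing = g

    cycle_states = np.unique(landing)

    # Group cycle states into cycles by walking the successor map.
    seen: set[int] = set()
    cycles: list[list[int]] = []
    for c in cycle_states.tolist():
        if c in seen:
            continue
        cyc = [c]
        seen.add(c)
        x = int(succ[c])
        while x != c:
            cyc.append(x)
            seen.add(x)
            x = int(succ[x])
        cycles.append(cyc)

    # Basin sizes partition the initial subspace.
    reps = np.fromiter((min(cyc) for cyc in cycles), dtype=np.uint32,
                       count=len(cycles))
    order = np.argsort(reps, kind="stable")
    all_states = np.concatenate([np.asarray(cycles[int(q)], dtype=np.uint32)
                                 for q in order]) if cycles else np.empty(0, np.uint32)
    cid = np.concatenate([np.full(len(cycles[int(q)]), rank, dtype=np.int64)
                          for rank, q in enumerate(order)]) if cycles else np.empty(0, np.int64)
    sorter = np.argsort(all_states)
    pos = np.searchsorted(all_states[sorter], landing)
    basins = np.bincount(cid[sorter[pos]], minlength=len(cycles))

    out = []
    for rank, q in enumerate(order):
        cyc = cycles[int(q)]
        full = _expand_indices(rs, clamps, free, cyc)
        out.append(Attractor.from_cycle(rs.nodes, full, int(basins[rank])))
    out.sort(key=lambda a: a.state_values)
    return out


# ---------------------------------------------------------------------------
# Naive per-state enumeration (oracle engine)
# ---------------------------------------------------------------------------

def _naive_enumerate(rs: RuleSet, clamps: Mapping[str, int],
                     initial_values: Iterable[int]) -> list[Attractor]:
    state_aid: dict[int, int] = {}
    cycles: list[tuple[int, ...]] = []
    basins: dict[int, int] = {}

    for s0 in initial_values:
        x = _project(rs, s0, clamps)
        path: list[int] = []
        pos: dict[int, int] = {}
        while x not in state_aid and x not in pos:
            pos[x] = len(path)
            path.append(x)
            x = _step_int(rs, x, clamps)
        if x in state_aid:
            aid = state_aid[x]
        else:
            cyc = tuple(path[pos[x]:])
            aid = len(cycles)
            cycles.append(cyc)
            basins[aid] = 0
        for s in path:
            state_aid[s] = aid
        basins[aid] += 1

    atts = [Attractor.from_cycle(rs.nodes, cyc, basins[aid])
            for aid, cyc in enumerate(cycles)]
    atts.sort(key=lambda a: a.state_values)
    return atts


def enumerate_attractors(rs: RuleSet,
                         clamps: Mapping[str, int] | None = None,
                         initial_space: str | Iterable[StateLike] = "all",
                         method: str = "auto",
                         initial_fixed: Mapping[str, int] | None = None,
                         max_bits: int = MAX_EXHAUSTIVE_BITS) -> list[Attractor]:
    """Enumerate attractors reachable from an initial space, with basins.

    ``initial_space="all"`` means every assignment of the unclamped nodes
    (initial states conflicting with clamps are projected onto the clamps,
    so basin sizes partition the reduced space).  ``initial_fixed`` further
    fixes some nodes *at time zero only* (a damage pulse); the basins then
    partition that restricted slice.  An explicit iterable of states may be
    given instead.

    ``method`` is ``"bulk"``, ``"naive"`` or ``"auto"`` (bulk for the full
    space, naive for explicit lists).  Exhaustive enumeration refuses above
    2^``max_bits`` free states rather than silently subsampling.
    """
    clamps = _check_clamps(rs, clamps)
    initial_fixed = _check_clamps(rs, initial_fixed)

    explicit = not (isinstance(initial_space, str) and initial_space == "all")
    if isinstance(initial_space, str) and initial_space != "all":
        raise ValueError(f"unknown initial_space {initial_space!r}")
    if method not in ("auto", "bulk", "naive"):
        raise ValueError(f"unknown method {method!r}")

    if explicit:
        values = [int(rs.state(s)) for s in initial_space]
        if initial_fixed:
            values = [_project(rs, v, initial_fixed) for v in values]
        return _naive_enumerate(rs, clamps, values)

    free = [n for n in rs.nodes if n not in clamps]
    if method == "naive":
        m = len(free)
        if m > 20:
            raise StateSpaceTooLargeError(
                f"naive engine refuses 2^{m} initial states")
        base = _project(rs, 0, {**initial_fixed, **clamps})
        fixed_pos = [rs.index(n) for n in free if n in initial_fixed]
        loose = [rs.index(n) for n in free if n not in initial_fixed]
        values = []
        for i in range(1 << len(loose)):
            v = base
            for t, p in enumerate(loose):
                if (i >> t) & 1:
                    v |= 1 << p
            values.append(v)
        return _naive_enumerate(rs, clamps, values)
    return _bulk_enumerate(rs, clamps, initial_fixed, max_bits)


def attractor_table(attractors: Iterable[Attractor]) -> pd.DataFrame:
    """One row per attractor state: id, period, basin size, then node columns."""
    rows = []
    for aid, att in enumerate(attractors):
        for t, s in enumerate(att.states):
            rows.append({"attractor": aid, "period": att.period,
                         "basin_size": att.basin_size, "t": t, **s.as_dict()})
    return pd.DataFrame(rows)
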