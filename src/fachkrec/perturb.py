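"""Mutant and damage-exposure experiments: clamps, edge removals, screens.

Null and constitutive-activation mutants are modelled by clamping a node to
0 or 1 for the whole simulation.  Interaction removal substitutes the source
variable by the constant 0 inside the target's rule (activating occurrences
become inert, negated occurrences permissive) — the unique local operation
that expresses "this regulation is absent" without inventing new biology.

Damage exposure comes in two protocols: a *pulse* sets the damage node(s)
to 1 at the initial state only and lets the dynamics run free, a
*persistent* exposure clamps them at 1 throughout.  The canonical starting
condition is the all-OFF state plus the pulsed/clamped nodes — a quiescent
cell hit by damage; an ensemble mode over all initial states is also
available.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace

import pandas as pd

from .dynamics import Attractor, enumerate_attractors, trajectory
from .phenotype import PhenotypeCall, Signature, classify_attractor
from .rules import Const, RuleSet

__all__ = [
    "Perturbation",
    "Protocol",
    "EdgeNotPresentError",
    "knockout",
    "constitutive",
    "remove_interaction",
    "run_protocol",
    "double_mutant_screen",
]


class EdgeNotPresentError(ValueError):
    def __init__(self, source: str, target: str):
        super().__init__(f"{source!r} does not occur in the rule of {target!r}")


@dataclass(frozen=True)
class Perturbation:
    """A mutant condition: node clamps plus removed interactions."""

    clamps: dict[str, int] = field(default_factory=dict)
    removed_edges: frozenset[tuple[str, str]] = frozenset()
    label: str = "wild-type"

    def combine(self, other: "Perturbation") -> "Perturbation":
        overlap = set(self.clamps) & set(other.clamps)
        if overlap:
            raise ValueError(f"conflicting clamps for {sorted(overlap)}")
        return Perturbation({**self.clamps, **other.clamps},
                            self.removed_edges | other.removed_edges,
                            f"{self.label} + {other.label}")

    def apply(self, rs: RuleSet) -> RuleSet:
        """Return the rule set with this perturbation's edges removed.

        Clamps are not baked into the rules; they are handled by the
        dynamics engine."""
        for node in self.clamps:
            rs.index(node)  # validate
        # Group by target so several regulators of one node can be removed
        # together (sequential removal could constant-fold a rule and make a
        # later, originally present, edge look absent).
        by_target: dict[str, set[str]] = {}
        for source, target in self.removed_edges:
            by_target.setdefault(target, set()).add(source)
        for target in sorted(by_target):
            rule = rs.rules[target]
            missing = by_target[target] - rule.variables()
            if missing:
                raise EdgeNotPresentError(sorted(missing)[0], target)
            rs = rs.replace_rule(
                target, rule.substitute({s: Const(0) for s in by_target[target]}))
        return rs


WILD_TYPE = Perturbation()


def knockout(node: str) -> Perturbation:
    """Null mutant: the node is fixed at 0."""
    return Perturbation({node: 0}, label=f"{node}-KO")


def constitutive(node: str) -> Perturbation:
    """Constitutive-activation mutant: the node is fixed at 1.  For a damage
    node this is identical to persistent exposure."""
    return Perturbation({node: 1}, label=f"{node}-ON")


def remove_interaction(rs: RuleSet, source: str, target: str) -> RuleSet:
    """Delete the regulation of ``target`` by ``source``.

    Every occurrence of ``source`` inside ``target``'s rule is replaced by
    the constant 0 (then constant-folded); no other rule changes."""
    rs.index(source)
    rs.index(target)
    rule = rs.rules[target]
    if source not in rule.variables():
        raise EdgeNotPresentError(source, target)
    return rs.replace_rule(target, rule.substitute({source: Const(0)}))


@dataclass(frozen=True)
class Protocol:
    """A damage-exposure protocol.

    ``exposure`` is ``"pulse"`` (damage nodes ON at t=0 only),
    ``"persistent"`` (damage nodes clamped ON) or ``"none"``.
    ``initial`` is ``"canonical"`` (all nodes OFF except the damage nodes —
    a single trajectory) or ``"all"`` (exhaustive over every initial
    assignment of the remaining nodes).
    """

    exposure: str = "pulse"
    damage_nodes: tuple[str, ...] = ("ICL",)
    initial: str = "canonical"

    def __post_init__(self):
        if self.exposure not in ("pulse", "persistent", "none"):
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.initial not in ("canonical", "all"):
            raise ValueError(f"unknown initial condition spec {self.initial!r}")


PULSE = Protocol("pulse")
PERSISTENT = Protocol("persistent")


def run_protocol(rs: RuleSet, perturbation: Perturbation = WILD_TYPE,
                 protocol: Protocol = PULSE,
                 signature: Signature | None = None,
                 ) -> list[tuple[Attractor, PhenotypeCall]]:
    """Simulate a mutant condition under a damage protocol.

    Returns the reached attractors with phenotype calls (one attractor for
    the canonical start; the full reachable set with basin sizes in
    ensemble mode).  Clamps always win over the initial condition: a pulsed
    node that is also clamped follows its clamp.
    """
    rs2 = perturbation.apply(rs)
    clamps = dict(perturbation.clamps)
    damage_on = {n: 1 for n in protocol.damage_nodes}
    if protocol.exposure == "persistent":
        for node, bit in damage_on.items():
            clamps.setdefault(node, bit)
        initial_fixed = {}
    elif protocol.exposure == "pulse":
        initial_fixed = damage_on
    else:
        initial_fixed = {}

    if protocol.initial == "canonical":
        start = {**initial_fixed, **{n: 1 for n, v in clamps.items() if v}}
        traj = trajectory(rs2, rs2.state(start), clamps)
        attractors = [traj.attractor]
    else:
        attractors = enumerate_attractors(rs2, clamps,
                                          initial_fixed=initial_fixed)
    return [(att, classify_attractor(att, signature)) for att in attractors]


def double_mutant_screen(rs: RuleSet, background: Perturbation,
                         candidates: Sequence[str],
                         protocol: Protocol = PERSISTENT,
                         signature: Signature | None = None) -> pd.DataFrame:
    """Knock out each candidate on top of a background perturbation.

    Every candidate is run (none skipped); candidates clashing with a
    background clamp raise before anything runs.  Returns one row per
    (candidate, attractor): candidate, attractor id, period, basin size,
    phenotype category and the evidence bits.  Output is independent of
    candidate order up to row order.
    """
    overlap = set(candidates) & set(background.clamps)
    if overlap:
        raise ValueError(
            f"candidate(s) {sorted(overlap)} already clamped in background "
            f"{background.label!r}")
    for c in candidates:
        rs.index(c)

    rows = []
    for candidate in candidates:
        pert = background.combine(knockout(candidate))
        for aid, (att, call) in enumerate(run_protocol(rs, pert, protocol,
                                                       signature)):
            rows.append({"candidate": candidate, "attractor": aid,
                         "period": att.period, "basin_size": att.basin_size,
                         "category": call.category, **call.evidence,
                         "on_nodes": "|".join(
                             n for n in att.nodes if att.ever_on(n))})
    return pd.DataFrame(rows)


def remove_novel_interactions(rs: RuleSet,
                              edges: Iterable[tuple[str, str]] | None = None
                              ) -> RuleSet:
    """Strip the configured inferred-interaction set from the model."""
    if edges is None:
        from .model import novel_interactions
        edges = [(e.source, e.target) for e in novel_interactions()]
    pert = Perturbation(removed_edges=frozenset(edges),
                        label="novel-interactions-removed")
    return pert.apply(rs)
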