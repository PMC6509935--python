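"""Reproducible random Boolean networks (testing/oracle fixtures).

Each node gets ``k`` distinct regulators chosen uniformly and a uniform
random truth table over them, rendered as a disjunctive normal form.  The
same spec and seed always produce the identical rule set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rules import And, BoolExpr, Const, Not, Or, RuleSet, Var

__all__ = ["RandomNetworkSpec", "generate_random_network", "expression_from_table"]


@dataclass(frozen=True)
class RandomNetworkSpec:
    n: int
    k: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one node")
        if not 0 <= self.k <= self.n:
            raise ValueError("in-degree k must be in [0, n]")


def expression_from_table(regs: tuple[str, ...], table) -> BoolExpr:
    """DNF expression whose truth table over ``regs`` (bit j = regs[j]) is
    ``table``."""
    table = np.asarray(table, dtype=bool)
    if len(table) != 1 << len(regs):
        raise ValueError("table length must be 2^len(regs)")
    if table.all():
        return Const(1)
    if not table.any():
        return Const(0)
    terms = []
    for i in np.nonzero(table)[0]:
        lits = [Var(r) if (int(i) >> j) & 1 else Not(Var(r))
                for j, r in enumerate(regs)]
        terms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def generate_random_network(spec: RandomNetworkSpec) -> RuleSet:
    rng = np.random.default_rng(spec.seed)
    nodes = tuple(f"N{i:02d}" for i in range(spec.n))
    rules = {}
    for node in nodes:
        regs = tuple(sorted(rng.choice(spec.n, size=spec.k, replace=False)))
        reg_names = tuple(nodes[r] for r in regs)
        table = rng.integers(0, 2, size=1 << spec.k).astype(bool)
        rules[node] = expression_from_table(reg_names, table)
    return RuleSet(nodes, rules)
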