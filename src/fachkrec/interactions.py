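"""Signed regulatory graph derived from the Boolean rules.

An edge ``u -> v`` exists iff ``u`` is *semantically* a regulator of ``v``:
there is at least one assignment of ``v``'s other regulators (a witness
context) in which flipping ``u`` from 0 to 1 changes ``v``'s update value.
The edge is positive if some witness raises the output, negative if some
witness lowers it, and dual if both kinds exist.  Literals that occur in a
rule's text but never change its output (inert literals) are excluded from
the edge list and reported separately — syntactic occurrence counts would
otherwise inflate edge statistics.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rules import RuleSet, truth_table

__all__ = [
    "SignedEdge",
    "derive_signed_edges",
    "inert_literals",
    "edge_summary",
    "verify_witness",
    "to_networkx",
    "to_sif",
]

MAX_RULE_REGULATORS = 16


@dataclass(frozen=True)
class SignedEdge:
    """A witnessed regulatory interaction.

    ``positive_witness`` / ``negative_witness`` assign every regulator of the
    target except the source; flipping the source 0 -> 1 under that context
    raises (resp. lowers) the target's update value.
    """

    source: str
    target: str
    sign: str  # "positive" | "negative" | "dual"
    positive_witness: dict[str, int] | None = None
    negative_witness: dict[str, int] | None = None


def _rule_analysis(rs: RuleSet, target: str):
    rule = rs.rules[target]
    regs = tuple(sorted(rule.variables()))
    if len(regs) > MAX_RULE_REGULATORS:
        raise ValueError(
            f"rule for {target!r} references {len(regs)} variables; "
            f"context enumeration above {MAX_RULE_REGULATORS} is refused")
    table = truth_table(rule, regs)
    return rule, regs, table


def _witnesses(regs, table, u):
    """Witness contexts for source u over a rule's truth table."""
    j = regs.index(u)
    idx = np.arange(len(table), dtype=np.uint32)
    low = idx[((idx >> j) & 1) == 0]
    f0 = table[low]
    f1 = table[low | (1 << j)]
    others = [r for r in regs if r != u]

    def ctx(i):
        return {r: int((i >> regs.index(r)) & 1) for r in others}

    pos = np.nonzero(f1 & ~f0)[0]
    neg = np.nonzero(~f1 & f0)[0]
    pos_w = ctx(int(low[pos[0]])) if len(pos) else None
    neg_w = ctx(int(low[neg[0]])) if len(neg) else None
    return pos_w, neg_w


def derive_signed_edges(rs: RuleSet) -> list[SignedEdge]:
    """All witnessed edges of the rule set, in (target, source) order."""
    edges: list[SignedEdge] = []
    for target in rs.nodes:
        _, regs, table = _rule_analysis(rs, target)
        for u in regs:
            pos_w, neg_w = _witnesses(regs, table, u)
            if pos_w is None and neg_w is None:
                continue
            sign = ("dual" if pos_w is not None and neg_w is not None
                    else "positive" if pos_w is not None else "negative")
            edges.append(SignedEdge(u, target, sign, pos_w, neg_w))
    return edges


def inert_literals(rs: RuleSet) -> list[tuple[str, str]]:
    """(source, target) pairs that occur syntactically but never change the
    target's output."""
    out = []
    for target in rs.nodes:
        _, regs, table = _rule_analysis(rs, target)
        for u in regs:
            pos_w, neg_w = _witnesses(regs, table, u)
            if pos_w is None and neg_w is None:
                out.append((u, target))
    return out


def verify_witness(rs: RuleSet, edge: SignedEdge) -> bool:
    """Re-evaluate the stored witnesses under the rules.  True iff every
    stored witness exhibits the claimed output change."""
    rule = rs.rules[edge.target]
    ok = True
    for witness, raised in ((edge.positive_witness, True),
                            (edge.negative_witness, False)):
        if witness is None:
            continue
        env0 = {**witness, edge.source: 0}
        env1 = {**witness, edge.source: 1}
        v0, v1 = rule(env0), rule(env1)
        ok = ok and ((v0, v1) == ((0, 1) if raised else (1, 0)))
    return ok


def edge_summary(edges: Iterable[SignedEdge]) -> dict:
    """Counts (total, positive, negative, dual) and a per-node degree table.

    Dual edges are counted once in the total and reported in their own
    column, not split into a positive plus a negative edge.
    """
    edges = list(edges)
    counts = {"total": len(edges),
              "positive": sum(e.sign == "positive" for e in edges),
              "negative": sum(e.sign == "negative" for e in edges),
              "dual": sum(e.sign == "dual" for e in edges)}
    nodes = sorted({e.source for e in edges} | {e.target for e in edges})
    deg = pd.DataFrame(0, index=nodes,
                       columns=["out_positive", "out_negative", "out_dual",
                                "in_positive", "in_negative", "in_dual"])
    for e in edges:
        deg.loc[e.source, f"out_{e.sign}"] += 1
        deg.loc[e.target, f"in_{e.sign}"] += 1
    return {"counts": counts, "degrees": deg}


def to_networkx(edges: Iterable[SignedEdge]):
    import networkx as nx
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.source, e.target, sign=e.sign)
    return g


def to_sif(edges: Iterable[SignedEdge]) -> str:
    """Simple interaction format: ``source <sign> target`` per line."""
    return "\n".join(f"{e.source}\t{e.sign}\t{e.target}" for e in edges) + "\n"
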