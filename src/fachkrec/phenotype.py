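"""Attractor phenotype classification: CCP, CCP-DDA, CCA, OTHER.

Attractors are read as cell-fate decisions from the activity of three
signature node sets:

* division drivers — CDK1-AurA, PLK1, CDC25, CycB-CDK1;
* damage nodes — ICL, DSB, R-DSB;
* arrest nodes — ATM, ATR, p53, p21, WEE1, MYT1.

A node counts as *active* in a cyclic attractor if it is ON in at least one
cycle state (arrest attractors show recurrent, not constant, activation).
The decision rule is ordered, because strict cell-cycle progression (CCP)
is a special case of progression with damage adaptation (CCP-DDA):

1. **CCP** — in every cycle state all four division drivers are ON and every
   other node is OFF;
2. **CCP_DDA** — CycB-CDK1 active and at least one damage node active
   (division despite unrepaired damage);
3. **CCA** — CycB-CDK1 OFF in all states, at least one damage node active
   and at least one arrest node active (checkpoint-imposed arrest);
4. **OTHER** — anything else.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from . import model as _model
from .dynamics import Attractor

__all__ = [
    "CATEGORIES",
    "PhenotypeCall",
    "Signature",
    "classify_attractor",
    "classify_all",
]

CATEGORIES = ("CCP", "CCP_DDA", "CCA", "OTHER")


@dataclass(frozen=True)
class Signature:
    """The node sets that define the phenotype signatures."""

    division: tuple[str, ...] = _model.DIVISION_NODES
    damage: tuple[str, ...] = _model.DAMAGE_NODES
    arrest: tuple[str, ...] = _model.ARREST_NODES

    @classmethod
    def from_categories(cls, categories: Mapping[str, str]) -> "Signature":
        """Build a signature from a node -> functional-category map.

        Division drivers are the CHKREC nodes minus WIP1 (a phosphatase, not
        a mitosis driver); arrest nodes are the checkpoint nodes minus
        PP2A-B55 (checkpoint-supporting but not an arrest effector).
        """
        division = tuple(n for n, c in categories.items()
                         if c == "CHKREC" and n != "WIP1")
        damage = tuple(n for n, c in categories.items() if c == "DNA_damage")
        arrest = tuple(n for n, c in categories.items()
                       if c == "checkpoint" and n != "PP2A-B55")
        return cls(division, damage, arrest)

    def check(self, att: Attractor) -> None:
        missing = [n for n in (*self.division, *self.damage, *self.arrest)
                   if n not in att.nodes]
        if missing:
            raise KeyError(f"signature node(s) absent from model: {missing}")


DEFAULT_SIGNATURE = Signature()

_CYCB = "CycB-CDK1"


@dataclass(frozen=True)
class PhenotypeCall:
    """Category plus the per-criterion evidence it was derived from."""

    category: str
    evidence: dict[str, bool]

    def __str__(self):
        return self.category


def classify_attractor(att: Attractor,
                       signature: Signature | Mapping[str, str] | None = None
                       ) -> PhenotypeCall:
    """Classify one attractor by the ordered decision rule above.

    ``signature`` may be a :class:`Signature` or a node -> category mapping;
    by default the built-in model's signature sets are used.
    """
    if signature is None:
        sig = DEFAULT_SIGNATURE
    elif isinstance(signature, Signature):
        sig = signature
    else:
        sig = Signature.from_categories(signature)
    sig.check(att)

    division_always_on = all(att.always_on(n) for n in sig.division)
    non_division = [n for n in att.nodes if n not in sig.division]
    others_always_off = not any(att.ever_on(n) for n in non_division)
    cycb = sig.division[-1] if _CYCB not in att.nodes else _CYCB
    cycb_ever_on = att.ever_on(cycb)
    damage_ever_on = any(att.ever_on(n) for n in sig.damage)
    arrest_ever_on = any(att.ever_on(n) for n in sig.arrest)

    evidence = {
        "division_always_on": division_always_on,
        "others_always_off": others_always_off,
        "cycb_ever_on": cycb_ever_on,
        "damage_ever_on": damage_ever_on,
        "arrest_ever_on": arrest_ever_on,
    }

    if division_always_on and others_always_off:
        category = "CCP"
    elif cycb_ever_on and damage_ever_on:
        category = "CCP_DDA"
    elif not cycb_ever_on and damage_ever_on and arrest_ever_on:
        category = "CCA"
    else:
        category = "OTHER"
    return PhenotypeCall(category, evidence)


def classify_all(attractors: Iterable[Attractor],
                 signature: Signature | Mapping[str, str] | None = None
                 ) -> pd.DataFrame:
    """Classify a list of attractors; returns a table in input order with a
    ``counts`` attribute (category -> number of attractors)."""
    rows = []
    for aid, att in enumerate(attractors):
        call = classify_attractor(att, signature)
        rows.append({"attractor": aid, "period": att.period,
                     "basin_size": att.basin_size, "category": call.category,
                     **call.evidence})
    table = pd.DataFrame(rows, columns=["attractor", "period", "basin_size",
                                        "category", "division_always_on",
                                        "others_always_off", "cycb_ever_on",
                                        "damage_ever_on", "arrest_ever_on"])
    counts = {c: 0 for c in CATEGORIES}
    for row in rows:
        counts[row["category"]] += 1
    table.attrs["counts"] = counts
    return table
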