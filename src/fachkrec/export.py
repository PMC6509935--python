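"""Model export: BoolNet plain text and SBML-qual.

The SBML-qual writer emits a minimal level-3 version-1 qual document: one
qualitative species per node (max level 1) and one transition per node whose
single function term encodes the update rule as MathML, default term 0.
"""

from __future__ import annotations

from collections.abc import Mapping
from xml.sax.saxutils import escape

from .rules import And, BoolExpr, Const, Not, Or, RuleSet, Var, sanitize_name, serialize_rules

__all__ = ["to_boolnet", "to_sbml_qual"]


def to_boolnet(rs: RuleSet, name_map: Mapping[str, str] | None = None) -> str:
    """BoolNet plain text (``targets, factors`` header, ``& | !`` operators)."""
    return serialize_rules(rs, dialect="boolnet", name_map=name_map)


def _mathml(expr: BoolExpr, ids: Mapping[str, str], indent: int) -> str:
    pad = "  " * indent
    if isinstance(expr, Const):
        return f"{pad}<{'true' if expr.value else 'false'}/>\n"
    if isinstance(expr, Var):
        return (f"{pad}<apply>\n{pad}  <eq/>\n"
                f"{pad}  <ci> {escape(ids[expr.name])} </ci>\n"
                f"{pad}  <cn type=\"integer\">1</cn>\n{pad}</apply>\n")
    if isinstance(expr, Not):
        inner = _mathml(expr.arg, ids, indent + 2)
        return (f"{pad}<apply>\n{pad}  <not/>\n{inner}{pad}</apply>\n")
    op = "<and/>" if isinstance(expr, And) else "<or/>"
    inner = "".join(_mathml(a, ids, indent + 2) for a in expr.args)
    return f"{pad}<apply>\n{pad}  {op}\n{inner}{pad}</apply>\n"


def to_sbml_qual(rs: RuleSet, name_map: Mapping[str, str] | None = None,
                 model_id: str = "boolean_network") -> str:
    """Serialize the rule set as an SBML level 3 qual document."""
    nm = dict(name_map or {})
    ids = {n: nm.get(n, sanitize_name(n)) for n in rs.nodes}
    if len(set(ids.values())) != len(ids):
        raise ValueError("name map does not yield unique identifiers")

    out = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
        'xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1" '
        'level="3" version="1" qual:required="true">\n',
        f'  <model id="{escape(model_id)}">\n',
        '    <listOfCompartments>\n'
        '      <compartment id="cell" constant="true"/>\n'
        '    </listOfCompartments>\n',
        '    <qual:listOfQualitativeSpecies>\n',
    ]
    for node in rs.nodes:
        out.append(f'      <qual:qualitativeSpecies qual:id="{escape(ids[node])}" '
                   f'qual:compartment="cell" qual:constant="false" '
                   f'qual:maxLevel="1" qual:name="{escape(node)}"/>\n')
    out.append('    </qual:listOfQualitativeSpecies>\n')
    out.append('    <qual:listOfTransitions>\n')
    for node in rs.nodes:
        rule = rs.rules[node]
        out.append(f'      <qual:transition qual:id="tr_{escape(ids[node])}">\n')
        out.append('        <qual:listOfInputs>\n')
        for j, reg in enumerate(sorted(rule.variables())):
            out.append(f'          <qual:input qual:id="tr_{escape(ids[node])}_in_{j}" '
                       f'qual:qualitativeSpecies="{escape(ids[reg])}" '
                       f'qual:transitionEffect="none"/>\n')
        out.append('        </qual:listOfInputs>\n')
        out.append('        <qual:listOfOutputs>\n')
        out.append(f'          <qual:output qual:qualitativeSpecies="{escape(ids[node])}" '
                   f'qual:transitionEffect="assignmentLevel"/>\n')
        out.append('        </qual:listOfOutputs>\n')
        out.append('        <qual:listOfFunctionTerms>\n')
        out.append('          <qual:defaultTerm qual:resultLevel="0"/>\n')
        out.append('          <qual:functionTerm qual:resultLevel="1">\n')
        out.append('            <math xmlns="http://www.w3.org/1998/Math/MathML">\n')
        out.append(_mathml(rule, ids, 7))
        out.append('            </math>\n')
        out.append('          </qual:functionTerm>\n')
        out.append('        </qual:listOfFunctionTerms>\n')
        out.append('      </qual:transition>\n')
    out.append('    </qual:listOfTransitions>\n  </model>\n</sbml>\n')
    return "".join(out)
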