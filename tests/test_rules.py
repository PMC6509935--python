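"""Expression parsing, evaluation, serialization and their invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fachkrec.rules import (And, Const, DuplicateTargetError, NetworkState, Not,
                            Or, RuleSyntaxError, UndeclaredVariableError, Var,
                            parse_expression, parse_rules, semantically_equal,
                            serialize_rules, truth_table)

# ---------------------------------------------------------------------------
# Parsing and evaluation
# ---------------------------------------------------------------------------

def test_single_rule_parses_and_evaluates():
    rs = parse_rules("p21 <- p53\np53 <- p53\n")
    assert rs.rules["p21"]({"p53": 1}) == 1
    assert rs.rules["p21"]({"p53": 0}) == 0


def test_identity_rule_is_identity():
    rs = parse_rules("A <- A")
    assert rs.rules["A"]({"A": 0}) == 0
    assert rs.rules["A"]({"A": 1}) == 1


def test_parsed_expression_matches_bruteforce_truth_table():
    # independent oracle: evaluate ¬(A∧B)∨C by direct Python logic
    expr = parse_expression("!(A & B) | C", dialect="boolnet")
    for a, b, c in itertools.product((0, 1), repeat=3):
        expected = int((not (a and b)) or c)
        assert expr({"A": a, "B": b, "C": c}) == expected


@pytest.mark.parametrize("dialect,text", [
    ("unicode", "A ∨ B ∧ C"),
    ("boolnet", "A | B & C"),
])
def test_and_binds_tighter_than_or(dialect, text):
    grouped = {"unicode": "A ∨ (B ∧ C)", "boolnet": "A | (B & C)"}[dialect]
    assert semantically_equal(parse_expression(text, dialect),
                              parse_expression(grouped, dialect))


def test_not_binds_tighter_than_and():
    assert semantically_equal(parse_expression("¬A ∧ B"),
                              parse_expression("(¬A) ∧ B"))
    assert not semantically_equal(parse_expression("¬A ∧ B"),
                                  parse_expression("¬(A ∧ B)"))


def test_constant_expressions():
    assert parse_expression("1")({}) == 1
    assert parse_expression("A ∧ 0")({"A": 1}) == 0


def test_hyphenated_names_in_unicode_dialect():
    expr = parse_expression("KU-53BP1 ∧ ¬PARP-1")
    assert expr.variables() == {"KU-53BP1", "PARP-1"}


@pytest.mark.parametrize("bad,exc", [
    ("A <- B &", RuleSyntaxError),
    ("A <- (B", RuleSyntaxError),
    ("A B", RuleSyntaxError),
    ("A <- ∧B", RuleSyntaxError),
])
def test_syntax_errors_carry_line_numbers(bad, exc):
    text = "X <- X\n" + bad + "\n"
    with pytest.raises(exc) as e:
        parse_rules(text)
    assert "line 2" in str(e.value)


def test_undeclared_variables_are_listed():
    with pytest.raises(UndeclaredVariableError) as e:
        parse_rules("A <- B ∧ C\n")
    assert e.value.names == ["B", "C"]


def test_duplicate_target_rejected():
    with pytest.raises(DuplicateTargetError):
        parse_rules("A <- A\nA <- ¬A\n")


# ---------------------------------------------------------------------------
# Serialization round-trips
# ---------------------------------------------------------------------------

_names = ("A", "B", "C", "D", "E", "F", "G", "H")


def exprs(depth):
    """Hypothesis strategy for expression trees (depth ≤ 6, ≤ 8 variables)."""
    leaf = st.one_of(st.sampled_from([Var(n) for n in _names]),
                     st.builds(Const, st.integers(0, 1)))
    if depth == 0:
        return leaf
    sub = exprs(depth - 1)
    return st.one_of(
        leaf,
        st.builds(Not, sub),
        st.builds(lambda a, b: And((a, b)), sub, sub),
        st.builds(lambda a, b: Or((a, b)), sub, sub),
    )


@given(exprs(6), st.sampled_from(["unicode", "boolnet"]))
def test_serializer_parser_roundtrip_is_semantic_identity(expr, dialect):
    text = expr.to_text(dialect)
    back = parse_expression(text, dialect)
    assert semantically_equal(expr, back)


def test_rule_file_roundtrip_with_name_map():
    rs = parse_rules("PARP-1 <- PARP-1 ∧ ¬R-DSB\nR-DSB <- PARP-1\n")
    nm = {"PARP-1": "PARP1", "R-DSB": "RDSB"}
    text = serialize_rules(rs, "boolnet", nm)
    assert "PARP1, PARP1 & !RDSB" in text
    back = parse_rules(text, "boolnet",
                       name_map={safe: canon for canon, safe in nm.items()})
    assert back.nodes == rs.nodes
    for node in rs.nodes:
        assert semantically_equal(back.rules[node], rs.rules[node])


def test_boolnet_serialization_sanitizes_unmapped_names():
    rs = parse_rules("PARP-1 <- PARP-1\n")
    text = serialize_rules(rs, "boolnet")
    assert "PARP_1" in text and "PARP-1" not in text


# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------

@given(st.integers(0, 2**8 - 1))
def test_state_encoding_roundtrips(value):
    rs = parse_rules("\n".join(f"N{i} <- N{i}" for i in range(8)))
    state = rs.state(value)
    assert rs.encode(state.as_dict()) == value
    assert rs.state(state.as_dict()) == state
    assert int(NetworkState(rs.nodes, value)) == value


def test_truth_table_semantics():
    expr = parse_expression("A ∧ ¬B")
    # variable order sorted: (A, B); index bit0=A, bit1=B
    assert truth_table(expr).tolist() == [False, True, False, False]
    assert np.array_equal(truth_table(Const(1), ("A",)), [True, True])
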