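"""Boolean update rules: expression trees, parsing, evaluation, serialization.

A Boolean network is a set of nodes, each updated by a logic function of
other nodes.  Rules are plain expression trees over variable references,
negation (``¬``/``!``), conjunction (``∧``/``&``), disjunction (``∨``/``|``)
and the constants 0/1.  Two text dialects are supported:

* ``unicode`` — one rule per line, ``target <- expression`` (``←`` also
  accepted), operators ``∧ ∨ ¬``.  Node names may contain hyphens
  (``KU-53BP1``, ``CycB-CDK1``).
* ``boolnet`` — the BoolNet plain-text format: an optional
  ``targets, factors`` header, then ``target, expression`` lines with
  operators ``& | !``.  Names must be identifier-safe; a bidirectional
  name map translates hyphenated canonical names.

Operator precedence is ``¬`` > ``∧`` > ``∨``; parentheses override.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "BoolExpr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "RuleSet",
    "NetworkState",
    "RuleSyntaxError",
    "UndeclaredVariableError",
    "DuplicateTargetError",
    "parse_expression",
    "parse_rules",
    "serialize_rules",
    "truth_table",
    "semantically_equal",
    "sanitize_name",
]


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


class UndeclaredVariableError(ValueError):
    """A rule references variables that are not declared nodes."""

    def __init__(self, names: Iterable[str]):
        self.names = sorted(set(names))
        super().__init__("undeclared variable(s): " + ", ".join(self.names))


class DuplicateTargetError(ValueError):
    def __init__(self, name: str, line: int | None = None):
        self.name = name
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(f"{prefix}duplicate rule for node {name!r}")


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------

DIALECTS = ("unicode", "boolnet")

_OPS = {
    "unicode": {"not": "¬", "and": "∧", "or": "∨"},
    "boolnet": {"not": "!", "and": "&", "or": "|"},
}


class BoolExpr:
    """Base class for Boolean expression trees.

    Expressions are immutable and hashable.  ``expr(env)`` evaluates against
    a mapping ``name -> 0/1``; :meth:`bulk` evaluates against a mapping of
    numpy boolean arrays (vectorized over many states at once).
    """

    __slots__ = ()

    def __call__(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def bulk(self, env: Mapping[str, np.ndarray]):
        """Vectorized evaluation; ``env`` maps names to bool arrays."""
        raise NotImplementedError

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def substitute(self, mapping: Mapping[str, "BoolExpr"]) -> "BoolExpr":
        """Replace variable references; the result is constant-folded."""
        raise NotImplementedError

    def to_text(self, dialect: str = "unicode",
                name_map: Mapping[str, str] | None = None) -> str:
        return self._fmt(_OPS[dialect], name_map or {}, 0)

    def _fmt(self, ops, name_map, parent_level) -> str:
        raise NotImplementedError

    def __repr__(self):
        return f"{type(self).__name__}({self.to_text()!r})"


@dataclass(frozen=True, slots=True)
class Const(BoolExpr):
    value: int

    def __call__(self, env):
        return self.value

    def bulk(self, env):
        return np.bool_(self.value)

    def variables(self):
        return frozenset()

    def substitute(self, mapping):
        return self

    def _fmt(self, ops, name_map, parent_level):
        return str(self.value)


@dataclass(frozen=True, slots=True)
class Var(BoolExpr):
    name: str

    def __call__(self, env):
        try:
            return int(env[self.name])
        except KeyError:
            raise KeyError(f"state does not assign variable {self.name!r}") from None

    def bulk(self, env):
        return env[self.name]

    def variables(self):
        return frozenset((self.name,))

    def substitute(self, mapping):
        return mapping.get(self.name, self)

    def _fmt(self, ops, name_map, parent_level):
        return name_map.get(self.name, self.name)


@dataclass(frozen=True, slots=True)
class Not(BoolExpr):
    arg: BoolExpr

    def __call__(self, env):
        return 1 - self.arg(env)

    def bulk(self, env):
        return ~self.arg.bulk(env)

    def variables(self):
        return self.arg.variables()

    def substitute(self, mapping):
        return _make_not(self.arg.substitute(mapping))

    def _fmt(self, ops, name_map, parent_level):
        # precedence level 3 (binds tightest)
        inner = self.arg._fmt(ops, name_map, 3)
        if isinstance(self.arg, (And, Or)):
            inner = f"({inner})"
        return ops["not"] + inner


@dataclass(frozen=True, slots=True)
class And(BoolExpr):
    args: tuple[BoolExpr, ...]

    def __call__(self, env):
        for a in self.args:
            if not a(env):
                return 0
        return 1

    def bulk(self, env):
        out = self.args[0].bulk(env)
        for a in self.args[1:]:
            out = out & a.bulk(env)
        return out

    def variables(self):
        return frozenset().union(*(a.variables() for a in self.args))

    def substitute(self, mapping):
        return _make_and([a.substitute(mapping) for a in self.args])

    def _fmt(self, ops, name_map, parent_level):
        s = f" {ops['and']} ".join(a._fmt(ops, name_map, 2) if not isinstance(a, Or)
                                   else f"({a._fmt(ops, name_map, 0)})"
                                   for a in self.args)
        return s


@dataclass(frozen=True, slots=True)
class Or(BoolExpr):
    args: tuple[BoolExpr, ...]

    def __call__(self, env):
        for a in self.args:
            if a(env):
                return 1
        return 0

    def bulk(self, env):
        out = self.args[0].bulk(env)
        for a in self.args[1:]:
            out = out | a.bulk(env)
        return out

    def variables(self):
        return frozenset().union(*(a.variables() for a in self.args))

    def substitute(self, mapping):
        return _make_or([a.substitute(mapping) for a in self.args])

    def _fmt(self, ops, name_map, parent_level):
        return f" {ops['or']} ".join(a._fmt(ops, name_map, 1) for a in self.args)


def _make_not(a: BoolExpr) -> BoolExpr:
    if isinstance(a, Const):
        return Const(1 - a.value)
    if isinstance(a, Not):
        return a.arg
    return Not(a)


def _make_and(parts: list[BoolExpr]) -> BoolExpr:
    flat: list[BoolExpr] = []
    for p in parts:
        if isinstance(p, Const):
            if p.value == 0:
                return Const(0)
            continue  # drop neutral 1
        if isinstance(p, And):
            flat.extend(p.args)
        else:
            flat.append(p)
    if not flat:
        return Const(1)
    if len(flat) == 1:
        return flat[0]
    return And(tuple(flat))


def _make_or(parts: list[BoolExpr]) -> BoolExpr:
    flat: list[BoolExpr] = []
    for p in parts:
        if isinstance(p, Const):
            if p.value == 1:
                return Const(1)
            continue
        if isinstance(p, Or):
            flat.extend(p.args)
        else:
            flat.append(p)
    if not flat:
        return Const(0)
    if len(flat) == 1:
        return flat[0]
    return Or(tuple(flat))


def truth_table(expr: BoolExpr, variables: tuple[str, ...] | None = None) -> np.ndarray:
    """Truth table of ``expr`` over ``variables`` (default: its own, sorted).

    Returns a bool array of length ``2**k``; entry ``i`` is the value in the
    context where variable ``j`` takes bit ``j`` of ``i``.
    """
    if variables is None:
        variables = tuple(sorted(expr.variables()))
    k = len(variables)
    if k > 20:
        raise ValueError(f"truth table over {k} variables is too large")
    idx = np.arange(1 << k, dtype=np.uint32)
    env = {v: ((idx >> j) & 1).astype(bool) for j, v in enumerate(variables)}
    out = expr.bulk(env)
    return np.broadcast_to(out, idx.shape).copy()


def semantically_equal(a: BoolExpr, b: BoolExpr) -> bool:
    """True iff the expressions agree on every assignment of their variables."""
    variables = tuple(sorted(a.variables() | b.variables()))
    return bool(np.array_equal(truth_table(a, variables), truth_table(b, variables)))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = {
    # hyphen allowed inside names; ¬ ∧ ∨ are the operators
    "unicode": re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<not>[¬~])"
                          r"|(?P<and>∧)|(?P<or>∨)|(?P<const>[01])(?![\w-])"
                          r"|(?P<name>[A-Za-z_][A-Za-z0-9_-]*))"),
    "boolnet": re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<not>!)"
                          r"|(?P<and>&)|(?P<or>\|)|(?P<const>[01])(?![\w])"
                          r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*))"),
}


def _tokenize(text: str, dialect: str, line: int | None):
    pat = _TOKEN_RE[dialect]
    pos, tokens = 0, []
    while pos < len(text):
        m = pat.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise RuleSyntaxError(f"unexpected character {rest[0]!r} in expression", line)
        pos = m.end()
        kind = m.lastgroup
        tokens.append((kind, m.group(kind)))
    tokens.append(("end", ""))
    return tokens


class _Parser:
    """Recursive-descent parser; precedence ¬ > ∧ > ∨."""

    def __init__(self, tokens, line=None):
        self.tokens = tokens
        self.i = 0
        self.line = line

    def peek(self):
        return self.tokens[self.i][0]

    def pop(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> BoolExpr:
        e = self.parse_or()
        if self.peek() != "end":
            raise RuleSyntaxError(f"unexpected token {self.tokens[self.i][1]!r}", self.line)
        return e

    def parse_or(self):
        parts = [self.parse_and()]
        while self.peek() == "or":
            self.pop()
            parts.append(self.parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and(self):
        parts = [self.parse_unary()]
        while self.peek() == "and":
            self.pop()
            parts.append(self.parse_unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_unary(self):
        kind, val = self.pop()
        if kind == "not":
            return Not(self.parse_unary())
        if kind == "lpar":
            e = self.parse_or()
            if self.pop()[0] != "rpar":
                raise RuleSyntaxError("missing closing parenthesis", self.line)
            return e
        if kind == "name":
            return Var(val)
        if kind == "const":
            return Const(int(val))
        raise RuleSyntaxError("expected a variable, constant, '(' or negation", self.line)


def parse_expression(text: str, dialect: str = "unicode",
                     line: int | None = None) -> BoolExpr:
    """Parse a single Boolean expression."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    return _Parser(_tokenize(text, dialect, line), line).parse()


_ARROW_RE = re.compile(r"\s*(<-|←)\s*")


def sanitize_name(name: str) -> str:
    """Identifier-safe fallback name (used when no explicit map entry exists)."""
    return re.sub(r"[^A-Za-z0-9_]", "_", name)


def parse_rules(text: str, dialect: str = "unicode",
                name_map: Mapping[str, str] | None = None) -> "RuleSet":
    """Parse a rule file into a :class:`RuleSet`.

    ``unicode`` dialect lines read ``target <- expression``; ``boolnet``
    lines read ``target, expression`` below an optional
    ``targets, factors`` header.  ``#`` starts a comment.  ``name_map``
    maps *file* names to canonical names (e.g. ``PARP1 -> PARP-1`` when
    reading BoolNet text written with the canonical-to-safe map).

    Every variable referenced by any rule must itself be a declared target;
    unknown names raise :class:`UndeclaredVariableError` listing them.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    rename = dict(name_map or {})

    nodes: list[str] = []
    rules: dict[str, BoolExpr] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.split("#", 1)[0].strip()
        if not stripped:
            continue
        if dialect == "boolnet":
            if stripped.lower().replace(" ", "") == "targets,factors":
                continue
            if "," not in stripped:
                raise RuleSyntaxError("expected 'target, expression'", lineno)
            target_raw, expr_text = stripped.split(",", 1)
        else:
            m = _ARROW_RE.search(stripped)
            if m is None:
                raise RuleSyntaxError("expected 'target <- expression'", lineno)
            target_raw, expr_text = stripped[:m.start()], stripped[m.end():]
        target = rename.get(target_raw.strip(), target_raw.strip())
        if not target:
            raise RuleSyntaxError("empty target name", lineno)
        if target in rules:
            raise DuplicateTargetError(target, lineno)
        expr = parse_expression(expr_text, dialect, lineno)
        if rename:
            expr = expr.substitute({old: Var(new) for old, new in rename.items()})
        nodes.append(target)
        rules[target] = expr

    rs = RuleSet(tuple(nodes), rules)
    unknown = rs.referenced_variables() - set(nodes)
    if unknown:
        raise UndeclaredVariableError(unknown)
    return rs


def serialize_rules(rs: "RuleSet", dialect: str = "unicode",
                    name_map: Mapping[str, str] | None = None) -> str:
    """Render a :class:`RuleSet` back to rule text.

    In the ``boolnet`` dialect every name must be identifier-safe; names are
    translated through ``name_map`` (canonical -> safe), falling back to
    :func:`sanitize_name` for any name the map omits.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    nm = dict(name_map or {})
    if dialect == "boolnet":
        for node in rs.nodes:
            if node not in nm and not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", node):
                nm[node] = sanitize_name(node)
        lines = ["targets, factors"]
        for node in rs.nodes:
            lines.append(f"{nm.get(node, node)}, "
                         f"{rs.rules[node].to_text('boolnet', nm)}")
    else:
        lines = [f"{nm.get(node, node)} <- {rs.rules[node].to_text('unicode', nm)}"
                 for node in rs.nodes]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Rule sets and network states
# ---------------------------------------------------------------------------

StateLike = Union["NetworkState", Mapping[str, int], int]


@dataclass(frozen=True)
class RuleSet:
    """An ordered set of nodes with one update rule per node.

    Node order is part of the contract: state integer encodings use bit ``i``
    for ``nodes[i]``.
    """

    nodes: tuple[str, ...]
    rules: dict[str, BoolExpr]
    metadata: dict[str, dict] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if set(self.nodes) != set(self.rules):
            raise ValueError("nodes and rules must cover the same names")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        try:
            return self.nodes.index(node)
        except ValueError:
            raise KeyError(f"unknown node {node!r}") from None

    def referenced_variables(self) -> set[str]:
        out: set[str] = set()
        for e in self.rules.values():
            out |= e.variables()
        return out

    # -- state plumbing ----------------------------------------------------
    def encode(self, assignment: Mapping[str, int]) -> int:
        value = 0
        for i, node in enumerate(self.nodes):
            if assignment.get(node, 0):
                value |= 1 << i
        return value

    def decode(self, value: int) -> dict[str, int]:
        return {node: (value >> i) & 1 for i, node in enumerate(self.nodes)}

    def state(self, spec: StateLike = 0) -> "NetworkState":
        """Coerce an int encoding or a partial mapping to a NetworkState."""
        if isinstance(spec, NetworkState):
            if spec.nodes != self.nodes:
                raise ValueError("state belongs to a different node order")
            return spec
        if isinstance(spec, int):
            if not 0 <= spec < (1 << self.n):
                raise ValueError(f"state integer out of range [0, 2^{self.n})")
            return NetworkState(self.nodes, spec)
        unknown = set(spec) - set(self.nodes)
        if unknown:
            raise KeyError(f"unknown node(s) in state: {sorted(unknown)}")
        return NetworkState(self.nodes, self.encode(spec))

    def replace_rule(self, node: str, expr: BoolExpr) -> "RuleSet":
        self.index(node)
        rules = dict(self.rules)
        rules[node] = expr
        return RuleSet(self.nodes, rules, dict(self.metadata))

    def content_hash(self) -> str:
        import hashlib
        text = serialize_rules(self, "unicode")
        return hashlib.sha256(text.encode()).hexdigest()[:16]


class NetworkState(Mapping):
    """One complete 0/1 assignment, stored as an integer over a node order.

    Bit ``i`` of :attr:`value` is the state of ``nodes[i]``; encoding and
    decoding round-trip exactly, and two states compare equal iff node order
    and all values agree.
    """

    __slots__ = ("nodes", "value")

    def __init__(self, nodes: tuple[str, ...], value: int):
        self.nodes = nodes
        self.value = value

    def __getitem__(self, node: str) -> int:
        try:
            i = self.nodes.index(node)
        except ValueError:
            raise KeyError(node) from None
        return (self.value >> i) & 1

    def __iter__(self):
        return iter(self.nodes)

    def __len__(self):
        return len(self.nodes)

    def __int__(self):
        return self.value

    def __hash__(self):
        return hash((self.nodes, self.value))

    def __eq__(self, other):
        if isinstance(other, NetworkState):
            return self.nodes == other.nodes and self.value == other.value
        return NotImplemented

    def as_dict(self) -> dict[str, int]:
        return {node: (self.value >> i) & 1 for i, node in enumerate(self.nodes)}

    def on_nodes(self) -> tuple[str, ...]:
        return tuple(n for i, n in enumerate(self.nodes) if (self.value >> i) & 1)

    def with_values(self, **values: int) -> "NetworkState":
        v = self.value
        for node, bit in values.items():
            i = self.nodes.index(node)
            v = (v | (1 << i)) if bit else (v & ~(1 << i))
        return NetworkState(self.nodes, v)

    def __repr__(self):
        on = ", ".join(self.on_nodes()) or "-"
        return f"<NetworkState {self.value} ON: {on}>"
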