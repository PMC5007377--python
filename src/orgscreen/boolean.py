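"""Boolean algebra over per-comparison differential calls.

The screen combines six pairwise organizer-vs-non-organizer comparisons
with a Boolean expression: a gene belongs to the organizer signature when
its pattern of significant enrichment (or, symmetrically, depletion)
satisfies the expression.  Leaves name comparisons; a leaf is true for a
gene exactly when that gene's call in the named comparison equals the
direction being evaluated ("enriched" or "depleted").  The same expression
therefore serves both directions — sign consistency across comparisons is
what makes the combination a synexpression criterion rather than a union
of hit lists.

Grammar::

    expr   := term ('OR' term)*
    term   := factor ('AND' factor)*
    factor := NAME | '(' expr ')'

AND binds tighter than OR; keywords are case-insensitive; NAME is
``[A-Za-z_][A-Za-z0-9_]*`` (comparison names such as ``C1``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Union

from .errors import OrgscreenError, ParseError

#: Direction labels of a per-comparison call.
CALL_ENRICHED = "enriched"
CALL_DEPLETED = "depleted"
CALL_NS = "ns"
CALLS = (CALL_ENRICHED, CALL_DEPLETED, CALL_NS)


@dataclass(frozen=True)
class Leaf:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple["BooleanExpr", ...]

    def __post_init__(self):
        if not self.children:
            raise OrgscreenError("AND node with no children")


@dataclass(frozen=True)
class Or:
    children: tuple["BooleanExpr", ...]

    def __post_init__(self):
        if not self.children:
            raise OrgscreenError("OR node with no children")


BooleanExpr = Union[Leaf, And, Or]

_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<name>[A-Za-z_][A-Za-z0-9_]*))")


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == m.start():
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ParseError(f"unexpected character {stripped[0]!r}", pos)
        if m.lastgroup == "name":
            word = m.group("name")
            kind = word.upper() if word.upper() in ("AND", "OR") else "name"
            yield kind, word, m.start("name")
        else:
            yield m.lastgroup, m.group(), m.start()
        pos = m.end()
    yield "end", "", len(text)


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.i = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def advance(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> BooleanExpr:
        node = self.expr()
        kind, value, pos = self.peek()
        if kind != "end":
            raise ParseError(f"unexpected token {value!r}", pos)
        return node

    def expr(self) -> BooleanExpr:
        terms = [self.term()]
        while self.peek()[0] == "OR":
            self.advance()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term(self) -> BooleanExpr:
        factors = [self.factor()]
        while self.peek()[0] == "AND":
            self.advance()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor(self) -> BooleanExpr:
        kind, value, pos = self.advance()
        if kind == "name":
            return Leaf(value)
        if kind == "lpar":
            node = self.expr()
            kind, value, pos = self.advance()
            if kind != "rpar":
                raise ParseError("unbalanced parentheses: expected ')'", pos)
            return node
        if kind == "rpar":
            raise ParseError("unbalanced parentheses: unexpected ')'", pos)
        if kind == "end":
            raise ParseError("unexpected end of expression", pos)
        raise ParseError(f"unexpected token {value!r}", pos)


def parse_expression(text: str) -> BooleanExpr:
    """Parse ``text`` into an AST; raises :class:`ParseError` with position."""
    if not text or not text.strip():
        raise ParseError("empty expression", 0)
    return _Parser(text).parse()


def to_text(expr: BooleanExpr) -> str:
    """Canonical fully parenthesized serialization (parses back to ``expr``)."""
    if isinstance(expr, Leaf):
        return expr.name
    op = " AND " if isinstance(expr, And) else " OR "
    return "(" + op.join(to_text(c) for c in expr.children) + ")"


def leaves(expr: BooleanExpr) -> set[str]:
    """Comparison names referenced by ``expr``."""
    if isinstance(expr, Leaf):
        return {expr.name}
    out: set[str] = set()
    for c in expr.children:
        out |= leaves(c)
    return out


def evaluate(expr: BooleanExpr, truth: Mapping[str, bool]) -> bool:
    """Evaluate with explicit per-leaf truth values."""
    if isinstance(expr, Leaf):
        try:
            return bool(truth[expr.name])
        except KeyError:
            raise OrgscreenError(f"no truth value for comparison {expr.name!r}") from None
    if isinstance(expr, And):
        return all(evaluate(c, truth) for c in expr.children)
    return any(evaluate(c, truth) for c in expr.children)


def evaluate_gene(
    expr: BooleanExpr,
    calls: Mapping[str, str],
    direction: str,
) -> bool:
    """Does a gene's call vector satisfy ``expr`` in the given direction?

    A leaf is true iff ``calls[name] == direction``; ``direction`` is
    ``"enriched"`` or ``"depleted"``.  Every leaf must have a call.
    """
    if direction not in (CALL_ENRICHED, CALL_DEPLETED):
        raise OrgscreenError(f"direction must be enriched/depleted, got {direction!r}")
    for name in leaves(expr):
        if name not in calls:
            raise OrgscreenError(f"missing call for comparison {name!r}")
    return evaluate(expr, {name: calls[name] == direction for name in leaves(expr)})
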