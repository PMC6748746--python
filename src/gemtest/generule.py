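"""Boolean gene-reaction rules (GPRs).

A rule is a boolean expression over gene identifiers with ``and`` / ``or``
connectives and parentheses, e.g. ``(g1 and g2) or g3``.  An empty rule
means the reaction is not gene-associated and is always available.

``not`` is deliberately rejected: negative gene associations have no
agreed semantics in constraint-based models, so accepting them silently
would invite incorrect knockout predictions.

The expression tree is stored in a small normalized form::

    None                      empty rule
    "g1"                      a single gene leaf
    ("and", (child, ...))     n-ary conjunction (children flattened)
    ("or",  (child, ...))     n-ary disjunction (children flattened)

Parsing then re-serializing is structurally lossless.
"""

from __future__ import annotations

import re
from typing import FrozenSet, Iterator, Optional, Set, Tuple, Union

from .errors import GeneRuleError

Expr = Union[None, str, Tuple[str, tuple]]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> Iterator[str]:
    for match in _TOKEN_RE.finditer(text):
        yield match.group(0)


class _Parser:
    """Recursive-descent parser; ``or`` has lowest precedence."""

    def __init__(self, tokens):
        self.tokens = list(tokens)
        self.pos = 0

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GeneRuleError("unexpected end of gene rule")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.expr()
        if self.peek() is not None:
            raise GeneRuleError(f"unexpected token {self.peek()!r} in gene rule")
        return expr

    def expr(self) -> Expr:
        children = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            children.append(self.term())
        return children[0] if len(children) == 1 else _flatten("or", children)

    def term(self) -> Expr:
        children = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            children.append(self.factor())
        return children[0] if len(children) == 1 else _flatten("and", children)

    def factor(self) -> Expr:
        tok = self.next()
        if tok == "(":
            inner = self.expr()
            if self.next() != ")":
                raise GeneRuleError("unbalanced parentheses in gene rule")
            return inner
        if tok == ")":
            raise GeneRuleError("unbalanced parentheses in gene rule")
        if tok.lower() in _KEYWORDS:
            raise GeneRuleError(f"misplaced connective {tok!r} in gene rule")
        if tok.lower() == "not":
            raise GeneRuleError(
                "'not' is not supported in gene rules; only AND/OR connectives "
                "over gene identifiers are accepted"
            )
        return tok


def _flatten(op: str, children) -> Expr:
    flat = []
    for child in children:
        if isinstance(child, tuple) and child[0] == op:
            flat.extend(child[1])
        else:
            flat.append(child)
    return (op, tuple(flat))


def _evaluate(expr: Expr, inactive: FrozenSet[str]) -> bool:
    if expr is None:
        return True
    if isinstance(expr, str):
        return expr not in inactive
    op, children = expr
    if op == "and":
        return all(_evaluate(c, inactive) for c in children)
    return any(_evaluate(c, inactive) for c in children)


def _genes(expr: Expr) -> Set[str]:
    if expr is None:
        return set()
    if isinstance(expr, str):
        return {expr}
    out: Set[str] = set()
    for child in expr[1]:
        out |= _genes(child)
    return out


def _to_string(expr: Expr, parent_op: Optional[str] = None) -> str:
    if expr is None:
        return ""
    if isinstance(expr, str):
        return expr
    op, children = expr
    joined = f" {op} ".join(_to_string(c, op) for c in children)
    # "and" binds tighter than "or"; an "or" nested under "and" needs parens.
    if parent_op == "and" and op == "or":
        return f"({joined})"
    return joined


class GeneRule:
    """Immutable gene-reaction rule.

    Parameters
    ----------
    expression
        The normalized expression tree; use :meth:`parse` to build one
        from a rule string.
    """

    __slots__ = ("expression",)

    def __init__(self, expression: Expr = None):
        object.__setattr__(self, "expression", expression)

    def __setattr__(self, *_):  # pragma: no cover - immutability guard
        raise AttributeError("GeneRule is immutable")

    @classmethod
    def parse(cls, text: str) -> "GeneRule":
        """Parse a rule string like ``"(g1 and g2) or g3"`` (case-insensitive
        connectives).  An empty/whitespace string yields the empty rule."""
        if text is None or not text.strip():
            return cls(None)
        return cls(_Parser(_tokenize(text)).parse())

    @property
    def is_empty(self) -> bool:
        return self.expression is None

    @property
    def genes(self) -> Set[str]:
        """Set of gene ids appearing in the rule."""
        return _genes(self.expression)

    def evaluate(self, inactive_genes=()) -> bool:
        """Evaluate with the given genes set false and all others true.

        Gene ids in ``inactive_genes`` that do not occur in the rule are
        ignored.  The empty rule always evaluates true.
        """
        return _evaluate(self.expression, frozenset(inactive_genes))

    def to_string(self) -> str:
        """Canonical rule string; parsing it back reproduces the tree."""
        return _to_string(self.expression)

    def __eq__(self, other):
        return isinstance(other, GeneRule) and self.expression == other.expression

    def __hash__(self):
        return hash(self.expression)

    def __repr__(self):
        return f"GeneRule({self.to_string()!r})"


EMPTY_RULE = GeneRule(None)
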