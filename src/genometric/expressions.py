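"""Predicate and arithmetic expression ASTs with an infix text surface.

Two evaluation modes share one syntax:

* metadata mode — comparisons between a key and a literal, combined with
  AND/OR/NOT.  A comparison is true iff *any* value of that key satisfies it;
  an absent key makes the comparison false.  Both sides are compared
  numerically when both parse as numbers; otherwise ``==``/``!=`` fall back to
  string comparison, while order operators raise an evaluation error naming
  the offending key and value.
* region mode — both sides may be arithmetic expressions over coordinates
  (``left``, ``right``), schema attributes and numeric constants.  A missing
  referenced value makes the enclosing comparison false.

Surface syntax example::

    cell == 'H1-hESC' AND NOT(audit_warning != '')
    right - left > 100
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .model import (
    EvaluationError,
    MetadataSet,
    Region,
    Schema,
    SchemaError,
    Value,
)

__all__ = [
    "Attr",
    "Const",
    "BinOp",
    "Comparison",
    "And",
    "Or",
    "Not",
    "parse_predicate",
    "parse_scalar_expr",
    "evaluate_meta_predicate",
    "evaluate_region_predicate",
    "evaluate_region_expr",
]

COMPARISON_OPS = ("==", "!=", "<=", ">=", "<", ">")
ORDER_OPS = ("<", "<=", ">", ">=")


# ---------------------------------------------------------------------------
# AST nodes


@dataclass(frozen=True)
class Attr:
    name: str


@dataclass(frozen=True)
class Const:
    value: Union[str, int, float]


@dataclass(frozen=True)
class BinOp:
    op: str  # + - * /
    left: "ScalarExpr"
    right: "ScalarExpr"


ScalarExpr = Union[Attr, Const, BinOp]


@dataclass(frozen=True)
class Comparison:
    left: ScalarExpr
    op: str
    right: ScalarExpr


@dataclass(frozen=True)
class And:
    left: "Predicate"
    right: "Predicate"


@dataclass(frozen=True)
class Or:
    left: "Predicate"
    right: "Predicate"


@dataclass(frozen=True)
class Not:
    operand: "Predicate"


Predicate = Union[Comparison, And, Or, Not]


# ---------------------------------------------------------------------------
# tokenizer / parser

_TOKEN_RE = re.compile(
    r"""\s*(?:
      (?P<number>\d+\.\d*|\.\d+|\d+)
    | (?P<string>'(?:[^'\\]|\\.)*')
    | (?P<op><=|>=|==|!=|<|>|\(|\)|\+|-|\*|/)
    | (?P<ident>[A-Za-z_][A-Za-z0-9_.]*)
    )""",
    re.VERBOSE,
)

_KEYWORDS = {"AND", "OR", "NOT", "and", "or", "not"}


def _tokenize(text: str) -> list:
    tokens = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            if text[pos:].strip() == "":
                break
            raise EvaluationError(f"cannot tokenize predicate at: {text[pos:]!r}")
        pos = match.end()
        if match.lastgroup == "number":
            raw = match.group("number")
            tokens.append(("number", float(raw) if "." in raw else int(raw)))
        elif match.lastgroup == "string":
            raw = match.group("string")[1:-1]
            tokens.append(("string", raw.replace("\\'", "'").replace("\\\\", "\\")))
        elif match.lastgroup == "op":
            tokens.append(("op", match.group("op")))
        else:
            ident = match.group("ident")
            if ident in _KEYWORDS:
                tokens.append(("kw", ident.upper()))
            else:
                tokens.append(("ident", ident))
    return tokens


class _Parser:
    """Recursive-descent parser with backtracking for parenthesized terms."""

    def __init__(self, tokens: list, source: str) -> None:
        self.tokens = tokens
        self.source = source
        self.pos = 0

    def peek(self) -> Optional[tuple]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple:
        tok = self.peek()
        if tok is None:
            raise EvaluationError(f"unexpected end of expression in {self.source!r}")
        self.pos += 1
        return tok

    def expect_op(self, op: str) -> None:
        tok = self.next()
        if tok != ("op", op):
            raise EvaluationError(f"expected {op!r} in {self.source!r}, got {tok!r}")

    # predicate grammar -----------------------------------------------------

    def predicate(self) -> Predicate:
        node = self.conjunction()
        while self.peek() == ("kw", "OR"):
            self.next()
            node = Or(node, self.conjunction())
        return node

    def conjunction(self) -> Predicate:
        node = self.negation()
        while self.peek() == ("kw", "AND"):
            self.next()
            node = And(node, self.negation())
        return node

    def negation(self) -> Predicate:
        if self.peek() == ("kw", "NOT"):
            self.next()
            return Not(self.negation())
        if self.peek() == ("op", "("):
            # Could be a parenthesized predicate or the lhs of a comparison:
            # try the comparison route first and backtrack on failure.
            saved = self.pos
            try:
                return self.comparison()
            except EvaluationError:
                self.pos = saved
            self.expect_op("(")
            node = self.predicate()
            self.expect_op(")")
            return node
        return self.comparison()

    def comparison(self) -> Comparison:
        left = self.arith()
        tok = self.next()
        if tok[0] != "op" or tok[1] not in COMPARISON_OPS:
            raise EvaluationError(
                f"expected comparison operator in {self.source!r}, got {tok!r}"
            )
        right = self.arith()
        return Comparison(left, tok[1], right)

    # arithmetic grammar ----------------------------------------------------

    def arith(self) -> ScalarExpr:
        node = self.term()
        while self.peek() in (("op", "+"), ("op", "-")):
            op = self.next()[1]
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> ScalarExpr:
        node = self.factor()
        while self.peek() in (("op", "*"), ("op", "/")):
            op = self.next()[1]
            node = BinOp(op, node, self.factor())
        return node

    def factor(self) -> ScalarExpr:
        tok = self.next()
        if tok[0] == "number":
            return Const(tok[1])
        if tok[0] == "string":
            return Const(tok[1])
        if tok[0] == "ident":
            return Attr(tok[1])
        if tok == ("op", "("):
            node = self.arith()
            self.expect_op(")")
            return node
        if tok == ("op", "-"):
            return BinOp("-", Const(0), self.factor())
        raise EvaluationError(f"unexpected token {tok!r} in {self.source!r}")


def parse_predicate(text: str) -> Predicate:
    """Parse an infix predicate; raises :class:`EvaluationError` on syntax errors."""
    parser = _Parser(_tokenize(text), text)
    node = parser.predicate()
    if parser.peek() is not None:
        raise EvaluationError(f"trailing input in predicate {text!r}")
    return node


def parse_scalar_expr(text: str) -> ScalarExpr:
    """Parse an arithmetic expression over attributes, coordinates, constants."""
    parser = _Parser(_tokenize(text), text)
    node = parser.arith()
    if parser.peek() is not None:
        raise EvaluationError(f"trailing input in expression {text!r}")
    return node


# ---------------------------------------------------------------------------
# evaluation


def _as_number(value: Value) -> Optional[float]:
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return None
    return None


def _compare(left: Value, op: str, right: Value, *, context: str) -> bool:
    ln, rn = _as_number(left), _as_number(right)
    if ln is not None and rn is not None:
        if op == "==":
            return ln == rn
        if op == "!=":
            return ln != rn
        if op == "<":
            return ln < rn
        if op == "<=":
            return ln <= rn
        if op == ">":
            return ln > rn
        if op == ">=":
            return ln >= rn
    if op == "==":
        return str(left) == str(right)
    if op == "!=":
        return str(left) != str(right)
    raise EvaluationError(f"order comparison on non-numeric value: {context}")


def evaluate_meta_predicate(pred: Predicate, metadata: MetadataSet) -> bool:
    """Evaluate a metadata-mode predicate with ANY-value semantics."""
    if isinstance(pred, And):
        return evaluate_meta_predicate(pred.left, metadata) and evaluate_meta_predicate(
            pred.right, metadata
        )
    if isinstance(pred, Or):
        return evaluate_meta_predicate(pred.left, metadata) or evaluate_meta_predicate(
            pred.right, metadata
        )
    if isinstance(pred, Not):
        return not evaluate_meta_predicate(pred.operand, metadata)
    if isinstance(pred, Comparison):
        if not isinstance(pred.left, Attr) or not isinstance(pred.right, Const):
            raise EvaluationError(
                "metadata predicates compare a key to a literal, "
                f"got {pred.left!r} {pred.op} {pred.right!r}"
            )
        key = pred.left.name
        values = metadata.values(key)
        if not values:
            return False
        result = False
        for value in values:
            if _compare(
                value, pred.op, pred.right.value, context=f"key={key!r} value={value!r}"
            ):
                result = True
        return result
    raise EvaluationError(f"not a predicate node: {pred!r}")


def evaluate_region_expr(expr: ScalarExpr, region: Region, schema: Schema) -> Value:
    """Evaluate an arithmetic expression on one region.

    Returns ``None`` when any referenced attribute value is missing.  An
    attribute name absent from both the coordinates and the schema raises
    :class:`SchemaError`.
    """
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Attr):
        name = expr.name
        if name == "left":
            return region.left
        if name == "right":
            return region.right
        if name == "chr":
            return region.chrom
        if name == "strand":
            return region.strand
        return region.values[schema.index(name)]
    if isinstance(expr, BinOp):
        left = evaluate_region_expr(expr.left, region, schema)
        right = evaluate_region_expr(expr.right, region, schema)
        if left is None or right is None:
            return None
        ln, rn = _as_number(left), _as_number(right)
        if ln is None or rn is None:
            raise EvaluationError(
                f"arithmetic on non-numeric operands {left!r} {expr.op} {right!r}"
            )
        if isinstance(left, str):
            left = ln
        if isinstance(right, str):
            right = rn
        if expr.op == "+":
            return left + right
        if expr.op == "-":
            return left - right
        if expr.op == "*":
            return left * right
        if expr.op == "/":
            if rn == 0:
                raise EvaluationError("division by zero in region expression")
            return left / right
    raise EvaluationError(f"not a scalar expression node: {expr!r}")


def evaluate_region_predicate(pred: Predicate, region: Region, schema: Schema) -> bool:
    """Evaluate a region-mode predicate; missing values make comparisons false."""
    if isinstance(pred, And):
        return evaluate_region_predicate(pred.left, region, schema) and (
            evaluate_region_predicate(pred.right, region, schema)
        )
    if isinstance(pred, Or):
        return evaluate_region_predicate(pred.left, region, schema) or (
            evaluate_region_predicate(pred.right, region, schema)
        )
    if isinstance(pred, Not):
        return not evaluate_region_predicate(pred.operand, region, schema)
    if isinstance(pred, Comparison):
        left = evaluate_region_expr(pred.left, region, schema)
        right = evaluate_region_expr(pred.right, region, schema)
        if left is None or right is None:
            return False
        return _compare(left, pred.op, right, context=f"{left!r} {pred.op} {right!r}")
    raise EvaluationError(f"not a predicate node: {pred!r}")


def predicate_keys(pred: Predicate) -> set:
    """Attribute/key names referenced by a predicate (for validation)."""
    if isinstance(pred, (And, Or)):
        return predicate_keys(pred.left) | predicate_keys(pred.right)
    if isinstance(pred, Not):
        return predicate_keys(pred.operand)
    if isinstance(pred, Comparison):
        return _expr_keys(pred.left) | _expr_keys(pred.right)
    return set()


def _expr_keys(expr: ScalarExpr) -> set:
    if isinstance(expr, Attr):
        return {expr.name}
    if isinstance(expr, BinOp):
        return _expr_keys(expr.left) | _expr_keys(expr.right)
    return set()
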