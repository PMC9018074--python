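"""Boolean rule expressions: AST, parser, evaluation and semantic analysis.

Rules are trees of binary AND/OR, unary NOT, node-name literals and the
constants 0/1.  Two surface spellings are accepted interchangeably:
the BoolNet style (``&``, ``|``, ``!``) and the MaBoSS style
(``AND``/``&&``, ``OR``/``||``, ``NOT``/``!``).  Node names are
case-sensitive identifiers; ``/``, ``-`` and ``_`` are permitted inside a
name (e.g. ``MYC_MAX``, ``MEK1_2``) so long as the name starts with a letter
or underscore.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "Expr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "RuleParseError",
    "parse_expression",
    "evaluate",
    "variables",
    "to_string",
    "truth_table",
    "regulator_signs",
    "count_binary_ops",
    "swap_binary_op",
    "expressions_equivalent",
]


class Expr:
    """Base class for rule expression nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Const(Expr):
    value: int  # 0 or 1


@dataclass(frozen=True)
class Var(Expr):
    name: str


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr


class RuleParseError(ValueError):
    """Raised on malformed rule text; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Tokenizer / parser
# ---------------------------------------------------------------------------

_KEYWORDS = {"AND": "&", "OR": "|", "NOT": "!"}

_NAME_START = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ_")
_NAME_BODY = _NAME_START | set("0123456789/-")


def _tokenize(text: str, line: int | None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, c))
            i += 1
        elif c == "!":
            tokens.append(("!", c))
            i += 1
        elif c == "&":
            i += 2 if text[i : i + 2] == "&&" else 1
            tokens.append(("&", "&"))
        elif c == "|":
            i += 2 if text[i : i + 2] == "||" else 1
            tokens.append(("|", "|"))
        elif c in "01" and (i + 1 == n or text[i + 1] not in _NAME_BODY):
            tokens.append(("const", c))
            i += 1
        elif c in _NAME_START:
            j = i + 1
            while j < n and text[j] in _NAME_BODY:
                j += 1
            word = text[i:j]
            if word in _KEYWORDS:
                tokens.append((_KEYWORDS[word], word))
            else:
                tokens.append(("name", word))
            i = j
        else:
            raise RuleParseError(f"unexpected character {c!r} in rule {text!r}", line)
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], text: str, line: int | None):
        self.tokens = tokens
        self.pos = 0
        self.text = text
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str]:
        if self.pos >= len(self.tokens):
            raise RuleParseError(f"unexpected end of rule {self.text!r}", self.line)
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.or_expr()
        if self.pos != len(self.tokens):
            kind, value = self.tokens[self.pos]
            raise RuleParseError(
                f"unexpected token {value!r} in rule {self.text!r}", self.line
            )
        return expr

    def or_expr(self) -> Expr:
        expr = self.and_expr()
        while self.peek() == "|":
            self.next()
            expr = Or(expr, self.and_expr())
        return expr

    def and_expr(self) -> Expr:
        expr = self.not_expr()
        while self.peek() == "&":
            self.next()
            expr = And(expr, self.not_expr())
        return expr

    def not_expr(self) -> Expr:
        if self.peek() == "!":
            self.next()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> Expr:
        kind, value = self.next()
        if kind == "name":
            return Var(value)
        if kind == "const":
            return Const(int(value))
        if kind == "(":
            expr = self.or_expr()
            kind, value = self.next()
            if kind != ")":
                raise RuleParseError(
                    f"expected ')' but found {value!r} in rule {self.text!r}", self.line
                )
            return expr
        raise RuleParseError(
            f"unexpected token {value!r} in rule {self.text!r}", self.line
        )


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a single rule expression.

    Parameters
    ----------
    text:
        Rule text in either the BoolNet or the MaBoSS spelling.
    line:
        Optional source line number, included in error messages.
    """
    tokens = _tokenize(text, line)
    if not tokens:
        raise RuleParseError(f"empty rule expression", line)
    return _Parser(tokens, text, line).parse()


# ---------------------------------------------------------------------------
# Evaluation and analysis
# ---------------------------------------------------------------------------


def evaluate(expr: Expr, state: Mapping[str, int]) -> int:
    """Evaluate ``expr`` on a complete binary state; returns 0 or 1."""
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Var):
        try:
            return int(state[expr.name])
        except KeyError:
            raise KeyError(f"unbound literal {expr.name!r} in rule") from None
    if isinstance(expr, Not):
        return 1 - evaluate(expr.operand, state)
    if isinstance(expr, And):
        return evaluate(expr.left, state) & evaluate(expr.right, state)
    if isinstance(expr, Or):
        return evaluate(expr.left, state) | evaluate(expr.right, state)
    raise TypeError(f"not an expression node: {expr!r}")


def variables(expr: Expr) -> list[str]:
    """Ordered unique list of node names occurring in ``expr``."""
    seen: dict[str, None] = {}

    def walk(e: Expr) -> None:
        if isinstance(e, Var):
            seen.setdefault(e.name, None)
        elif isinstance(e, Not):
            walk(e.operand)
        elif isinstance(e, (And, Or)):
            walk(e.left)
            walk(e.right)

    walk(expr)
    return list(seen)


def to_string(expr: Expr, dialect: str = "boolnet") -> str:
    """Serialise an expression; ``dialect`` is 'boolnet' or 'maboss'."""
    if dialect == "boolnet":
        sym_and, sym_or, sym_not = "&", "|", "!"
    elif dialect == "maboss":
        sym_and, sym_or, sym_not = "AND", "OR", "NOT "
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    def walk(e: Expr, parent: str) -> str:
        if isinstance(e, Const):
            return str(e.value)
        if isinstance(e, Var):
            return e.name
        if isinstance(e, Not):
            return f"{sym_not}{walk(e.operand, 'not')}"
        if isinstance(e, And):
            s = f"{walk(e.left, 'and')} {sym_and} {walk(e.right, 'atom')}"
            return f"({s})" if parent in ("not", "atom") else s
        if isinstance(e, Or):
            s = f"{walk(e.left, 'or')} {sym_or} {walk(e.right, 'atom')}"
            return f"({s})" if parent in ("not", "atom", "and") else s
        raise TypeError(f"not an expression node: {e!r}")

    return walk(expr, "top")


MAX_TRUTH_TABLE_REGULATORS = 20


def truth_table(expr: Expr, var_order: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Exhaustive truth table of ``expr``.

    Returns the variable order and a uint8 array of length ``2**k`` where
    the entry at index ``m`` is the rule value when variable ``i`` carries
    bit ``(m >> i) & 1``.
    """
    if var_order is None:
        var_order = variables(expr)
    k = len(var_order)
    if k > MAX_TRUTH_TABLE_REGULATORS:
        raise ValueError(
            f"rule has {k} regulators; truth-table analysis is capped at "
            f"{MAX_TRUTH_TABLE_REGULATORS}"
        )
    table = np.empty(2**k, dtype=np.uint8)
    state = dict.fromkeys(var_order, 0)
    for m in range(2**k):
        for i, name in enumerate(var_order):
            state[name] = (m >> i) & 1
        table[m] = evaluate(expr, state)
    return var_order, table


def regulator_signs(expr: Expr) -> dict[str, str]:
    """Semantic sign of each literal: 'activator', 'inhibitor' or 'dual'.

    A literal with no semantic effect (its flip never changes the rule value
    in any context) is omitted.  Signs are determined by exhaustive context
    enumeration over the rule's own literals.
    """
    names, table = truth_table(expr)
    signs: dict[str, str] = {}
    for i, name in enumerate(names):
        bit = 1 << i
        positive = negative = False
        for m in range(len(table)):
            if m & bit:
                continue
            lo, hi = table[m], table[m | bit]
            if hi > lo:
                positive = True
            elif hi < lo:
                negative = True
            if positive and negative:
                break
        if positive and negative:
            signs[name] = "dual"
        elif positive:
            signs[name] = "activator"
        elif negative:
            signs[name] = "inhibitor"
    return signs


def count_binary_ops(expr: Expr) -> int:
    """Number of binary AND/OR operators in the expression tree."""
    if isinstance(expr, (And, Or)):
        return 1 + count_binary_ops(expr.left) + count_binary_ops(expr.right)
    if isinstance(expr, Not):
        return count_binary_ops(expr.operand)
    return 0


def swap_binary_op(expr: Expr, index: int) -> Expr:
    """Return a copy of ``expr`` with its ``index``-th (pre-order) binary
    operator swapped AND<->OR.  ``index`` counts from 0."""
    counter = itertools.count()

    def walk(e: Expr) -> Expr:
        if isinstance(e, (And, Or)):
            my_index = next(counter)
            left, right = walk(e.left), walk(e.right)
            if my_index == index:
                return Or(left, right) if isinstance(e, And) else And(left, right)
            return type(e)(left, right)
        if isinstance(e, Not):
            return Not(walk(e.operand))
        return e

    result = walk(expr)
    total = next(counter)
    if index >= total or index < 0:
        raise IndexError(f"operator index {index} out of range (rule has {total})")
    return result


def expressions_equivalent(a: Expr, b: Expr) -> bool:
    """Truth-table equality over the union of both expressions' literals."""
    names = list(dict.fromkeys(variables(a) + variables(b)))
    _, ta = truth_table(a, names)
    _, tb = truth_table(b, names)
    return bool(np.array_equal(ta, tb))


def iter_states(names: list[str]) -> Iterator[dict[str, int]]:
    """All complete binary states over ``names`` (little-endian bit order)."""
    for m in range(2 ** len(names)):
        yield {name: (m >> i) & 1 for i, name in enumerate(names)}
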