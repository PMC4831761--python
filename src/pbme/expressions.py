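"""Arithmetic expressions used in process equations.

The expression language deliberately stays small: +, -, *, /, unary minus,
parentheses, decimal literals, bare identifiers (process constants) and dotted
``role.variable`` references. Expressions are parsed into a tiny immutable AST
that can be rendered back to text, symbol-substituted (role -> entity
instance), and converted to :mod:`sympy` for compilation into fast numeric
right-hand sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy


class ExpressionError(ValueError):
    pass


@dataclass(frozen=True)
class Num:
    value: float

    def __str__(self) -> str:
        v = self.value
        return repr(int(v)) if float(v).is_integer() else repr(v)


@dataclass(frozen=True)
class Const:
    """A bare identifier: a process constant."""

    name: str

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class VarRef:
    """A dotted reference ``role.variable``."""

    role: str
    variable: str

    def __str__(self) -> str:
        return f"{self.role}.{self.variable}"


@dataclass(frozen=True)
class Neg:
    operand: "Expr"

    def __str__(self) -> str:
        return f"-{_paren(self.operand, above=('+', '-'))}"


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * /
    left: "Expr"
    right: "Expr"

    def __str__(self) -> str:
        if self.op in "+-":
            return f"{self.left} {self.op} {_paren(self.right, above=('+', '-')) if self.op == '-' else self.right}"
        left = _paren(self.left, above=("+", "-"))
        right = _paren(self.right, above=("+", "-", "*", "/"))
        return f"{left} {self.op} {right}"


Expr = Num | Const | VarRef | Neg | BinOp


def _paren(e: Expr, above: tuple[str, ...]) -> str:
    if isinstance(e, BinOp) and e.op in above or isinstance(e, Neg):
        return f"({e})"
    return str(e)


def free_symbols(e: Expr) -> tuple[set[str], set[tuple[str, str]]]:
    """Return (constant names, (role, variable) references) used in *e*."""
    consts: set[str] = set()
    refs: set[tuple[str, str]] = set()

    def walk(node: Expr) -> None:
        if isinstance(node, Const):
            consts.add(node.name)
        elif isinstance(node, VarRef):
            refs.add((node.role, node.variable))
        elif isinstance(node, Neg):
            walk(node.operand)
        elif isinstance(node, BinOp):
            walk(node.left)
            walk(node.right)

    walk(e)
    return consts, refs


def to_sympy(
    e: Expr,
    const_map: dict[str, sympy.Symbol],
    ref_map: dict[tuple[str, str], sympy.Symbol],
) -> sympy.Expr:
    """Convert an AST to a sympy expression under the given symbol bindings."""
    if isinstance(e, Num):
        return sympy.Float(e.value) if not float(e.value).is_integer() else sympy.Integer(int(e.value))
    if isinstance(e, Const):
        try:
            return const_map[e.name]
        except KeyError:
            raise ExpressionError(f"unbound constant {e.name!r}") from None
    if isinstance(e, VarRef):
        try:
            return ref_map[(e.role, e.variable)]
        except KeyError:
            raise ExpressionError(f"unbound reference {e.role}.{e.variable}") from None
    if isinstance(e, Neg):
        return -to_sympy(e.operand, const_map, ref_map)
    if isinstance(e, BinOp):
        left = to_sympy(e.left, const_map, ref_map)
        right = to_sympy(e.right, const_map, ref_map)
        if e.op == "+":
            return left + right
        if e.op == "-":
            return left - right
        if e.op == "*":
            return left * right
        return left / right
    raise TypeError(f"not an expression node: {e!r}")
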