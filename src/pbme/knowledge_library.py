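"""Domain-knowledge libraries of template entities and template processes.

A library is the modeling-knowledge input of process-based modeling: template
entities declare system variables (with an aggregation function, unit and
admissible range) and constants; template processes declare the interactions
between entity roles, organized in a hierarchy in which an internal template
(e.g. ``Growth``) names a modeling choice and its leaf descendants
(e.g. ``ExponentialGrowth``, ``LogisticGrowth``) are the concrete
alternatives. Leaf templates carry ``td(...) = expression`` equations, the
additive contributions to the time derivatives of entity variables.

Libraries are written in a small plain-text DSL (suggested extension
``.pbl``)::

    template entity Population {
      vars: d {aggregation: sum, unit: "kg/m3", range: <0, 500>};
    }
    template process Growth(pop: Population) { consts: gR {range: <0, 5>}; }
    template process ExponentialGrowth : Growth {
      equations: td(pop.d) = gR * pop.d;
    }

`parse_library` parses and validates the text; `serialize_library` renders a
library back to canonical text such that parse-serialize-parse is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .expressions import BinOp, Const, Expr, Neg, Num, VarRef, free_symbols


class LibraryError(ValueError):
    """Validation error in a domain-knowledge library."""


class LibrarySyntaxError(LibraryError):
    """Syntax error, carrying 1-based line and column."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

AGGREGATIONS = ("sum",)


@dataclass(frozen=True)
class TemplateVariable:
    name: str
    aggregation: str = "sum"
    unit: str = ""
    range: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class ConstantSpec:
    name: str
    range: tuple[float, float]


@dataclass(frozen=True)
class TemplateEntity:
    name: str
    variables: tuple[TemplateVariable, ...] = ()
    constants: tuple[ConstantSpec, ...] = ()

    def variable(self, name: str) -> TemplateVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise LibraryError(f"entity {self.name!r} has no variable {name!r}")


@dataclass(frozen=True)
class Equation:
    """One additive contribution ``td(target) = expression``.

    ``target_role`` is the role whose variable the contribution feeds. When
    the written target names an undeclared role (Table-style shorthand such
    as ``td(pop.d)`` inside a process whose roles are ``pop1, pop2``), the
    i-th equation is resolved positionally to the i-th declared role; the
    written form is preserved for serialization.
    """

    target: VarRef
    expression: Expr
    target_role: str = ""

    @property
    def target_variable(self) -> str:
        return self.target.variable


@dataclass(frozen=True)
class TemplateProcess:
    name: str
    parent: str | None = None
    roles: tuple[tuple[str, str], ...] = ()  # (role name, entity template)
    constants: tuple[ConstantSpec, ...] = ()
    equations: tuple[Equation, ...] = ()


@dataclass(frozen=True)
class Library:
    entities: tuple[TemplateEntity, ...] = ()
    processes: tuple[TemplateProcess, ...] = ()

    # -- lookups ----------------------------------------------------------
    def entity(self, name: str) -> TemplateEntity:
        for e in self.entities:
            if e.name == name:
                return e
        raise LibraryError(f"unknown template entity {name!r}")

    def process(self, name: str) -> TemplateProcess:
        for p in self.processes:
            if p.name == name:
                return p
        raise LibraryError(f"unknown template process {name!r}")

    def has_process(self, name: str) -> bool:
        return any(p.name == name for p in self.processes)

    def children(self, name: str) -> tuple[TemplateProcess, ...]:
        return tuple(p for p in self.processes if p.parent == name)

    def is_leaf(self, name: str) -> bool:
        return not self.children(name)

    # -- inheritance ------------------------------------------------------
    def ancestors(self, name: str) -> tuple[TemplateProcess, ...]:
        """Chain from root to the named process, inclusive."""
        chain = [self.process(name)]
        while chain[0].parent is not None:
            chain.insert(0, self.process(chain[0].parent))
        return tuple(chain)

    def effective_roles(self, name: str) -> tuple[tuple[str, str], ...]:
        roles: list[tuple[str, str]] = []
        for p in self.ancestors(name):
            roles.extend(r for r in p.roles if r not in roles)
        return tuple(roles)

    def effective_constants(self, name: str) -> tuple[ConstantSpec, ...]:
        consts: list[ConstantSpec] = []
        for p in self.ancestors(name):
            consts.extend(c for c in p.constants if c.name not in {x.name for x in consts})
        return tuple(consts)


def leaf_alternatives(lib: Library, template: str) -> list[TemplateProcess]:
    """All leaf descendants of *template*, in declaration order.

    A leaf template is its own (single) alternative.
    """
    lib.process(template)  # raises on unknown name
    reachable = {template}
    changed = True
    while changed:
        changed = False
        for p in lib.processes:
            if p.parent in reachable and p.name not in reachable:
                reachable.add(p.name)
                changed = True
    return [p for p in lib.processes if p.name in reachable and lib.is_leaf(p.name)]


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+|\\\\[^\n]*|//[^\n]*|\#[^\n]*)
  | (?P<number>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?|\d+(?:[eE][+-]?\d+)?)
  | (?P<ident>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<string>"[^"\n]*")
  | (?P<sym>[{}()<>:;,.=+*/-])
    """,
    re.VERBOSE,
)

_UNICODE_FIXES = {"−": "-", "“": '"', "”": '"', "‘": "'", "’": "'"}


@dataclass(frozen=True)
class _Token:
    kind: str  # number | ident | string | sym | eof
    text: str
    line: int
    column: int


def _tokenize(text: str) -> list[_Token]:
    for bad, good in _UNICODE_FIXES.items():
        text = text.replace(bad, good)
    tokens: list[_Token] = []
    pos, line, col = 0, 1, 1
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise LibrarySyntaxError(f"unexpected character {text[pos]!r}", line, col)
        kind = m.lastgroup
        chunk = m.group()
        if kind != "ws":
            tokens.append(_Token(kind, chunk, line, col))
        nl = chunk.count("\n")
        if nl:
            line += nl
            col = len(chunk) - chunk.rfind("\n")
        else:
            col += len(chunk)
        pos = m.end()
    tokens.append(_Token("eof", "", line, col))
    return tokens


# ---------------------------------------------------------------------------
# parser
# ---------------------------------------------------------------------------


class _Parser:
    def __init__(self, text: str):
        self.tokens = _tokenize(text)
        self.i = 0

    # -- primitives -------------------------------------------------------
    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def error(self, msg: str) -> LibrarySyntaxError:
        t = self.cur
        shown = t.text or "end of input"
        return LibrarySyntaxError(f"{msg}, got {shown!r}", t.line, t.column)

    def accept(self, text: str) -> bool:
        if self.cur.text == text and self.cur.kind in ("sym", "ident"):
            self.i += 1
            return True
        return False

    def expect(self, text: str) -> _Token:
        if not (self.cur.text == text and self.cur.kind in ("sym", "ident")):
            raise self.error(f"expected {text!r}")
        tok = self.cur
        self.i += 1
        return tok

    def ident(self) -> str:
        if self.cur.kind != "ident":
            raise self.error("expected identifier")
        t = self.cur
        self.i += 1
        return t.text

    def number(self) -> float:
        sign = -1.0 if self.accept("-") else 1.0
        if self.cur.kind != "number":
            raise self.error("expected number")
        t = self.cur
        self.i += 1
        return sign * float(t.text)

    # -- grammar ----------------------------------------------------------
    def library(self) -> Library:
        if self.cur.kind == "eof":
            raise self.error("empty library")
        entities: list[TemplateEntity] = []
        processes: list[TemplateProcess] = []
        while self.cur.kind != "eof":
            self.expect("template")
            if self.accept("entity"):
                entities.append(self.entity_def())
            elif self.accept("process"):
                processes.append(self.process_def())
            else:
                raise self.error("expected 'entity' or 'process'")
            self.accept(";")
        return Library(entities=tuple(entities), processes=tuple(processes))

    def entity_def(self) -> TemplateEntity:
        name = self.ident()
        self.expect("{")
        variables: list[TemplateVariable] = []
        constants: list[ConstantSpec] = []
        while not self.accept("}"):
            if self.accept("vars"):
                self.expect(":")
                variables.extend(self._spec_list(self.var_spec))
            elif self.accept("consts"):
                self.expect(":")
                constants.extend(self._spec_list(self.const_spec))
            else:
                raise self.error("expected 'vars:' or 'consts:'")
        return TemplateEntity(name, tuple(variables), tuple(constants))

    def _spec_list(self, one):
        specs = [one()]
        while self.accept(","):
            specs.append(one())
        self.accept(";")
        return specs

    def var_spec(self) -> TemplateVariable:
        name = self.ident()
        aggregation, unit, rng = "sum", "", (0.0, 1.0)
        self.expect("{")
        while not self.accept("}"):
            key_tok = self.cur
            key = self.ident()
            self.expect(":")
            if key == "aggregation":
                aggregation = self.ident()
                if aggregation not in AGGREGATIONS:
                    raise LibrarySyntaxError(
                        f"unsupported aggregation {aggregation!r} (supported: {', '.join(AGGREGATIONS)})",
                        key_tok.line,
                        key_tok.column,
                    )
            elif key == "unit":
                if self.cur.kind != "string":
                    raise self.error("expected quoted unit string")
                unit = self.cur.text[1:-1]
                self.i += 1
            elif key == "range":
                rng = self.range_spec()
            else:
                raise LibrarySyntaxError(f"unknown variable attribute {key!r}", key_tok.line, key_tok.column)
            self.accept(",")
        return TemplateVariable(name, aggregation, unit, rng)

    def const_spec(self) -> ConstantSpec:
        name = self.ident()
        self.expect("{")
        self.expect("range")
        self.expect(":")
        rng = self.range_spec()
        self.expect("}")
        return ConstantSpec(name, rng)

    def range_spec(self) -> tuple[float, float]:
        tok = self.cur
        self.expect("<")
        lo = self.number()
        self.expect(",")
        hi = self.number()
        self.expect(">")
        if lo > hi:
            raise LibrarySyntaxError(f"range lower bound {lo} exceeds upper bound {hi}", tok.line, tok.column)
        return (lo, hi)

    def process_def(self) -> TemplateProcess:
        name = self.ident()
        roles: list[tuple[str, str]] = []
        if self.accept("("):
            while True:
                role = self.ident()
                self.expect(":")
                roles.append((role, self.ident()))
                if not self.accept(","):
                    break
            self.expect(")")
        parent = None
        if self.accept(":"):
            parent = self.ident()
        self.expect("{")
        constants: list[ConstantSpec] = []
        equations: list[Equation] = []
        while not self.accept("}"):
            if self.accept("consts"):
                self.expect(":")
                constants.extend(self._spec_list(self.const_spec))
            elif self.accept("equations"):
                self.expect(":")
                equations.extend(self._spec_list(self.equation))
            else:
                raise self.error("expected 'consts:' or 'equations:'")
        return TemplateProcess(name, parent, tuple(roles), tuple(constants), tuple(equations))

    def equation(self) -> Equation:
        self.expect("td")
        self.expect("(")
        role = self.ident()
        self.expect(".")
        var = self.ident()
        self.expect(")")
        self.expect("=")
        return Equation(target=VarRef(role, var), expression=self.expr())

    # -- expressions ------------------------------------------------------
    def expr(self) -> Expr:
        node = self.term()
        while self.cur.text in ("+", "-") and self.cur.kind == "sym":
            op = self.cur.text
            self.i += 1
            node = BinOp(op, node, self.term())
        return node

    def term(self) -> Expr:
        node = self.factor()
        while self.cur.text in ("*", "/") and self.cur.kind == "sym":
            op = self.cur.text
            self.i += 1
            node = BinOp(op, node, self.factor())
        return node

    def factor(self) -> Expr:
        if self.accept("-"):
            return Neg(self.factor())
        return self.primary()

    def primary(self) -> Expr:
        if self.accept("("):
            node = self.expr()
            self.expect(")")
            return node
        if self.cur.kind == "number":
            return Num(self.number())
        if self.cur.kind == "ident":
            name = self.ident()
            if self.accept("."):
                return VarRef(name, self.ident())
            return Const(name)
        raise self.error("expected expression")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _validate(lib: Library) -> Library:
    names: set[str] = set()
    for item in (*lib.entities, *lib.processes):
        if item.name in names:
            raise LibraryError(f"duplicate template name {item.name!r}")
        names.add(item.name)

    for e in lib.entities:
        local: set[str] = set()
        for member in (*e.variables, *e.constants):
            if member.name in local:
                raise LibraryError(f"duplicate member {member.name!r} in entity {e.name!r}")
            local.add(member.name)

    proc_names = {p.name for p in lib.processes}
    for p in lib.processes:
        if p.parent is not None and p.parent not in proc_names:
            raise LibraryError(f"process {p.name!r}: unresolved parent {p.parent!r}")
        for role, entity in p.roles:
            if not any(e.name == entity for e in lib.entities):
                raise LibraryError(f"process {p.name!r}: role {role!r} names unknown entity {entity!r}")

    # hierarchy must be a forest
    for p in lib.processes:
        seen = {p.name}
        cur = p.parent
        while cur is not None:
            if cur in seen:
                raise LibraryError(f"cycle in process hierarchy at {cur!r}")
            seen.add(cur)
            cur = lib.process(cur).parent

    # resolve equation targets and check symbol references
    processes = []
    for p in lib.processes:
        roles = dict(lib.effective_roles(p.name))
        consts = {c.name for c in lib.effective_constants(p.name)}
        role_order = [r for r, _ in lib.effective_roles(p.name)]
        equations = []
        for i, eq in enumerate(p.equations):
            if eq.target.role in roles:
                target_role = eq.target.role
            elif i < len(role_order):
                target_role = role_order[i]  # positional shorthand
            else:
                raise LibraryError(
                    f"process {p.name!r}: equation {i + 1} targets unknown role {eq.target.role!r}"
                )
            lib.entity(roles[target_role]).variable(eq.target.variable)
            used_consts, used_refs = free_symbols(eq.expression)
            for c in used_consts - consts:
                raise LibraryError(f"process {p.name!r}: undeclared constant {c!r}")
            for role, var in used_refs:
                if role not in roles:
                    raise LibraryError(f"process {p.name!r}: undeclared role {role!r}")
                lib.entity(roles[role]).variable(var)
            equations.append(replace(eq, target_role=target_role))
        processes.append(replace(p, equations=tuple(equations)))
    return replace(lib, processes=tuple(processes))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def parse_library(text: str) -> Library:
    """Parse and validate a domain-knowledge library from DSL text."""
    if not text or not text.strip():
        raise LibrarySyntaxError("empty library", 1, 1)
    return _validate(_Parser(text).library())


def serialize_library(lib: Library) -> str:
    """Render a library back to canonical DSL text (parse round-trips)."""
    out: list[str] = []
    for e in lib.entities:
        out.append(f"template entity {e.name} {{")
        if e.variables:
            specs = ", ".join(
                f'{v.name} {{aggregation: {v.aggregation}, unit: "{v.unit}", range: {_rng(v.range)}}}'
                for v in e.variables
            )
            out.append(f"  vars: {specs};")
        if e.constants:
            out.append(f"  consts: {_const_specs(e.constants)};")
        out.append("}")
    for p in lib.processes:
        sig = p.name
        if p.roles:
            sig += "(" + ", ".join(f"{r}: {ent}" for r, ent in p.roles) + ")"
        if p.parent:
            sig += f" : {p.parent}"
        out.append(f"template process {sig} {{")
        if p.constants:
            out.append(f"  consts: {_const_specs(p.constants)};")
        if p.equations:
            eqs = ",\n             ".join(f"td({eq.target}) = {eq.expression}" for eq in p.equations)
            out.append(f"  equations: {eqs};")
        out.append("}")
    return "\n".join(out) + "\n"


def _rng(r: tuple[float, float]) -> str:
    return f"<{_num(r[0])}, {_num(r[1])}>"


def _num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(x)


def _const_specs(consts: tuple[ConstantSpec, ...]) -> str:
    return ", ".join(f"{c.name} {{range: {_rng(c.range)}}}" for c in consts)
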