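"""Candidate model structures and library samples.

An *incomplete model* fixes the entity instances and the process slots of a
model while leaving some slots bound to general (internal) templates. Each
such slot is a modeling choice among the template's leaf alternatives; the
candidate structure space is the Cartesian product of these choices.

A *library sample* retains, for every open choice template, a random
non-empty subset of its leaf alternatives. Samples are not uniform: the
probability of a sample is proportional to the number of candidate models it
induces, so a sample retaining everything is the single most likely one.
For the Predator-Prey library with growth and interaction open (2 + 2
alternatives) there are nine samples with probabilities 1/4 (full library),
1/8 (four samples inducing two candidates) and 1/16 (four samples inducing
one candidate).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import sympy

from . import knowledge_library as kl
from .expressions import to_sympy
from .knowledge_library import Library, _Parser


class ModelSpaceError(ValueError):
    pass


# ---------------------------------------------------------------------------
# incomplete models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityInstance:
    name: str
    template: str
    exogenous: bool = False


@dataclass(frozen=True)
class ProcessSlot:
    name: str
    template: str  # leaf or internal template process
    arguments: tuple[tuple[str, str], ...]  # role -> entity instance


@dataclass(frozen=True)
class IncompleteModel:
    name: str
    instances: tuple[EntityInstance, ...]
    slots: tuple[ProcessSlot, ...]

    def instance(self, name: str) -> EntityInstance:
        for inst in self.instances:
            if inst.name == name:
                return inst
        raise ModelSpaceError(f"unknown entity instance {name!r}")


class _IncParser(_Parser):
    def incomplete(self) -> IncompleteModel:
        self.expect("incomplete")
        self.expect("model")
        name = self.ident()
        self.expect("{")
        instances: list[EntityInstance] = []
        slots: list[ProcessSlot] = []
        while not self.accept("}"):
            if self.accept("entity"):
                iname = self.ident()
                self.expect(":")
                template = self.ident()
                exo = self.accept("exogenous")
                instances.append(EntityInstance(iname, template, exo))
            elif self.accept("process"):
                sname = self.ident()
                self.expect(":")
                template = self.ident()
                args: list[tuple[str, str]] = []
                if self.accept("("):
                    while not self.accept(")"):
                        role = self.ident()
                        self.expect("=")
                        args.append((role, self.ident()))
                        self.accept(",")
                slots.append(ProcessSlot(sname, template, tuple(args)))
            else:
                raise self.error("expected 'entity' or 'process'")
            self.accept(";")
        return IncompleteModel(name, tuple(instances), tuple(slots))


def parse_incomplete_model(text: str) -> IncompleteModel:
    """Parse an incomplete-model specification from its text form."""
    if not text or not text.strip():
        raise ModelSpaceError("empty incomplete model")
    return _IncParser(text).incomplete()


def validate_incomplete(lib: Library, inc: IncompleteModel) -> None:
    """Check an incomplete model against a library; raise on inconsistency."""
    seen: set[str] = set()
    for inst in inc.instances:
        if inst.name in seen:
            raise ModelSpaceError(f"duplicate entity instance {inst.name!r}")
        seen.add(inst.name)
        lib.entity(inst.template)
    slot_names: set[str] = set()
    for slot in inc.slots:
        if slot.name in slot_names:
            raise ModelSpaceError(f"duplicate process slot {slot.name!r}")
        slot_names.add(slot.name)
        if not lib.has_process(slot.template):
            raise ModelSpaceError(f"slot {slot.name!r}: unknown template process {slot.template!r}")
        roles = dict(lib.effective_roles(slot.template))
        args = dict(slot.arguments)
        if set(args) != set(roles):
            missing = set(roles) - set(args)
            extra = set(args) - set(roles)
            raise ModelSpaceError(
                f"slot {slot.name!r}: role bindings do not match template {slot.template!r}"
                + (f"; missing {sorted(missing)}" if missing else "")
                + (f"; unknown {sorted(extra)}" if extra else "")
            )
        for role, inst_name in slot.arguments:
            inst = inc.instance(inst_name)
            if inst.template != roles[role]:
                raise ModelSpaceError(
                    f"slot {slot.name!r}: role {role!r} expects entity {roles[role]!r}, "
                    f"got instance {inst_name!r} of {inst.template!r}"
                )
        if not kl.leaf_alternatives(lib, slot.template):
            raise ModelSpaceError(f"slot {slot.name!r}: template {slot.template!r} has no leaf alternative")


# ---------------------------------------------------------------------------
# model structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelStructure:
    """One fully resolved entity/process combination with free parameters."""

    instances: tuple[EntityInstance, ...]
    resolved: tuple[tuple[str, str, tuple[tuple[str, str], ...]], ...]  # (slot, leaf, args)
    parameters: tuple[tuple[str, tuple[float, float]], ...]  # qualified name, range

    @property
    def key(self) -> str:
        """Canonical identity string (slot -> leaf assignment)."""
        return ";".join(f"{slot}={leaf}" for slot, leaf, _ in self.resolved)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.parameters)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([rng for _, rng in self.parameters], dtype=float).reshape(-1, 2)


def enumerate_structures(
    lib: Library,
    inc: IncompleteModel,
    restrict: dict[str, tuple[str, ...]] | None = None,
) -> list[ModelStructure]:
    """Enumerate all candidate model structures of *inc* under *lib*.

    ``restrict`` optionally limits the leaf alternatives of choice templates
    (a library sample). The result is ordered lexicographically over (slot
    declaration order, leaf declaration order) and its length is the product
    of the per-slot alternative counts.
    """
    validate_incomplete(lib, inc)
    per_slot: list[list[str]] = []
    for slot in inc.slots:
        leaves = [p.name for p in kl.leaf_alternatives(lib, slot.template)]
        if restrict is not None and slot.template in restrict:
            keep = set(restrict[slot.template])
            leaves = [name for name in leaves if name in keep]
        if not leaves:
            raise ModelSpaceError(f"slot {slot.name!r}: no leaf alternative retained")
        per_slot.append(leaves)
    structures = []
    for combo in itertools.product(*per_slot):
        resolved = tuple(
            (slot.name, leaf, slot.arguments) for slot, leaf in zip(inc.slots, combo)
        )
        params: list[tuple[str, tuple[float, float]]] = []
        for slot, leaf in zip(inc.slots, combo):
            for c in lib.effective_constants(leaf):
                params.append((f"{slot.name}.{c.name}", c.range))
        structures.append(ModelStructure(inc.instances, resolved, tuple(params)))
    return structures


# ---------------------------------------------------------------------------
# ODE compilation
# ---------------------------------------------------------------------------


def _sym(name: str) -> sympy.Symbol:
    return sympy.Symbol(name.replace(".", "__"))


@dataclass(frozen=True)
class ODESystem:
    """A compiled model: one first-order ODE per endogenous state variable."""

    state_vars: tuple[str, ...]  # "instance.variable"
    exog_vars: tuple[str, ...]
    parameters: tuple[tuple[str, tuple[float, float]], ...]
    rhs: tuple[sympy.Expr, ...]  # d(state)/dt, aligned with state_vars

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.parameters)

    def _args(self) -> list[sympy.Symbol]:
        return (
            [_sym(v) for v in self.state_vars]
            + [_sym(v) for v in self.exog_vars]
            + [_sym(p) for p in self.parameter_names]
        )

    def rhs_function(self):
        """``f(y, exog, params) -> dy/dt`` built with lambdify (memoized)."""
        cached = getattr(self, "_rhs_fn", None)
        if cached is not None:
            return cached
        fn = sympy.lambdify(self._args(), list(self.rhs), modules="numpy", cse=True)

        def f(y, exog, params):
            return np.asarray(fn(*y, *exog, *params), dtype=float)

        object.__setattr__(self, "_rhs_fn", f)
        return f

    def jacobian_function(self):
        """Analytic Jacobian d(rhs)/d(state) for implicit solvers (memoized)."""
        cached = getattr(self, "_jac_fn", None)
        if cached is not None:
            return cached
        state = [_sym(v) for v in self.state_vars]
        jac = sympy.Matrix(list(self.rhs)).jacobian(state)
        fn = sympy.lambdify(self._args(), jac, modules="numpy", cse=True)

        def f(y, exog, params):
            return np.asarray(fn(*y, *exog, *params), dtype=float)

        object.__setattr__(self, "_jac_fn", f)
        return f


def compile_to_odes(lib: Library, structure: ModelStructure) -> ODESystem:
    """Compile a fully resolved structure into an ODE system.

    Every ``td`` contribution targeting a state variable is summed (the only
    aggregation supported); endogenous variables without contributions get a
    zero derivative. Variables of exogenous entity instances become named
    inputs driven by data at simulation time.
    """
    state_vars: list[str] = []
    exog_vars: list[str] = []
    for inst in structure.instances:
        for v in lib.entity(inst.template).variables:
            (exog_vars if inst.exogenous else state_vars).append(f"{inst.name}.{v.name}")
    contributions: dict[str, list[sympy.Expr]] = {v: [] for v in state_vars}

    for slot_name, leaf_name, arguments in structure.resolved:
        args = dict(arguments)
        roles = dict(lib.effective_roles(leaf_name))
        leaf = lib.process(leaf_name)
        if not leaf.equations:
            raise ModelSpaceError(f"leaf template {leaf_name!r} defines no equations")
        ref_map = {}
        for role, entity in roles.items():
            if role not in args:
                raise ModelSpaceError(f"slot {slot_name!r}: unbound role {role!r}")
            for v in lib.entity(entity).variables:
                ref_map[(role, v.name)] = _sym(f"{args[role]}.{v.name}")
        const_map = {c.name: _sym(f"{slot_name}.{c.name}") for c in lib.effective_constants(leaf_name)}
        for eq in leaf.equations:
            target = f"{args[eq.target_role]}.{eq.target_variable}"
            if target not in contributions:
                raise ModelSpaceError(
                    f"slot {slot_name!r}: equation targets exogenous or unknown variable {target!r}"
                )
            contributions[target].append(to_sympy(eq.expression, const_map, ref_map))

    rhs = tuple(sympy.Add(*contributions[v]) if contributions[v] else sympy.Integer(0) for v in state_vars)
    return ODESystem(tuple(state_vars), tuple(exog_vars), structure.parameters, rhs)


# ---------------------------------------------------------------------------
# library samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LibrarySample:
    """Retained leaf alternatives per open choice template."""

    subsets: tuple[tuple[str, tuple[str, ...]], ...]  # template -> retained leaves
    model_count: int  # |L_S|
    probability: float

    def restriction(self) -> dict[str, tuple[str, ...]]:
        return dict(self.subsets)


def _choice_templates(lib: Library, inc: IncompleteModel) -> list[tuple[str, list[str], int]]:
    """Open choice templates: (template, leaves, number of slots bound to it).

    A slot bound directly to a leaf template is pinned and defines no choice.
    """
    validate_incomplete(lib, inc)
    counts: dict[str, int] = {}
    order: list[str] = []
    for slot in inc.slots:
        if lib.is_leaf(slot.template):
            continue
        if slot.template not in counts:
            order.append(slot.template)
        counts[slot.template] = counts.get(slot.template, 0) + 1
    return [
        (t, [p.name for p in kl.leaf_alternatives(lib, t)], counts[t]) for t in order
    ]


def _subset_weights(leaves: list[str], n_slots: int) -> tuple[list[tuple[str, ...]], np.ndarray]:
    subsets: list[tuple[str, ...]] = []
    for r in range(1, len(leaves) + 1):
        subsets.extend(itertools.combinations(leaves, r))
    weights = np.array([len(s) ** n_slots for s in subsets], dtype=float)
    return subsets, weights


def enumerate_library_samples(lib: Library, inc: IncompleteModel) -> list[LibrarySample]:
    """All library samples with induced model counts and probabilities.

    One sample per combination of non-empty leaf subsets across the open
    choice templates; P(sample) = |L_S| / sum over samples of |L_S|, the
    sample-size-proportional law. Probabilities sum to 1 exactly.
    """
    choices = _choice_templates(lib, inc)
    if not choices:
        return [LibrarySample(subsets=(), model_count=1, probability=1.0)]
    per_template = [_subset_weights(leaves, n) for _, leaves, n in choices]
    samples = []
    total = 0.0
    for combo in itertools.product(*[range(len(s)) for s, _ in per_template]):
        subsets = tuple(
            (choices[j][0], per_template[j][0][idx]) for j, idx in enumerate(combo)
        )
        count = int(np.prod([per_template[j][1][idx] for j, idx in enumerate(combo)]))
        samples.append((subsets, count))
        total += count
    return [
        LibrarySample(subsets=s, model_count=c, probability=c / total) for s, c in samples
    ]


def sample_library(lib: Library, inc: IncompleteModel, rng: np.random.Generator) -> LibrarySample:
    """Draw one library sample from the size-proportional distribution.

    Per open choice template the retained non-empty subset S is drawn with
    probability proportional to |S| raised to the number of slots bound to
    the template, which makes the joint sample probability exactly
    proportional to the induced model count |L_S|.
    """
    choices = _choice_templates(lib, inc)
    subsets: list[tuple[str, tuple[str, ...]]] = []
    count = 1
    prob = 1.0
    for template, leaves, n_slots in choices:
        cand, weights = _subset_weights(leaves, n_slots)
        p = weights / weights.sum()
        idx = int(rng.choice(len(cand), p=p))
        subsets.append((template, cand[idx]))
        count *= len(cand[idx]) ** n_slots
        prob *= p[idx]
    return LibrarySample(subsets=tuple(subsets), model_count=count, probability=prob)
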