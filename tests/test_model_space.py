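import itertools

import numpy as np
import pytest
import sympy
from scipy import stats

from pbme.knowledge_library import parse_library
from pbme.model_space import (
    ModelSpaceError,
    compile_to_odes,
    enumerate_library_samples,
    enumerate_structures,
    parse_incomplete_model,
    sample_library,
    validate_incomplete,
)

FULLY_RESOLVED = """
incomplete model Resolved {
  entity prey : Population;
  entity predator : Population;
  process growth : ExponentialGrowth(pop = prey);
  process predator_prey : UnsaturatedPP(pop1 = predator, pop2 = prey);
  process decay : Decay(pop = predator);
}
"""

THREE_LEAF_LIBRARY = """
template entity E { vars: v {aggregation: sum, unit: "", range: <0, 10>}; }
template process A(x: E) { consts: a {range: <0, 1>}; }
template process A1 : A { equations: td(x.v) = a * x.v; }
template process A2 : A { equations: td(x.v) = -a * x.v; }
template process A3 : A { equations: td(x.v) = a; }
template process B(x: E) { consts: b {range: <0, 1>}; }
template process B1 : B { equations: td(x.v) = b * x.v; }
template process B2 : B { equations: td(x.v) = -b * x.v; }
template process B3 : B { equations: td(x.v) = b; }
"""

THREE_LEAF_INCOMPLETE = """
incomplete model M {
  entity e : E;
  process pa : A(x = e);
  process pb : B(x = e);
}
"""


class TestEnumerateStructures:
    def test_predator_prey_space_has_four_candidates(self, pp_structures):
        assert len(pp_structures) == 4
        keys = [s.key for s in pp_structures]
        assert keys == sorted(keys, key=keys.index)  # deterministic order
        assert keys[0] == "growth=ExponentialGrowth;predator_prey=UnsaturatedPP;decay=Decay"

    def test_fully_resolved_model_yields_one_structure(self, pp_library):
        inc = parse_incomplete_model(FULLY_RESOLVED)
        assert len(enumerate_structures(pp_library, inc)) == 1

    def test_restriction_to_single_alternatives(self, pp_library, pp_incomplete):
        restrict = {"Growth": ("LogisticGrowth",), "Interaction": ("SaturatedPP",)}
        (structure,) = enumerate_structures(pp_library, pp_incomplete, restrict=restrict)
        assert structure.key == "growth=LogisticGrowth;predator_prey=SaturatedPP;decay=Decay"

    def test_count_is_multiplicative_across_slots(self):
        # oracle: brute-force Cartesian product over per-slot alternatives
        lib = parse_library(THREE_LEAF_LIBRARY)
        inc = parse_incomplete_model(THREE_LEAF_INCOMPLETE)
        structures = enumerate_structures(lib, inc)
        expected = list(itertools.product(["A1", "A2", "A3"], ["B1", "B2", "B3"]))
        assert len(structures) == len(expected) == 9
        got = [(s.resolved[0][1], s.resolved[1][1]) for s in structures]
        assert got == expected

    def test_parameter_order_follows_slots_then_declarations(self, pp_structures):
        saturated = next(s for s in pp_structures if "SaturatedPP" in s.key)
        assert saturated.parameter_names == (
            "growth.gR",
            "predator_prey.iR",
            "predator_prey.eF",
            "predator_prey.sR",
            "decay.dR",
        )

    def test_inconsistent_incomplete_model_rejected(self, pp_library):
        bad = parse_incomplete_model(
            "incomplete model M { entity x : Population; process g : Osmosis(pop = x); }"
        )
        with pytest.raises(ModelSpaceError, match="Osmosis"):
            validate_incomplete(pp_library, bad)
        unbound = parse_incomplete_model(
            "incomplete model M { entity x : Population; process g : Growth(); }"
        )
        with pytest.raises(ModelSpaceError, match="missing"):
            validate_incomplete(pp_library, unbound)


class TestCompileToOdes:
    def test_lotka_volterra_equations(self, pp_library, pp_structures):
        system = compile_to_odes(pp_library, pp_structures[0])
        assert system.state_vars == ("prey.d", "predator.d")
        prey, pred = sympy.symbols("prey__d predator__d")
        gR, iR, eF, dR = sympy.symbols("growth__gR predator_prey__iR predator_prey__eF decay__dR")
        rhs = dict(zip(system.state_vars, system.rhs))
        assert sympy.simplify(rhs["prey.d"] - (gR * prey - iR * prey * pred)) == 0
        assert sympy.simplify(rhs["predator.d"] - (iR * eF * prey * pred - dR * pred)) == 0

    def test_saturated_interaction_divides_by_prey_plus_sR(self, pp_library, pp_structures):
        saturated = next(s for s in pp_structures if "SaturatedPP" in s.key)
        system = compile_to_odes(pp_library, saturated)
        prey, sR = sympy.symbols("prey__d predator_prey__sR")
        for expr in system.rhs:
            num, den = sympy.fraction(sympy.together(expr))
            assert den.has(prey + sR) or (prey + sR) in den.as_ordered_factors()

    def test_uninfluenced_variable_has_zero_derivative(self, pp_library):
        inc = parse_incomplete_model(
            "incomplete model M { entity prey : Population; entity predator : Population; "
            "process decay : Decay(pop = predator); }"
        )
        (structure,) = enumerate_structures(pp_library, inc)
        system = compile_to_odes(pp_library, structure)
        rhs = dict(zip(system.state_vars, system.rhs))
        assert rhs["prey.d"] == 0


class TestLibrarySamples:
    def test_nine_samples_with_worked_counts_and_probabilities(self, pp_library, pp_incomplete):
        samples = enumerate_library_samples(pp_library, pp_incomplete)
        assert len(samples) == 9
        counts = sorted(s.model_count for s in samples)
        assert counts == [1, 1, 1, 1, 2, 2, 2, 2, 4]
        probs = {s.model_count: s.probability for s in samples}
        assert probs[4] == pytest.approx(1 / 4)
        assert probs[2] == pytest.approx(1 / 8)
        assert probs[1] == pytest.approx(1 / 16)
        assert abs(sum(s.probability for s in samples) - 1.0) < 1e-12

    def test_sampled_count_matches_enumeration(self, pp_library, pp_incomplete):
        for sample in enumerate_library_samples(pp_library, pp_incomplete):
            induced = enumerate_structures(pp_library, pp_incomplete, restrict=sample.restriction())
            assert len(induced) == sample.model_count

    def test_no_choice_library_gives_single_certain_sample(self, pp_library, decay_incomplete):
        (sample,) = enumerate_library_samples(pp_library, decay_incomplete)
        assert sample.probability == 1.0
        assert sample.model_count == 1

    def test_two_templates_with_three_leaves_each(self):
        lib = parse_library(THREE_LEAF_LIBRARY)
        inc = parse_incomplete_model(THREE_LEAF_INCOMPLETE)
        samples = enumerate_library_samples(lib, inc)
        assert len(samples) == (2**3 - 1) ** 2 == 49
        assert abs(sum(s.probability for s in samples) - 1.0) < 1e-12

    def test_seeded_draws_match_analytic_distribution(self, pp_library, pp_incomplete):
        rng = np.random.default_rng(2024)
        samples = enumerate_library_samples(pp_library, pp_incomplete)
        index = {s.subsets: i for i, s in enumerate(samples)}
        observed = np.zeros(len(samples))
        n_draws = 16_000
        for _ in range(n_draws):
            drawn = sample_library(pp_library, pp_incomplete, rng)
            observed[index[drawn.subsets]] += 1
            assert drawn.model_count >= 1
        expected = np.array([s.probability for s in samples]) * n_draws
        _, p_value = stats.chisquare(observed, expected)
        assert p_value > 0.01
        (full_idx,) = [i for i, s in enumerate(samples) if s.model_count == 4]
        assert abs(observed[full_idx] / n_draws - 0.25) < 0.015

    def test_drawn_probability_field_matches_enumeration(self, pp_library, pp_incomplete):
        rng = np.random.default_rng(7)
        enumerated = {s.subsets: s.probability for s in enumerate_library_samples(pp_library, pp_incomplete)}
        for _ in range(50):
            drawn = sample_library(pp_library, pp_incomplete, rng)
            assert drawn.probability == pytest.approx(enumerated[drawn.subsets])
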