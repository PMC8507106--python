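"""Reaction-network representation and ODE assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rhono import (
    ModelAssemblyError,
    ModelDefinition,
    ParameterSet,
    Reaction,
    SpeciesState,
    assemble,
    build_extended_model,
    build_initial_model,
    count_reactions,
    model_from_json,
    model_to_json,
)
from rhono.models import perturbable_parameters


class TestStructuralCounts:
    def test_initial_model_has_31_reactions_and_11_odes(self, initial_model):
        model, params = initial_model
        assert count_reactions(model) == 31
        assert assemble(model, params).dimension == 11

    def test_extended_model_has_12_odes_and_36_perturbable_parameters(
            self, extended_model):
        model, params = extended_model
        assert assemble(model, params).dimension == 12
        assert len(perturbable_parameters(params)) == 36

    def test_empty_model_has_zero_reactions(self):
        m = ModelDefinition("empty", [SpeciesState("X")], [])
        assert count_reactions(m) == 0

    def test_two_node_model_has_six_reactions(self):
        from rhono import build_two_node

        model, _ = build_two_node(1, 1, 1, 1, 0.1, 0.1)
        assert count_reactions(model) == 6

    def test_clamped_input_is_not_a_state_variable(self, initial_model):
        model, _ = initial_model
        assert "HGF" in model.inputs
        assert "HGF" not in model.state_species()


class TestRateLaws:
    def test_synthesis_plus_decay_is_birth_death(self):
        m = ModelDefinition(
            "bd", [SpeciesState("X")],
            [Reaction("s", "synthesis", products={"X": 1}, parameters=["s"]),
             Reaction("d", "decay", substrates={"X": 1}, parameters=["d"])],
        )
        f = assemble(m, ParameterSet({"s": 3.0, "d": 0.7}))
        for x in [0.0, 0.5, 2.0, 10.0]:
            assert f(0.0, np.array([x]))[0] == pytest.approx(3.0 - 0.7 * x)

    def test_mass_action_with_modifier_and_stoichiometry(self):
        # 2X -> 0 catalysed by Y: rate k*x^2*y, dX/dt = -2*rate
        m = ModelDefinition(
            "ma", [SpeciesState("X"), SpeciesState("Y")],
            [Reaction("r", "mass_action", substrates={"X": 2},
                      modifiers=[("Y", 1)], parameters=["k"])],
        )
        f = assemble(m, ParameterSet({"k": 0.5}))
        dx = f(0.0, np.array([3.0, 2.0]))
        assert dx[0] == pytest.approx(-2 * 0.5 * 9.0 * 2.0)
        assert dx[1] == pytest.approx(0.0)

    def test_michaelis_menten_saturates(self):
        m = ModelDefinition(
            "mm", [SpeciesState("S"), SpeciesState("E")],
            [Reaction("r", "michaelis_menten", substrates={"S": 1},
                      modifiers=[("E", 1)], parameters=["kcat", "Km"])],
        )
        f = assemble(m, ParameterSet({"kcat": 2.0, "Km": 1.0}))
        v1 = -f(0.0, np.array([1.0, 1.0]))[0]
        v2 = -f(0.0, np.array([100.0, 1.0]))[0]
        assert v1 == pytest.approx(2.0 * 1.0 / 2.0)
        assert v2 == pytest.approx(2.0 * 100 / 101)
        assert v2 < 2.0  # Vmax bound

    def test_hill_activation_with_coefficient(self):
        m = ModelDefinition(
            "h", [SpeciesState("P"), SpeciesState("C")],
            [Reaction("r", "hill", products={"P": 1}, modifiers=[("C", 1)],
                      parameters=["k", "K", "n"])],
        )
        f = assemble(m, ParameterSet({"k": 4.0, "K": 2.0, "n": 3.0}))
        assert f(0.0, np.array([0.0, 2.0]))[0] == pytest.approx(2.0)  # half
        assert f(0.0, np.array([0.0, 0.0]))[0] == pytest.approx(0.0)
        lo = f(0.0, np.array([0.0, 0.5]))[0]
        hi = f(0.0, np.array([0.0, 8.0]))[0]
        assert lo < 0.1 and hi > 3.9  # ultrasensitive

    def test_inhibitor_modifier_is_divisive(self):
        m = ModelDefinition(
            "i", [SpeciesState("X"), SpeciesState("I")],
            [Reaction("r", "synthesis", products={"X": 1},
                      modifiers=[("I", -1)], parameters=["k", "Ki"])],
        )
        f = assemble(m, ParameterSet({"k": 1.0, "Ki": 2.0}))
        assert f(0.0, np.array([0.0, 0.0]))[0] == pytest.approx(1.0)
        assert f(0.0, np.array([0.0, 2.0]))[0] == pytest.approx(0.5)


class TestValidation:
    def test_missing_parameter_is_named(self, initial_model):
        model, params = initial_model
        bad = ParameterSet({k: v for k, v in params.values.items()
                            if k != "ki1"})
        with pytest.raises(ModelAssemblyError, match="missing parameter 'ki1'"):
            assemble(model, bad)

    def test_unknown_rate_law_kind_rejected(self):
        with pytest.raises(ModelAssemblyError, match="unknown rate-law kind"):
            Reaction("r", "quadratic", substrates={"X": 1}, parameters=["k"])

    def test_species_parameter_name_collision_rejected(self):
        m = ModelDefinition(
            "c", [SpeciesState("k")],
            [Reaction("d", "decay", substrates={"k": 1}, parameters=["k"])],
        )
        with pytest.raises(ModelAssemblyError, match="collision"):
            assemble(m, ParameterSet({"k": 1.0}))

    def test_duplicate_species_rejected(self):
        with pytest.raises(ModelAssemblyError, match="duplicate species"):
            ModelDefinition("d", [SpeciesState("X"), SpeciesState("X")], [])

    def test_unknown_species_reference_rejected(self):
        m = ModelDefinition(
            "u", [SpeciesState("X")],
            [Reaction("r", "decay", substrates={"Y": 1}, parameters=["k"])],
        )
        with pytest.raises(ModelAssemblyError, match="unknown species 'Y'"):
            assemble(m, ParameterSet({"k": 1.0}))

    def test_negative_parameter_rejected(self):
        with pytest.raises(ModelAssemblyError):
            ParameterSet({"k": -1.0})


class TestAssembledField:
    def test_no_production_from_nothing(self, initial_model):
        """At the zero state, only zeroth-order syntheses contribute."""
        model, params = initial_model
        f = assemble(model, params)
        dx = f(0.0, np.zeros(f.dimension))
        assert np.all(dx >= 0)
        names = f.species_names
        # species with no zeroth-order or clamped-input production:
        for sp in ["RhoA_GTP", "RhoA_pS188", "ROCK", "eNOS", "peNOS",
                   "NO", "cGMP", "PKG"]:
            assert dx[names.index(sp)] == 0.0

    def test_assembly_is_deterministic(self, extended_model):
        model, params = extended_model
        f1 = assemble(model, params)
        f2 = assemble(model, params)
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.uniform(0, 100, f1.dimension)
            assert np.array_equal(f1(0.0, x), f2(0.0, x))

    def test_jacobian_consistent_with_directional_derivative(
            self, extended_field):
        """FD Jacobian reproduces directional derivatives of the evaluator."""
        f = extended_field
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.uniform(0.1, 50, f.dimension)
            v = rng.normal(size=f.dimension)
            v /= np.linalg.norm(v)
            h = 1e-5
            dd = (f(0.0, x + h * v) - f(0.0, x - h * v)) / (2 * h)
            Jv = f.jacobian(x) @ v
            denom = np.max(np.abs(dd)) + 1e-12
            assert np.max(np.abs(Jv - dd)) / denom < 1e-4

    def test_two_node_jacobian_matches_analytic(self):
        from rhono import build_two_node

        ks = (1.2, 0.3, 0.8, 0.2, 0.05, 0.07)
        model, params = build_two_node(*ks)
        f = assemble(model, params)
        ksynthA, kdegA, ksynthB, kdegB, kiA, kiB = ks
        rng = np.random.default_rng(3)
        for _ in range(20):
            A, B = rng.uniform(0.1, 20, 2)
            J = f.jacobian(np.array([A, B]))
            J_true = np.array([
                [-kdegA - kiB * B, -kiB * A],
                [-kiA * B, -kdegB - kiA * A],
            ])
            assert np.allclose(J, J_true, rtol=1e-5, atol=1e-7)


class TestSerialization:
    @pytest.mark.parametrize("builder", [build_initial_model,
                                         build_extended_model])
    def test_json_round_trip_is_lossless(self, builder):
        model, params = builder()
        text = model_to_json(model, params)
        model2, params2 = model_from_json(text)
        assert model2.name == model.name
        assert model2.species_names == model.species_names
        assert model2.inputs == model.inputs
        assert params2.values == params.values
        assert len(model2.reactions) == len(model.reactions)
        for r1, r2 in zip(model.reactions, model2.reactions):
            assert (r1.id, r1.kind, r1.substrates, r1.products,
                    r1.modifiers, r1.parameters) == (
                r2.id, r2.kind, r2.substrates, r2.products,
                r2.modifiers, r2.parameters)
        # round-tripped model assembles to an identical vector field
        f1, f2 = assemble(model, params), assemble(model2, params2)
        x = np.linspace(0.5, 30, f1.dimension)
        assert np.array_equal(f1(0.0, x), f2(0.0, x))

    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_evaluator_finite_on_positive_states(self, a, b):
        model, params = build_initial_model()
        f = assemble(model, params)
        x = np.full(f.dimension, a)
        x[::2] = b
        assert np.all(np.isfinite(f(0.0, x)))
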