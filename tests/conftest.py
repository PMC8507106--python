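import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rhono import (
    ModelDefinition,
    ParameterSet,
    Reaction,
    SpeciesState,
    assemble,
    build_extended_model,
    build_initial_model,
    build_two_node,
)
from rhono.network_core import RateField, finite_difference_jacobian


@pytest.fixture(scope="session")
def initial_model():
    return build_initial_model()


@pytest.fixture(scope="session")
def extended_model():
    return build_extended_model()


@pytest.fixture(scope="session")
def initial_field(initial_model):
    return assemble(*initial_model)


@pytest.fixture(scope="session")
def extended_field(extended_model):
    return assemble(*extended_model)


def make_cubic_model():
    """dx/dt = r + x - x^3 as a one-species reaction network."""
    model = ModelDefinition(
        name="cubic_normal_form",
        species=[SpeciesState("X")],
        reactions=[
            Reaction("src", "synthesis", products={"X": 1}, parameters=["r"]),
            Reaction("lin", "mass_action", substrates={"X": 1},
                     products={"X": 2}, parameters=["klin"]),
            Reaction("cub", "mass_action", substrates={"X": 3},
                     products={"X": 2}, parameters=["kcub"]),
        ],
    )
    return model, ParameterSet({"r": 0.0, "klin": 1.0, "kcub": 1.0})


def make_birth_death(s=2.0, d=0.5):
    model = ModelDefinition(
        name="birth_death",
        species=[SpeciesState("X")],
        reactions=[
            Reaction("syn", "synthesis", products={"X": 1}, parameters=["s"]),
            Reaction("deg", "decay", substrates={"X": 1}, parameters=["d"]),
        ],
    )
    return model, ParameterSet({"s": s, "d": d})


def make_toy_switch(k=1.0, K=1.0, d=0.4):
    """dx/dt = k*x^2/(K^2+x^2) - d*x: bistable (0 and x_high) iff k > 2*K*d."""
    model = ModelDefinition(
        name="toy_switch",
        species=[SpeciesState("X")],
        reactions=[
            Reaction("auto", "hill", products={"X": 1}, modifiers=[("X", 1)],
                     parameters=["k", "K", "nhill"]),
            Reaction("deg", "decay", substrates={"X": 1}, parameters=["d"]),
        ],
    )
    return model, ParameterSet({"k": k, "K": K, "nhill": 2.0, "d": d})


def field_from_callable(f, dim):
    """Wrap a plain dx/dt callable as a RateField (FD Jacobian)."""
    return RateField(
        dimension=dim,
        evaluator=f,
        jacobian=lambda x: finite_difference_jacobian(f, x),
    )


@pytest.fixture
def cubic_model():
    return make_cubic_model()


@pytest.fixture
def birth_death():
    return make_birth_death()


@pytest.fixture
def two_node_generic():
    return build_two_node(1.2, 0.3, 0.8, 0.2, 0.05, 0.07)
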