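"""Multistart attractor census, extreme-initialization test, bistability search.

The operational definition of bistability used throughout the package is a
conjunction of two independent probes, so a missed basin in either cannot
produce a false positive:

1. a multistart census (:func:`classify_attractors`): many random initial
   states, each relaxed to a steady state and the stable endpoints clustered
   by relative max-norm distance;
2. an extreme-initialization test (:func:`extreme_init_test`): two
   deliberately opposite starting states — everything on the NO side high
   with the RhoA side low, and vice versa — which must settle into distinct
   stable states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .network_core import ModelDefinition, ParameterSet, assemble
from .simulation import (
    DEFAULT_HORIZON,
    IntegrationError,
    SteadyState,
    find_steady_state,
)
from .synthetic_inputs import (
    DEFAULT_HI,
    DEFAULT_LO,
    InitialConditionSpec,
    draw_initial_conditions,
    sample_parameter_sets,
    spawn_seeds,
)

__all__ = [
    "BistabilityResult",
    "classify_attractors",
    "is_bistable",
    "extreme_init_test",
    "extreme_initial_states",
    "search_bistable_parameters",
    "CLUSTER_TOL",
]

#: two stable states are the same attractor if their relative max-norm
#: distance is below this (far below the ~5-fold state separations the
#: analysis reports, far above integrator error)
CLUSTER_TOL = 1.0e-3

#: species whose levels rise with the relaxation/NO arm of the network;
#: used to construct the two extreme starting states
NO_SIDE_SPECIES = frozenset(
    {"eNOS_mRNA", "eNOS", "peNOS", "NO", "cGMP", "PKG", "B"}
)


def state_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Relative max-norm distance used for attractor clustering."""
    scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1.0)
    return float(np.max(np.abs(a - b))) / scale


@dataclass
class BistabilityResult:
    """Census of distinct attractors found by a multistart ensemble."""

    attractors: list[SteadyState]
    basin_counts: list[int]
    nonconverged: int
    n_starts: int
    seed: int
    assignments: list[int] = field(default_factory=list)

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_starts": self.n_starts,
                "seed": self.seed,
                "nonconverged": self.nonconverged,
                "basin_counts": self.basin_counts,
                "attractors": [a.state.tolist() for a in self.attractors],
                "residual_norms": [a.residual_norm for a in self.attractors],
            },
            indent=1,
        )


def classify_attractors(
    model: ModelDefinition,
    params: ParameterSet,
    n_starts: int = 100,
    seed: int = 0,
    ic_spec: InitialConditionSpec | None = None,
    horizon: float = DEFAULT_HORIZON,
    **integrate_kwargs,
) -> BistabilityResult:
    """Relax ``n_starts`` random initial states and cluster the attractors.

    Initial states default to independent log-uniform draws over
    [10^-2, 10^2] nM per species.  Marginal steady states (leading
    eigenvalue within the stability margin) and nonconvergent or divergent
    runs are counted separately and never enter the attractor list.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    field_ = assemble(model, params)
    if ic_spec is None:
        ic_spec = InitialConditionSpec.default(field_.dimension, seed=seed)
    starts = draw_initial_conditions(ic_spec, n_starts)

    attractors: list[SteadyState] = []
    basin_counts: list[int] = []
    assignments: list[int] = []
    nonconverged = 0
    for x0 in starts:
        try:
            ss = find_steady_state(field_, x0, horizon=horizon,
                                   **integrate_kwargs)
        except IntegrationError:
            nonconverged += 1
            assignments.append(-1)
            continue
        if not ss.stable or ss.marginal:
            nonconverged += 1
            assignments.append(-1)
            continue
        for i, a in enumerate(attractors):
            if state_distance(ss.state, a.state) < CLUSTER_TOL:
                basin_counts[i] += 1
                assignments.append(i)
                break
        else:
            attractors.append(ss)
            basin_counts.append(1)
            assignments.append(len(attractors) - 1)

    if not attractors:
        raise RuntimeError("no attractors found: all starts nonconvergent")
    # order attractors by their first coordinate for reproducible labelling
    order = np.argsort([a.state[0] for a in attractors])
    remap = {int(old): new for new, old in enumerate(order)}
    return BistabilityResult(
        attractors=[attractors[i] for i in order],
        basin_counts=[basin_counts[i] for i in order],
        nonconverged=nonconverged,
        n_starts=n_starts,
        seed=ic_spec.seed,
        assignments=[remap.get(a, -1) for a in assignments],
    )


def extreme_initial_states(
    model: ModelDefinition,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
) -> tuple[np.ndarray, np.ndarray]:
    """The 'NO-high' and 'RhoA-high' extreme starting states.

    NO-high: every NO-arm species at ``hi``, everything else at ``lo``;
    RhoA-high: the complement.  Both are synthetic stand-ins constructed
    from the species-side classification (the original extreme-start table
    is not public in the bundled sources).
    """
    names = model.state_species()
    no_high = np.array([hi if n in NO_SIDE_SPECIES else lo for n in names])
    rhoa_high = np.array([lo if n in NO_SIDE_SPECIES else hi for n in names])
    return no_high, rhoa_high


def extreme_init_test(
    model: ModelDefinition,
    params: ParameterSet,
    horizon: float = DEFAULT_HORIZON,
    **integrate_kwargs,
) -> bool | None:
    """Do the two extreme starts settle into distinct stable states?

    Returns True/False, or None ("inconclusive") if either start fails to
    converge to a stable steady state.
    """
    field_ = assemble(model, params)
    outcomes = []
    for x0 in extreme_initial_states(model):
        try:
            ss = find_steady_state(field_, x0, horizon=horizon,
                                   **integrate_kwargs)
        except IntegrationError:
            return None
        if not ss.stable or ss.marginal:
            return None
        outcomes.append(ss.state)
    return state_distance(outcomes[0], outcomes[1]) > CLUSTER_TOL


def is_bistable(
    model: ModelDefinition,
    params: ParameterSet,
    n_starts: int = 100,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
    **integrate_kwargs,
) -> bool:
    """Ensemble AND extreme-start evidence of >= 2 stable attractors.

    The conjunction is stricter than either probe alone; an inconclusive
    extreme-start test counts as not bistable.  The cheap two-run extreme
    probe runs first and short-circuits the multistart census whenever it
    already rules bistability out.
    """
    ext = extreme_init_test(model, params, horizon=horizon, **integrate_kwargs)
    if not ext:
        return False
    try:
        census = classify_attractors(
            model, params, n_starts=n_starts, seed=seed, horizon=horizon,
            **integrate_kwargs,
        )
    except RuntimeError:
        return False
    return census.n_attractors >= 2


def search_bistable_parameters(
    model: ModelDefinition,
    baseline: ParameterSet,
    budget: int,
    seed: int = 0,
    decades: float = 2.0,
    names: list[str] | None = None,
    n_starts: int = 20,
    horizon: float = DEFAULT_HORIZON,
    **integrate_kwargs,
) -> list[ParameterSet]:
    """Random log-uniform parameter-space search for bistable regimes.

    Draws ``budget`` parameter sets over ±``decades`` around baseline
    (optionally restricted to ``names``) and returns those classified
    bistable.  An empty result is a valid outcome.  Seeds for the embedded
    multistart ensembles are split deterministically from ``seed``.
    """
    if budget < 0:
        raise ValueError("budget must be >= 0")
    if budget == 0:
        return []
    candidates = sample_parameter_sets(baseline, decades, budget, seed=seed,
                                       names=names)
    sub_seeds = spawn_seeds(seed, budget)
    hits = []
    for ps, s in zip(candidates, sub_seeds):
        if is_bistable(model, ps, n_starts=n_starts, seed=s, horizon=horizon,
                       **integrate_kwargs):
            hits.append(ps)
    return hits
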