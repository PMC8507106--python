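"""Generators for every synthetic input the analysis consumes.

Random initial-condition ensembles (the multistart census), single-parameter
percentage perturbations (robustness grids) and log-uniform parameter-set
samples (bistability search) all come from here, each driven by an explicit
seed.  One root seed per experiment is split into independent per-task
streams with :func:`spawn_seeds`, so downstream results are reproducible
cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_core import ParameterSet

__all__ = [
    "InitialConditionSpec",
    "draw_initial_conditions",
    "perturb",
    "sample_parameter_sets",
    "spawn_seeds",
    "DEFAULT_LO",
    "DEFAULT_HI",
]

#: default per-species concentration bounds for random initialisation, nM
#: (five decades, bracketing every attractor of the bundled models)
DEFAULT_LO = 1.0e-2
DEFAULT_HI = 1.0e3


@dataclass
class InitialConditionSpec:
    """Per-species sampling bounds for random initial states.

    ``bounds`` is a list of ``(lo, hi)`` pairs, one per state variable, in
    model species order.  ``scale`` is ``"logarithmic"`` (default — species
    levels span decades) or ``"linear"``.
    """

    bounds: list[tuple[float, float]]
    scale: str = "logarithmic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "logarithmic"):
            raise ValueError(f"unknown scale {self.scale!r}")
        for i, (lo, hi) in enumerate(self.bounds):
            if lo > hi:
                raise ValueError(f"species {i}: lo {lo} > hi {hi}")
            if self.scale == "logarithmic" and lo <= 0:
                raise ValueError(
                    f"species {i}: logarithmic scale needs lo > 0, got {lo}"
                )
            if self.scale == "linear" and lo < 0:
                raise ValueError(f"species {i}: negative lower bound {lo}")

    @classmethod
    def default(cls, dimension: int, seed: int = 0,
                lo: float = DEFAULT_LO, hi: float = DEFAULT_HI,
                scale: str = "logarithmic") -> "InitialConditionSpec":
        return cls(bounds=[(lo, hi)] * dimension, scale=scale, seed=seed)


def draw_initial_conditions(spec: InitialConditionSpec, n: int) -> np.ndarray:
    """Draw ``n`` random initial-state vectors, shape ``(n, dimension)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    u = rng.random((n, lo.size))
    if spec.scale == "logarithmic":
        return 10.0 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo)))
    return lo + u * (hi - lo)


def perturb(params: ParameterSet, name: str, percent: float) -> ParameterSet:
    """Multiplicative single-parameter perturbation: k -> k*(1 + percent/100)."""
    if name not in params:
        raise KeyError(f"unknown parameter {name!r}")
    if percent <= -100:
        raise ValueError("percent must be > -100 (value must stay positive)")
    out = params.copy()
    out.values[name] = params[name] * (1.0 + percent / 100.0)
    out.provenance = f"{params.provenance} | {name} {percent:+g}%"
    return out


def sample_parameter_sets(
    baseline: ParameterSet,
    decades: float,
    n: int,
    seed: int = 0,
    names: list[str] | None = None,
) -> list[ParameterSet]:
    """Log-uniform parameter-set samples over ±``decades`` around baseline.

    Each sampled parameter k is drawn as ``k_base * 10**u`` with
    ``u ~ U(-decades, +decades)``, independently per parameter and per set.
    ``names`` restricts sampling to a subset (others stay at baseline).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not decades >= 0:
        raise ValueError("decades must be >= 0")
    rng = np.random.default_rng(seed)
    which = names if names is not None else baseline.names()
    out = []
    for i in range(n):
        ps = baseline.copy()
        u = rng.uniform(-decades, decades, size=len(which))
        for name, ui in zip(which, u):
            ps.values[name] = baseline[name] * 10.0 ** ui
        ps.provenance = f"search-derived (seed={seed}, draw={i})"
        out.append(ps)
    return out


def spawn_seeds(root_seed: int, n: int) -> list[int]:
    """Split one root seed into ``n`` independent 31-bit child seeds."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
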