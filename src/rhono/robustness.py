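"""Single-parameter robustness of bistability (percentage perturbation grids).

For every perturbable parameter and every percentage level, the parameter is
scaled by (1 ± level/100) — one at a time, everything else at baseline — and
the perturbed model is re-screened for bistability with the multistart +
extreme-start conjunction.  A parameter *retains* bistability at a level iff
both the + and the − perturbation are bistable (the stricter two-sided
reading; the raw signed outcomes are kept so the one-sided convention can be
recovered from the same matrix).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import perturbable_parameters
from .multistability import is_bistable
from .network_core import ModelDefinition, ParameterSet
from .simulation import DEFAULT_HORIZON
from .synthetic_inputs import perturb, spawn_seeds

__all__ = [
    "RobustnessMatrix",
    "single_parameter_robustness",
    "count_retaining",
    "DEFAULT_LEVELS",
]

#: default percentage grid (covers the 10-15% and 30% landmarks)
DEFAULT_LEVELS = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0)


class RobustnessMatrix:
    """Bistability-retention matrix: parameters × perturbation levels.

    ``signed[(name, level)]`` holds the raw outcome for one signed
    perturbation (True/False, or None for an inconclusive screen);
    ``retained(name, level)`` is the two-sided conjunction.
    """

    def __init__(self, parameter_names, levels, signed, baseline_bistable,
                 seed):
        self.parameter_names = list(parameter_names)
        self.levels = [float(l) for l in levels]
        self.signed = dict(signed)
        self.baseline_bistable = bool(baseline_bistable)
        self.seed = seed
        for name in self.parameter_names:
            for lv in self.levels:
                for s in (+1, -1):
                    key = (name, s * lv) if lv else (name, 0.0)
                    if key not in self.signed:
                        raise ValueError(f"missing cell {key}")

    def retained(self, name: str, level: float) -> bool | None:
        """Two-sided retention; None if either sign was inconclusive."""
        if level == 0:
            return self.signed[(name, 0.0)]
        plus = self.signed[(name, abs(level))]
        minus = self.signed[(name, -abs(level))]
        if plus is None or minus is None:
            return None
        return plus and minus

    def to_dataframe(self) -> pd.DataFrame:
        """Signed outcome table (rows = parameters, columns = signed levels)."""
        cols = sorted({lv for _, lv in self.signed}, key=lambda v: (abs(v), v))
        data = {
            c: [self.signed[(n, c)] for n in self.parameter_names]
            for c in cols
        }
        return pd.DataFrame(data, index=self.parameter_names)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.replace({True: "true", False: "false", None: "inconclusive"}
                   ).to_csv(path, index_label="parameter")


def single_parameter_robustness(
    model: ModelDefinition,
    params: ParameterSet,
    levels=DEFAULT_LEVELS,
    n_starts: int = 24,
    seed: int = 0,
    horizon: float = DEFAULT_HORIZON,
    parameter_names: list[str] | None = None,
    **integrate_kwargs,
) -> RobustnessMatrix:
    """Perturb each parameter by each ±level and re-screen for bistability.

    The 0% column (always included) is the unperturbed baseline screen.
    Per-cell multistart seeds are split deterministically from ``seed``, so
    the matrix is identical across repeated runs.  A cell whose screen
    raises nonconvergence is recorded as None ("inconclusive") rather than
    False.
    """
    names = parameter_names or perturbable_parameters(params)
    missing = [n for n in names if n not in params]
    if missing:
        raise KeyError(f"unknown parameters: {missing}")
    levels = sorted({abs(float(l)) for l in levels} - {0.0})

    cells = [(n, s * l) for n in names for l in levels for s in (+1, -1)]
    sub_seeds = spawn_seeds(seed, len(cells) + 1)

    def screen(ps, cell_seed):
        try:
            return is_bistable(model, ps, n_starts=n_starts, seed=cell_seed,
                               horizon=horizon, **integrate_kwargs)
        except Exception:
            return None

    baseline = screen(params, sub_seeds[-1])
    signed = {}
    for name in names:
        signed[(name, 0.0)] = baseline
    for (name, slevel), cell_seed in zip(cells, sub_seeds):
        signed[(name, float(slevel))] = screen(
            perturb(params, name, slevel), cell_seed
        )
    return RobustnessMatrix(names, [0.0] + levels, signed,
                            bool(baseline), seed)


def count_retaining(matrix: RobustnessMatrix, level: float) -> int:
    """Number of parameters retaining bistability at ``level`` (both signs)."""
    if float(abs(level)) not in matrix.levels:
        raise ValueError(f"level {level} not in matrix levels {matrix.levels}")
    return sum(
        1 for n in matrix.parameter_names
        if matrix.retained(n, abs(level)) is True
    )
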