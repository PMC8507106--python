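"""One-parameter equilibrium continuation, fold detection, hysteresis sweeps.

The continuation is a standard pseudo-arclength predictor-corrector:
tangents come from the null space of the bordered Jacobian ``[J_x | F_p]``,
the corrector is Newton on the rate field plus the arclength constraint, and
steps adapt between bounds.  Folds (saddle-node points) are detected by a
sign change of the tangent's parameter component and polished to machine
precision with a bordered fold system ``[F; J v; c·v - 1] = 0``.

:func:`hysteresis_sweep` provides an independent quasi-static cross-check:
the parameter is stepped up and then down, integrating to steady state at
every step from the previous endpoint; the up/down discrepancy delimits the
bistable interval and must agree with continuation within one step width.

Branches are anchored at both ends of the requested range (and merged), so
an interior fold pair cannot be missed on an S-shaped diagram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.optimize import root as _root

from .network_core import ModelDefinition, ParameterSet, assemble
from .simulation import (
    DEFAULT_HORIZON,
    STABILITY_MARGIN,
    IntegrationError,
    find_steady_state,
)
from .multistability import CLUSTER_TOL, state_distance

__all__ = [
    "BranchPoint",
    "BifurcationDiagram",
    "ContinuationError",
    "continue_branch",
    "hysteresis_sweep",
    "no_range_across_regime",
]


class ContinuationError(RuntimeError):
    """No usable steady-state anchor, or the corrector collapsed immediately."""


@dataclass
class BranchPoint:
    parameter: float
    state: np.ndarray
    stable: bool


@dataclass
class BifurcationDiagram:
    """Steady-state branches vs one swept parameter."""

    parameter_name: str
    branches: list[list[BranchPoint]]
    folds: list[tuple[float, np.ndarray]]
    bistable_interval: tuple[float, float] | None
    species_names: list[str] = dfield(default_factory=list)
    warnings: list[str] = dfield(default_factory=list)

    @property
    def parameter_values(self) -> np.ndarray:
        return np.array([bp.parameter for br in self.branches for bp in br])

    def stable_points(self) -> list[BranchPoint]:
        return [bp for br in self.branches for bp in br if bp.stable]

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = []
        for bi, br in enumerate(self.branches):
            for bp in br:
                rows.append(
                    [bi, bp.parameter, bp.stable] + list(bp.state)
                )
        cols = ["branch", self.parameter_name, "stable"] + (
            self.species_names or
            [f"x{i}" for i in range(len(rows[0]) - 3)]
        )
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)

    def summary_json(self) -> str:
        return json.dumps(
            {
                "parameter": self.parameter_name,
                "folds": [[p, s.tolist()] for p, s in self.folds],
                "bistable_interval": self.bistable_interval,
                "n_branches": len(self.branches),
                "warnings": self.warnings,
            },
            indent=1,
        )


class _ParametricField:
    """Rate field with one designated free parameter; caches assembly."""

    def __init__(self, model: ModelDefinition, params: ParameterSet,
                 parameter_name: str):
        if parameter_name not in params:
            raise KeyError(f"unknown parameter {parameter_name!r}")
        self.model = model
        self.params = params
        self.pname = parameter_name
        self._cache_p: float | None = None
        self._cache_field = None
        self.dimension = len(model.state_species())
        self.species_names = model.state_species()

    def field(self, p: float):
        if p != self._cache_p:
            ps = self.params.copy()
            ps.values[self.pname] = float(p)
            self._cache_field = assemble(self.model, ps)
            self._cache_p = float(p)
        return self._cache_field

    def F(self, x: np.ndarray, p: float) -> np.ndarray:
        return self.field(p)(0.0, x)

    def Jx(self, x: np.ndarray, p: float) -> np.ndarray:
        return self.field(p).jacobian(x)

    def Fp(self, x: np.ndarray, p: float, h_rel: float = 1e-6) -> np.ndarray:
        h = h_rel * (abs(p) + 1e-12)
        return (self.F(x, p + h) - self.F(x, p - h)) / (2 * h)


def _tangent(pf: _ParametricField, x, p, sx, sp, prev=None):
    """Unit tangent of the equilibrium curve in scaled (x, p) coordinates."""
    A = np.hstack([pf.Jx(x, p) / sx, (pf.Fp(x, p) / sp)[:, None]])
    # null vector via SVD of the n x (n+1) bordered Jacobian
    _, _, vt = np.linalg.svd(A)
    t = vt[-1]
    t = t / np.linalg.norm(t)
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


def _correct(pf, u_pred, t, sx, sp, tol=1e-10, max_iter=8):
    """Newton corrector with the fixed arclength (hyperplane) constraint."""
    n = pf.dimension
    u = u_pred.copy()
    for _ in range(max_iter):
        x, p = u[:n] * sx, u[n] * sp
        Fv = pf.F(x, p)
        res = np.max(np.abs(Fv))
        if res < tol * (1.0 + np.max(np.abs(x))):
            return u, True
        A = np.zeros((n + 1, n + 1))
        A[:n, :n] = pf.Jx(x, p) * sx
        A[:n, n] = pf.Fp(x, p) * sp
        A[n, :] = t
        rhs = np.concatenate([-Fv, [0.0]])
        try:
            du = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            return u, False
        u = u + du
        if not np.all(np.isfinite(u)):
            return u_pred, False
    x, p = u[:n] * sx, u[n] * sp
    ok = np.max(np.abs(pf.F(x, p))) < 1e2 * tol * (1.0 + np.max(np.abs(x)))
    return u, ok


def _stable(pf, x, p) -> bool:
    eig = np.linalg.eigvals(pf.Jx(x, p))
    return float(np.max(eig.real)) < -STABILITY_MARGIN


def _refine_fold(pf, x_guess, p_guess):
    """Polish a saddle-node with the bordered system [F; J v; c·v - 1].

    Solved by Newton iteration in scaled coordinates (states scaled by their
    guess magnitude, parameter by its guess), with finite-difference
    derivatives of the full bordered system.
    """
    n = pf.dimension
    sx = 1.0 + float(np.max(np.abs(x_guess)))
    sp = abs(p_guess) + 1e-12
    J = pf.Jx(x_guess, p_guess)
    _, _, vt = np.linalg.svd(J)
    v0 = vt[-1]
    c = v0.copy()

    def G(z):
        x, p, v = z[:n] * sx, z[n] * sp, z[n + 1:]
        return np.concatenate([
            pf.F(x, p) / sx,
            (pf.Jx(x, p) @ v),
            [c @ v - 1.0],
        ])

    z = np.concatenate([x_guess / sx, [p_guess / sp], v0])
    best_z, best_res = z.copy(), np.inf
    m = 2 * n + 1
    for _ in range(30):
        Gz = G(z)
        if np.max(np.abs(Gz)) < 1e-11:
            break
        Jg = np.empty((m, m))
        for j in range(m):
            h = 1e-7 * (1.0 + abs(z[j]))
            zp, zm = z.copy(), z.copy()
            zp[j] += h
            zm[j] -= h
            Jg[:, j] = (G(zp) - G(zm)) / (2 * h)
        try:
            dz = np.linalg.solve(Jg, -Gz)
        except np.linalg.LinAlgError:
            return None
        # undamped Newton step; fold iterations are non-monotone in the
        # residual norm, so keep the best iterate rather than damping
        z = z + dz
        if not np.all(np.isfinite(z)):
            break
        r_new = np.max(np.abs(G(z)))
        if r_new < best_res:
            best_res, best_z = r_new, z.copy()
        if best_res < 1e-12:
            break
    if best_res < 1e-8:
        return float(best_z[n] * sp), best_z[:n] * sx
    return None


def _anchor(pf, p, x0=None, horizon=DEFAULT_HORIZON):
    if x0 is None:
        x0 = np.ones(pf.dimension)
    try:
        ss = find_steady_state(pf.field(p), np.asarray(x0, float),
                               horizon=horizon)
    except IntegrationError:
        return None
    if ss.residual_norm > 1e-6 * (1.0 + np.max(np.abs(ss.state))):
        return None
    return ss.state


def continue_branch(
    model: ModelDefinition,
    params: ParameterSet,
    parameter_name: str,
    p_range: tuple[float, float],
    initial_step: float = 0.01,
    min_step: float = 1e-5,
    max_step: float = 0.05,
    max_points: int = 1500,
    anchor_states: tuple | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> BifurcationDiagram:
    """Trace the steady-state manifold across ``p_range`` through any folds.

    Step sizes are fractions of the parameter range (adaptive halving on
    corrector failure, doubling after fast success, bounded to
    ``[min_step, max_step]``).  The curve is anchored at both range
    endpoints; the second anchor is only traced if it does not already lie
    on the first branch, so a single S-shaped curve is traced exactly once.

    Raises
    ------
    ContinuationError
        If no steady-state anchor can be located at either endpoint.
    """
    lo, hi = float(p_range[0]), float(p_range[1])
    if not lo < hi:
        raise ValueError("range.lo must be < range.hi")
    pf = _ParametricField(model, params, parameter_name)
    n = pf.dimension
    width = hi - lo
    warnings: list[str] = []

    anchors = []
    x_lo0 = x_hi0 = None
    if anchor_states is not None:
        x_lo0, x_hi0 = anchor_states
    x_lo = _anchor(pf, lo, x_lo0, horizon)
    x_hi = _anchor(pf, hi, x_hi0, horizon)
    if x_lo is None and x_hi is None:
        raise ContinuationError(
            f"no anchor: no steady state located at either end of "
            f"{parameter_name} in [{lo}, {hi}]"
        )
    if x_lo is not None:
        anchors.append((x_lo, lo, +1.0))
    if x_hi is not None:
        anchors.append((x_hi, hi, -1.0))

    branches: list[list[BranchPoint]] = []
    for x_a, p_a, direction in anchors:
        # skip the second anchor if it already lies on a traced branch
        on_existing = False
        for br in branches:
            for bp in br:
                if (abs(bp.parameter - p_a) < 0.03 * width
                        and state_distance(bp.state, x_a) < 100 * CLUSTER_TOL):
                    on_existing = True
                    break
            if on_existing:
                break
        if on_existing:
            continue

        sx = 1.0 + float(np.max(np.abs(x_a)))
        sp = width
        u = np.concatenate([x_a / sx, [p_a / sp]])
        t = _tangent(pf, x_a, p_a, sx, sp)
        if t[n] * direction < 0:
            t = -t
        ds = initial_step
        branch = [BranchPoint(p_a, x_a.copy(), _stable(pf, x_a, p_a))]
        margin = 0.02 * width
        for _ in range(max_points):
            u_pred = u + ds * t
            u_new, ok = _correct(pf, u_pred, t, sx, sp)
            if not ok:
                ds *= 0.5
                if ds < min_step:
                    warnings.append(
                        f"step-size collapse at {parameter_name}="
                        f"{u[n] * sp:.6g}; partial branch returned"
                    )
                    break
                continue
            x_new, p_new = u_new[:n] * sx, u_new[n] * sp
            if p_new < lo - margin or p_new > hi + margin:
                if lo - 0.1 * width < p_new < hi + 0.1 * width:
                    branch.append(BranchPoint(p_new, x_new.copy(),
                                              _stable(pf, x_new, p_new)))
                break
            branch.append(BranchPoint(p_new, x_new.copy(),
                                      _stable(pf, x_new, p_new)))
            t_new = _tangent(pf, x_new, p_new, sx, sp, prev=t)
            u, t = u_new, t_new
            ds = min(ds * 1.3, max_step)
        branches.append(branch)

    # fold detection: turning points of p along each branch
    folds: list[tuple[float, np.ndarray]] = []
    for br in branches:
        ps = np.array([bp.parameter for bp in br])
        dp = np.diff(ps)
        for i in np.nonzero(np.sign(dp[:-1]) * np.sign(dp[1:]) < 0)[0]:
            res = _refine_fold(pf, br[i + 1].state, br[i + 1].parameter)
            if res is not None:
                p_f, x_f = res
                if lo - 0.02 * width <= p_f <= hi + 0.02 * width and not any(
                    abs(p_f - p0) < 1e-8 * max(1.0, abs(p0))
                    and state_distance(x_f, x0) < 10 * CLUSTER_TOL
                    for p0, x0 in folds
                ):
                    folds.append((p_f, x_f))
            else:
                warnings.append(
                    f"fold refinement failed near {parameter_name}="
                    f"{br[i + 1].parameter:.6g}"
                )
    folds.sort(key=lambda fx: fx[0])

    interval = _stable_coexistence_interval(branches, lo, hi)
    if interval is not None and len(folds) >= 2:
        # snap coverage endpoints to the refined fold positions when close
        snap = max(5 * (hi - lo) / 800, 2.0 * max_step * (hi - lo))
        fps = [pf_ for pf_, _ in folds]
        s_lo = min(fps, key=lambda q: abs(q - interval[0]))
        s_hi = min(fps, key=lambda q: abs(q - interval[1]))
        interval = (
            s_lo if abs(s_lo - interval[0]) < snap else interval[0],
            s_hi if abs(s_hi - interval[1]) < snap else interval[1],
        )
        interval = (max(interval[0], lo), min(interval[1], hi))
    return BifurcationDiagram(
        parameter_name=parameter_name,
        branches=branches,
        folds=folds,
        bistable_interval=interval,
        species_names=pf.species_names,
        warnings=warnings,
    )


def _stable_coexistence_interval(branches, lo, hi, n_grid=801):
    """Parameter range where >= 2 distinct stable branch segments coexist."""
    grid = np.linspace(lo, hi, n_grid)
    counts = np.zeros(n_grid, dtype=int)
    states_at: list[list[np.ndarray]] = [[] for _ in range(n_grid)]
    for br in branches:
        for a, b in zip(br[:-1], br[1:]):
            if not (a.stable and b.stable):
                continue
            p1, p2 = sorted((a.parameter, b.parameter))
            mask = (grid >= p1) & (grid <= p2)
            for gi in np.nonzero(mask)[0]:
                # linear interpolation of the state onto the grid point
                if abs(b.parameter - a.parameter) < 1e-300:
                    s = a.state
                else:
                    w = (grid[gi] - a.parameter) / (b.parameter - a.parameter)
                    s = (1 - w) * a.state + w * b.state
                if all(state_distance(s, s0) > 10 * CLUSTER_TOL
                       for s0 in states_at[gi]):
                    states_at[gi].append(s)
                    counts[gi] += 1
    bist = counts >= 2
    if not bist.any():
        return None
    return (float(grid[bist][0]), float(grid[bist][-1]))


def hysteresis_sweep(
    model: ModelDefinition,
    params: ParameterSet,
    parameter_name: str,
    p_range: tuple[float, float],
    n_steps: int = 60,
    x0: np.ndarray | None = None,
    horizon: float = DEFAULT_HORIZON,
) -> BifurcationDiagram:
    """Quasi-static up-then-down parameter sweep.

    At each step the system is re-integrated to steady state from the
    previous step's endpoint.  The up- and down-sweep branches disagree
    exactly over the bistable interval; the reported interval endpoints are
    midpoints between the last agreeing and first disagreeing steps, so the
    method is accurate to one step width.
    """
    lo, hi = float(p_range[0]), float(p_range[1])
    if not lo < hi:
        raise ValueError("range.lo must be < range.hi")
    pf = _ParametricField(model, params, parameter_name)
    grid = np.linspace(lo, hi, int(n_steps))
    warnings: list[str] = []

    def sweep(ps):
        x = np.ones(pf.dimension) if x0 is None else np.asarray(x0, float)
        out = []
        for p in ps:
            try:
                ss = find_steady_state(pf.field(p), x, horizon=horizon,
                                       nonnegative=False)
                x = ss.state
                out.append(BranchPoint(float(p), x.copy(), bool(ss.stable)))
            except IntegrationError:
                warnings.append(f"nonconvergence at {parameter_name}={p:.6g}")
        return out

    up = sweep(grid)
    down = sweep(grid[::-1])
    down_by_p = {bp.parameter: bp for bp in down}

    differ = np.array([
        state_distance(bp.state, down_by_p[bp.parameter].state) > 10 * CLUSTER_TOL
        if bp.parameter in down_by_p else False
        for bp in up
    ])
    interval = None
    folds: list[tuple[float, np.ndarray]] = []
    if differ.any():
        idx = np.nonzero(differ)[0]
        i0, i1 = idx[0], idx[-1]
        p_lo = grid[i0] if i0 == 0 else 0.5 * (grid[i0 - 1] + grid[i0])
        p_hi = grid[i1] if i1 == len(grid) - 1 else 0.5 * (grid[i1] + grid[i1 + 1])
        interval = (float(p_lo), float(p_hi))
        folds = [(float(p_lo), up[i0].state.copy()),
                 (float(p_hi), down_by_p[grid[i1]].state.copy())]

    return BifurcationDiagram(
        parameter_name=parameter_name,
        branches=[up, down],
        folds=folds,
        bistable_interval=interval,
        species_names=pf.species_names,
        warnings=warnings,
    )


def no_range_across_regime(
    diagram: BifurcationDiagram,
    species: str = "NO",
) -> tuple[float, float] | None:
    """Extremes of the stable-branch levels of one species over the bistable interval.

    Returns ``None`` (empty signal) when the diagram has no bistable
    interval.
    """
    if species not in diagram.species_names:
        raise KeyError(f"diagram has no {species!r} coordinate")
    if diagram.bistable_interval is None:
        return None
    j = diagram.species_names.index(species)
    lo, hi = diagram.bistable_interval
    vals = [bp.state[j] for bp in diagram.stable_points()
            if lo <= bp.parameter <= hi]
    if not vals:
        return None
    return (float(min(vals)), float(max(vals)))
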