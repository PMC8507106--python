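"""Equilibrium continuation, fold refinement, hysteresis cross-check."""

import numpy as np
import pytest

from rhono import assemble, integrate
from rhono.bifurcation import (
    continue_branch,
    hysteresis_sweep,
    no_range_across_regime,
)
from rhono.multistability import state_distance

from oracles import CUBIC_FOLD, cubic_equilibria


class TestLinearSweep:
    def test_single_stable_branch_no_folds(self, birth_death):
        model, params = birth_death  # dx/dt = s - d*x, sweep s
        d = continue_branch(model, params, "s", (0.5, 4.0))
        assert d.folds == []
        assert d.bistable_interval is None
        for bp in d.stable_points():
            assert bp.state[0] == pytest.approx(bp.parameter / 0.5, rel=1e-6)

    def test_monostable_hysteresis_up_down_identical(self, birth_death):
        model, params = birth_death
        h = hysteresis_sweep(model, params, "s", (0.5, 4.0), n_steps=21)
        assert h.bistable_interval is None
        up, down = h.branches
        for bp in up:
            mate = next(b for b in down if b.parameter == bp.parameter)
            assert state_distance(bp.state, mate.state) < 1e-6


class TestCubicNormalForm:
    def test_folds_match_closed_form(self, cubic_model):
        model, params = cubic_model
        d = continue_branch(model, params, "r", (-0.6, 0.6),
                            anchor_states=(np.array([2.0]), np.array([2.0])))
        assert len(d.folds) == 2
        fold_ps = sorted(p for p, _ in d.folds)
        assert fold_ps[0] == pytest.approx(-CUBIC_FOLD, abs=1e-4)
        assert fold_ps[1] == pytest.approx(+CUBIC_FOLD, abs=1e-4)
        # fold states are the degenerate equilibria +/- 1/sqrt(3)
        states = sorted(x[0] for _, x in d.folds)
        assert states[0] == pytest.approx(-1 / np.sqrt(3), abs=1e-4)
        assert states[1] == pytest.approx(+1 / np.sqrt(3), abs=1e-4)

    def test_bistable_interval_equals_fold_pair(self, cubic_model):
        model, params = cubic_model
        d = continue_branch(model, params, "r", (-0.6, 0.6),
                            anchor_states=(np.array([2.0]), np.array([2.0])))
        assert d.bistable_interval == pytest.approx(
            (-CUBIC_FOLD, CUBIC_FOLD), abs=1e-4)

    def test_branch_points_satisfy_equilibrium_equation(self, cubic_model):
        model, params = cubic_model
        d = continue_branch(model, params, "r", (-0.6, 0.6),
                            anchor_states=(np.array([2.0]), np.array([2.0])))
        for bp in d.branches[0][::5]:
            eq = cubic_equilibria(bp.parameter)
            assert min(abs(eq - bp.state[0])) < 1e-6

    def test_hysteresis_jumps_bracket_folds_within_one_step(self, cubic_model):
        model, params = cubic_model
        n_steps = 61
        step = 1.2 / (n_steps - 1)
        h = hysteresis_sweep(model, params, "r", (-0.6, 0.6),
                             n_steps=n_steps, x0=np.array([2.0]))
        assert h.bistable_interval is not None
        assert abs(h.bistable_interval[0] - (-CUBIC_FOLD)) <= step
        assert abs(h.bistable_interval[1] - CUBIC_FOLD) <= step

    def test_interval_invariant_under_step_refinement(self, cubic_model):
        model, params = cubic_model
        anchors = (np.array([2.0]), np.array([2.0]))
        d1 = continue_branch(model, params, "r", (-0.6, 0.6),
                             initial_step=0.01, max_step=0.05,
                             anchor_states=anchors)
        d2 = continue_branch(model, params, "r", (-0.6, 0.6),
                             initial_step=0.005, max_step=0.025,
                             anchor_states=anchors)
        for a, b in zip(d1.bistable_interval, d2.bistable_interval):
            assert abs(a - b) < 0.01 * 1.2


@pytest.fixture(scope="module")
def ki1_diagram(initial_model):
    model, params = initial_model
    return continue_branch(model, params, "ki1", (0.001, 0.03),
                           horizon=1e5)


class TestFullNetworkSweep:
    def test_s_shape_two_folds_nonempty_interval(self, ki1_diagram):
        d = ki1_diagram
        assert len(d.folds) == 2
        lo, hi = d.bistable_interval
        assert 0.001 < lo < hi < 0.03
        # middle branch is unstable
        assert any(not bp.stable for br in d.branches for bp in br)

    def test_unstable_branch_points_repel(self, ki1_diagram, initial_model):
        """Integration from a perturbed unstable point leaves its
        neighbourhood and reaches a distinct stable state."""
        model, params = initial_model
        mid = [bp for br in ki1_diagram.branches for bp in br
               if not bp.stable and
               ki1_diagram.bistable_interval[0] < bp.parameter <
               ki1_diagram.bistable_interval[1]]
        bp = mid[len(mid) // 2]
        ps = params.copy()
        ps.values["ki1"] = bp.parameter
        f = assemble(model, ps)
        x_pert = np.clip(bp.state * 1.01, 0, None)
        traj = integrate(f, x_pert, horizon=1e5)
        assert state_distance(traj.final_state, bp.state) > 0.05

    def test_stable_branch_points_reconverge(self, ki1_diagram,
                                             initial_model):
        model, params = initial_model
        pts = [bp for bp in ki1_diagram.stable_points()][::10][:5]
        for bp in pts:
            ps = params.copy()
            ps.values["ki1"] = bp.parameter
            f = assemble(model, ps)
            x_pert = np.clip(bp.state * 1.01, 0, None)
            traj = integrate(f, x_pert, horizon=1e5)
            assert state_distance(traj.final_state, bp.state) < 1e-3

    def test_no_range_extraction(self, ki1_diagram):
        nr = no_range_across_regime(ki1_diagram)
        assert nr is not None
        lo, hi = nr
        assert 0 < lo < hi
        assert hi / lo > 3  # well-separated NO branches

    def test_no_range_requires_no_coordinate(self, cubic_model):
        model, params = cubic_model
        d = continue_branch(model, params, "r", (-0.6, 0.6),
                            anchor_states=(np.array([2.0]), np.array([2.0])))
        with pytest.raises(KeyError):
            no_range_across_regime(d)

    def test_monostable_diagram_empty_no_range(self, birth_death):
        model, params = birth_death
        d = continue_branch(model, params, "s", (0.5, 4.0))
        d.species_names = ["NO"]  # relabel the single coordinate
        assert no_range_across_regime(d) is None


class TestErrors:
    def test_invalid_range_rejected(self, birth_death):
        model, params = birth_death
        with pytest.raises(ValueError):
            continue_branch(model, params, "s", (2.0, 1.0))

    def test_unknown_parameter_rejected(self, birth_death):
        model, params = birth_death
        with pytest.raises(KeyError):
            continue_branch(model, params, "nope", (0.1, 1.0))
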