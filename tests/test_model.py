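"""Dynamics, integration, doubling times, and steady states."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chemosched as cs
from chemosched.model import first_passage_time


def gompertz_params():
    """Single-compartment configuration with an (effectively) frozen capacity."""
    return cs.ModelParams(lambda1=0.192, lambda2=1e-12, tau1=0.0, tau2=0.0,
                          mu=0.0, b=1e-12, d=1e-12, beta1=0.3, beta=0.1,
                          gamma=2.0)


class TestRHS:
    def test_matches_term_by_term_hand_evaluation(self, params):
        # independent evaluation of each term at (280, 20, 650), u=0.25, v=0.5
        n1, n2, k, u, v = 280.0, 20.0, 650.0, 0.25, 0.5
        log_ratio = math.log((n1 + n2) / k)
        expected = np.array([
            -0.192 * n1 * log_ratio - 2e-5 * n1 + 1e-5 * n2 - 0.3 * n1 * u,
            -0.096 * n2 * log_ratio + 2e-5 * n1 - 1e-5 * n2,
            5.85 * (n1 + n2) - 8.73e-3 * (n1 + n2) ** (2 / 3) * k
            - 0.1 * k * u - 2.0 * k * v,
        ])
        got = cs.rhs(cs.TumorState(n1, n2, k), u, v, params)
        assert got == pytest.approx(expected, rel=1e-12)
        # frozen magnitudes from the independent evaluation
        assert got == pytest.approx([20.5613, 1.4899, 834.4527], abs=5e-4)

    def test_growth_vanishes_when_tumor_fills_capacity(self, params):
        p = params.replace(tau1=0.0, tau2=0.0)
        dn1, dn2, _ = cs.rhs(cs.TumorState(100, 100, 200), 0.0, 0.0, p)
        assert dn1 == 0.0 and dn2 == 0.0

    def test_rejects_nonpositive_state(self, params):
        with pytest.raises(ValueError, match="positive"):
            cs.rhs((280.0, -1.0, 650.0), 0.0, 0.0, params)

    def test_jacobian_matches_finite_differences(self, params, rng):
        x = np.array([280.0, 20.0, 650.0])
        jac = cs.rhs_jacobian(x, 0.25, 0.5, params)
        eps = 1e-6
        for j in range(3):
            step = np.zeros(3)
            step[j] = eps * x[j]
            fd = (cs.rhs(x + step, 0.25, 0.5, params)
                  - cs.rhs(x - step, 0.25, 0.5, params)) / (2 * step[j])
            assert jac[:, j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestSimulate:
    def test_matches_gompertz_closed_form(self):
        p = gompertz_params()
        x0 = cs.TumorState(280.0, 1e-8, 650.0)
        t_eval = np.linspace(0.0, 20.0, 41)
        traj = cs.simulate(p, x0, cs.DoseSchedule.constant(0.0, 0.0, 20.0),
                           rel_tol=1e-8, abs_tol=1e-12, t_eval=t_eval)
        decay = np.exp(-p.lambda1 * traj.times)
        closed = 650.0 ** (1 - decay) * 280.0 ** decay
        assert np.max(np.abs(traj.n1 / closed - 1)) < 1e-5

    def test_zero_length_span_returns_initial_point(self, params, initial):
        traj = cs.simulate(params, initial, cs.DoseSchedule.constant(0.3, 0.5),
                           t_span=(0.0, 0.0))
        assert traj.times.tolist() == [0.0]
        assert traj.final_state == initial

    def test_mutation_flux_conserves_total_volume(self):
        # with negligible proliferation and no kill term, the mutation terms
        # cancel pairwise and N1+N2 stays constant
        p = cs.ModelParams(lambda1=1e-12, lambda2=1e-12, tau1=5e-3, tau2=2e-3,
                           beta1=0.0, beta=0.0)
        x0 = cs.TumorState(280.0, 20.0, 650.0)
        traj = cs.simulate(p, x0, cs.DoseSchedule.constant(0.0, 0.0, 200.0),
                           rel_tol=1e-9, abs_tol=1e-12)
        assert np.max(np.abs(traj.total - 300.0)) < 1e-5
        # and the flux moves mass toward the resistant compartment
        assert traj.n2[-1] > traj.n2[0]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        u=st.lists(st.floats(0, 1), min_size=1, max_size=6),
        v=st.floats(0, 1),
        n1=st.floats(1.0, 5000.0),
        n2=st.floats(1.0, 5000.0),
        k=st.floats(50.0, 20000.0),
    )
    def test_positivity_under_any_admissible_schedule(self, u, v, n1, n2, k):
        traj = cs.simulate(cs.NOMINAL_PARAMS, cs.TumorState(n1, n2, k),
                           cs.DoseSchedule(np.array(u), v, horizon=30.0))
        assert traj.n1.min() > 0 and traj.n2.min() > 0 and traj.k.min() > 0


class TestDoublingTime:
    def test_formula_direct_evaluation(self):
        t = cs.doubling_time_formula(0.192, 17000.0, 300.0)
        assert t == pytest.approx(math.log(2) / (0.192 * math.log(17000 / 300)),
                                  rel=1e-12)
        assert 24 * t == pytest.approx(21.46, abs=0.01)

    def test_formula_reductions(self):
        assert cs.doubling_time_formula(1.0, 1000.0, 500.0) == pytest.approx(1.0)
        assert cs.doubling_time_formula(0.5, 17000.0, 300.0) == pytest.approx(
            2 * cs.doubling_time_formula(1.0, 17000.0, 300.0))
        with pytest.raises(ValueError):
            cs.doubling_time_formula(0.1, 300.0, 300.0)

    def test_numeric_first_passage_from_nominal_start(self, params, initial):
        hours = cs.doubling_time_numeric(params, initial)
        # cross-check against an independent direct-event integration
        t = first_passage_time(params, initial,
                               cs.DoseSchedule.constant(0.0, 0.0, 100.0),
                               600.0, 100.0)
        assert hours == pytest.approx(24 * t, abs=1e-3)

    def test_not_reached_at_saturating_volume(self, params):
        report = cs.find_steady_state(params, 0.0, 0.0,
                                      cs.TumorState(100.0, 16000.0, 17000.0))
        assert cs.doubling_time_numeric(params, report.state,
                                        cap_days=50.0) is None

    def test_rescaling_proliferation_rescales_doubling_time(self):
        p = gompertz_params()
        x0 = cs.TumorState(100.0, 1e-8, 650.0)
        slow = cs.doubling_time_numeric(p, x0)
        fast = cs.doubling_time_numeric(
            p.replace(lambda1=2 * p.lambda1, lambda2=2 * p.lambda2), x0)
        assert slow == pytest.approx(2 * fast, rel=1e-4)


class TestSteadyState:
    def test_untreated_single_compartment_closed_form(self, params):
        # tau1 = tau2 = 0: equilibrium requires N = K and b = d N^(2/3),
        # i.e. total volume ((b - mu)/d)^(3/2), independent of the split
        p = params.replace(tau1=0.0, tau2=0.0)
        report = cs.find_steady_state(p, 0.0, 0.0,
                                      cs.TumorState(17000.0, 10.0, 17000.0))
        expected = ((p.b - p.mu) / p.d) ** 1.5
        assert report.state.total == pytest.approx(expected, rel=1e-6)
        assert report.state.k == pytest.approx(expected, rel=1e-6)

    def test_residual_below_tolerance_whenever_converged(self, params):
        report = cs.find_steady_state(params, 0.25, 0.5,
                                      cs.TumorState(1000.0, 5000.0, 8000.0))
        assert report.residual_norm < 1e-9

    def test_treated_equilibrium_is_attractive_and_resistant(self, params):
        report = cs.find_steady_state(params, 0.25, 0.5,
                                      cs.TumorState(1000.0, 5000.0, 8000.0))
        assert report.stable
        # the surviving tumor at equilibrium is resistant-dominated
        assert report.state.n2 > report.state.n1
        # simulating from a nearby state contracts toward the equilibrium
        x_star = report.state.as_array()
        start = cs.TumorState.from_array(x_star * 1.05)
        traj = cs.simulate(params, start,
                           cs.DoseSchedule.constant(0.25, 0.5, 400.0))
        final_gap = np.abs(traj.final_state.as_array() / x_star - 1).max()
        assert final_gap < 1e-3
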