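"""Transcription, NLP solution structure, and schedule diagnostics."""

import itertools

import numpy as np
import pytest

import chemosched as cs


def small_settings(m=20, **kw):
    defaults = dict(n_intervals=m, multistart=(0.0, 0.5, 1.0), restarts=1)
    defaults.update(kw)
    return cs.TranscriptionSettings(**defaults)


class TestTranscription:
    def test_problem_dimensions(self, params, initial, weights):
        prob = cs.transcribe(params, initial, weights, 0.5,
                             small_settings(m=50))
        assert prob.n_control_vars == 50
        assert prob.n_state_vars == 3 * 51
        assert prob.n_equality_constraints == 3 * 50
        assert prob.n_control_bounds == 50

    def test_single_euler_step_by_hand(self, params, initial, weights):
        prob = cs.transcribe(params, initial, weights, 0.5,
                             small_settings(m=2, horizon=14.0))
        u = np.array([0.25, 0.25])
        states = prob.states(u)
        h = 7.0
        expected = initial.as_array() + h * cs.rhs(initial, 0.25, 0.5, params)
        assert states[1] == pytest.approx(expected, rel=1e-12)

    def test_adjoint_gradient_matches_finite_differences(self, highsens_params,
                                                         initial, weights):
        prob = cs.transcribe(highsens_params, initial, weights, 0.5,
                             small_settings(m=15))
        u = np.linspace(0.1, 0.9, 15)
        _, grad = prob.objective(u)
        eps = 1e-7
        for k in (0, 7, 14):
            up, um = u.copy(), u.copy()
            up[k] += eps
            um[k] -= eps
            fd = (prob.objective(up)[0] - prob.objective(um)[0]) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_euler_states_converge_linearly_to_rk45(self, params, initial):
        schedule = cs.DoseSchedule.constant(0.3, 0.5, horizon=14.0)
        reference = cs.simulate(params, initial, schedule, rel_tol=1e-10,
                                abs_tol=1e-12).final_state.as_array()
        w = cs.ObjectiveWeights()
        errs = []
        for m in (100, 200, 400, 800):
            prob = cs.transcribe(params, initial, w, 0.5, small_settings(m=m))
            final = prob.states(np.full(m, 0.3))[-1]
            errs.append(np.max(np.abs(final / reference - 1)))
        for coarse, fine in zip(errs[:-1], errs[1:]):
            assert coarse / fine == pytest.approx(2.0, rel=0.25)


class TestSolve:
    def test_zero_weights_make_any_control_optimal(self, params, initial):
        w = cs.ObjectiveWeights(omega1=0, omega2=0, eta1=0, eta2=0, xi=0,
                                epsilon=10.0, theta=0)
        sol = cs.solve_ocp(cs.transcribe(params, initial, w, 0.5,
                                         small_settings()))
        assert sol.objective.total == 0.0

    def test_costly_useless_drug_is_never_given(self, params, initial):
        p = params.replace(beta1=0.0, beta=0.0)
        w = cs.ObjectiveWeights(omega1=0, omega2=0, eta1=0, eta2=0, xi=0,
                                epsilon=10.0, theta=1.0)
        sol = cs.solve_ocp(cs.transcribe(p, initial, w, 0.5, small_settings()))
        assert sol.control.max() < 1e-8

    def test_dynamics_residual_is_zero_by_construction(self, ocp_solution_v05,
                                                       highsens_params,
                                                       initial, weights):
        prob = cs.transcribe(highsens_params, initial, weights, 0.5)
        assert prob.dynamics_residual(ocp_solution_v05.control,
                                      ocp_solution_v05.states) == 0.0

    def test_bang_singular_bang_structure(self, ocp_solution_v05):
        u = ocp_solution_v05.control
        assert u[:20].min() > 0.99          # starts at full dose
        assert u[-5:].min() > 0.99          # ends at full dose
        arcs = ocp_solution_v05.singular
        assert arcs and arcs.segments[0][1] - arcs.segments[0][0] > 5.0

    def test_beats_reference_constant_controls(self, ocp_solution_v05,
                                               highsens_params, initial,
                                               weights):
        prob = cs.transcribe(highsens_params, initial, weights, 0.5)
        j_opt = ocp_solution_v05.objective.total
        j_mtd, _ = prob.objective(np.ones(400))
        mean_level = ocp_solution_v05.control.mean()
        j_mean, _ = prob.objective(np.full(400, mean_level))
        assert j_opt <= j_mtd
        assert j_opt <= j_mean

    def test_beats_exhaustive_three_segment_bang_bang(self, highsens_params,
                                                      initial, weights):
        # brute-force oracle: every bang-bang control with at most three
        # segments on a coarse grid, both polarities
        m = 20
        prob = cs.transcribe(highsens_params, initial, weights, 0.5,
                             small_settings(m=m, horizon=14.0))
        best = np.inf
        for i, j in itertools.combinations(range(m + 1), 2):
            for levels in ((1.0, 0.0, 1.0), (0.0, 1.0, 0.0)):
                u = np.full(m, levels[0])
                u[i:j] = levels[1]
                u[j:] = levels[2]
                best = min(best, prob.objective(u)[0])
        for u_const in (0.0, 1.0):
            best = min(best, prob.objective(np.full(m, u_const))[0])
        sol = cs.solve_ocp(prob)
        assert sol.objective.total <= best * (1 + 1e-6)

    def test_deterministic_across_repeat_solves(self, highsens_params, initial,
                                                weights):
        settings = small_settings(m=60)
        run = [cs.solve_ocp(cs.transcribe(highsens_params, initial, weights,
                                          0.5, settings)) for _ in range(2)]
        assert np.array_equal(run[0].control, run[1].control)


class TestDiagnostics:
    def test_average_dose_limits(self):
        assert cs.average_dose(np.ones(10)) == 100.0
        assert cs.average_dose(np.zeros(10)) == 0.0
        assert cs.average_dose(np.array([0.0, 1.0])) == 50.0

    def test_extract_singular_empty_for_bang_bang(self, ocp_solution_v05):
        sol = cs.OCSolution(
            control=np.concatenate([np.ones(10), np.zeros(10), np.ones(10)]),
            times=np.linspace(0, 14, 31), states=np.ones((31, 3)),
            objective=ocp_solution_v05.objective, solver_status="ok",
            v=0.5, horizon=14.0)
        arcs = cs.extract_singular(sol)
        assert not arcs and arcs.mean_pct is None

    def test_extract_singular_ignores_short_transients(self, ocp_solution_v05):
        u = np.ones(40)
        u[5] = 0.5               # single switching node, not an arc
        u[20:30] = 0.3           # a genuine interior run
        sol = cs.OCSolution(control=u, times=np.linspace(0, 14, 41),
                            states=np.ones((41, 3)),
                            objective=ocp_solution_v05.objective,
                            solver_status="ok", v=0.5, horizon=14.0)
        arcs = cs.extract_singular(sol)
        assert len(arcs.segments) == 1
        assert arcs.mean_pct == pytest.approx(30.0)

    def test_protocol_classification_threshold(self):
        assert cs.classify_protocol(100.0).label == "full-dose"
        assert cs.classify_protocol(52.51).label == "intermediate-dose"
        # the rule is a strict "exceeds 90%"
        assert cs.classify_protocol(90.0).label == "intermediate-dose"


class TestMultiWindow:
    def test_single_window_reduces_to_solve_ocp(self, highsens_params, initial,
                                                weights):
        settings = small_settings(m=60)
        multi = cs.multiwindow_optimize(highsens_params, initial, weights, 0.5,
                                        settings, n_windows=1)
        direct = cs.solve_ocp(cs.transcribe(highsens_params, initial, weights,
                                            0.5, settings))
        assert np.array_equal(multi.control, direct.control)
        assert multi.average_dose_pct == pytest.approx(direct.average_dose_pct)

    def test_windows_chain_through_simulated_states(self, highsens_params,
                                                    initial, weights):
        settings = small_settings(m=40)
        multi = cs.multiwindow_optimize(highsens_params, initial, weights, 0.5,
                                        settings, n_windows=2)
        traj = cs.simulate(highsens_params, initial,
                           cs.DoseSchedule(multi.windows[0].control, 0.5,
                                           settings.horizon))
        assert multi.window_initials[1].as_array() == pytest.approx(
            traj.final_state.as_array(), rel=1e-9)
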