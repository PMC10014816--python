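import numpy as np
import pytest

from dpdcm.forward import simulate
from dpdcm.inversion import (InversionConfig, RecurrentState, _Problem, bold_latency,
                             invert_window, run_recurrent_inversion, window_loss)
from dpdcm.model import (DEFAULT_PHYSIO, RegionGraphSpec, StimulusSet, validate_model)
from dpdcm.profiles import make_stimulus
from dpdcm.windows import plan_windows

from _oracles import grid_search_edge
from conftest import two_region_model


def _rest(n):
    s = np.zeros((6, n))
    s[3:6] = 1.0
    return s


class TestWindowLoss:
    def test_true_parameters_give_zero_loss(self, small_model):
        y = simulate(small_model).y
        loss = window_loss(np.array([0.3]), y, small_model,
                           free_parameters=("edges",))
        assert loss == pytest.approx(0.0, abs=1e-20)

    def test_constant_offset_gives_rt_delta_squared(self, small_model):
        y = simulate(small_model).y
        delta = 0.01
        loss = window_loss(np.array([0.3]), y + delta, small_model,
                           free_parameters=("edges",))
        T, R = y.shape
        assert loss == pytest.approx(R * T * delta ** 2, rel=1e-10)

    def test_invariant_to_consistent_region_relabeling(self):
        # same physics with regions swapped: identical loss for the
        # consistently permuted candidate and data
        def build(flip):
            a, b = (1, 0) if flip else (0, 1)
            n = int(round(20.0 / (1 / 32))) + 1
            grid = np.arange(n) / 32
            u = make_stimulus("block", grid, 1.0, 2.0, 15.0)
            stim = StimulusSet(dt=1 / 32, duration=20.0, driving=u[None, :],
                               modulatory=np.zeros((0, n)),
                               mu_context=np.zeros((0, n)),
                               lambda_context=np.zeros((0, n)))
            graph = RegionGraphSpec(n_regions=2, edges={(a, b): 0.3},
                                    driving_map={(a, 0): 0.1})
            return validate_model(graph, DEFAULT_PHYSIO, stim)

        m_fwd, m_rev = build(False), build(True)
        y = simulate(m_fwd).y
        loss_fwd = window_loss(np.array([0.5]), y, m_fwd, free_parameters=("edges",))
        loss_rev = window_loss(np.array([0.5]), y[:, ::-1], m_rev,
                               free_parameters=("edges",))
        assert loss_fwd == pytest.approx(loss_rev, rel=1e-12)

    def test_divergent_candidate_returns_inf(self, small_model):
        graph = RegionGraphSpec(n_regions=2, edges={(0, 1): 0.3, (1, 0): 0.0},
                                driving_map={(0, 0): 0.1})
        looped = validate_model(graph, small_model.params, small_model.stimuli)
        y = simulate(looped).y
        # candidate loop gain far beyond stability: rejected as inf
        assert window_loss(np.array([5.0, 5.0]), y, looped,
                           free_parameters=("edges",)) == np.inf


class TestGradients:
    def test_forward_sensitivities_match_finite_differences(self):
        rng = np.random.default_rng(17)
        model = two_region_model(duration=12.0, a01=0.35)
        y = simulate(model).y
        obs = y + rng.normal(0, 2e-4, y.shape)  # non-zero residuals
        problem = _Problem(model, model.stimuli, obs, ("edges", "driving"))
        T = 5 * 32
        init = _rest(2)
        for _ in range(5):
            p = rng.normal(0, 0.2, problem.n_params)
            l_fs, g_fs = problem.loss_grad(p, 0, T, init)
            l_fd, g_fd = problem.loss_grad_fd(p, 0, T, init)
            assert l_fs == pytest.approx(l_fd, rel=1e-12)
            np.testing.assert_allclose(g_fs, g_fd, rtol=1e-4, atol=1e-12)


class TestInvertWindow:
    def test_recovers_single_edge_against_grid_search(self, small_model):
        y = simulate(small_model).y
        T = 8 * 32
        loss_fn = lambda p: window_loss(p, y[:T], small_model,
                                        free_parameters=("edges",))
        best, _, resolution = grid_search_edge(loss_fn, 0.0, 0.6, 1201)
        state = invert_window(
            RecurrentState(params=np.zeros(1), state=_rest(2)), y[:T],
            small_model, InversionConfig(free_parameters=("edges",)))
        assert state.params[0] == pytest.approx(best, abs=2 * resolution)
        assert state.params[0] == pytest.approx(0.3, abs=1e-3)

    def test_ground_truth_init_is_a_fixed_point(self, small_model):
        y = simulate(small_model).y
        T = 8 * 32
        state = invert_window(
            RecurrentState(params=np.array([0.3]), state=_rest(2)), y[:T],
            small_model, InversionConfig(free_parameters=("edges",)))
        assert state.diagnostics["iterations"] <= 3
        assert state.diagnostics["final_loss"] == pytest.approx(0.0, abs=1e-18)
        assert state.params[0] == pytest.approx(0.3, abs=1e-9)

    def test_zero_tolerance_runs_the_full_iteration_budget(self, small_model):
        y = simulate(small_model).y
        T = 4 * 32
        state = invert_window(
            RecurrentState(params=np.array([0.3]), state=_rest(2)), y[:T],
            small_model, InversionConfig(tolerance=0.0, free_parameters=("edges",)))
        assert state.diagnostics["iterations"] == 200


@pytest.fixture(scope="module")
def static_run():
    model = two_region_model(duration=40.0, a01=0.3)
    y = simulate(model).y
    plan = plan_windows(40.0, 5.0, 1.0, 1 / 32)
    cfg = InversionConfig(free_parameters=("edges",))
    est = run_recurrent_inversion(model, y, model.stimuli, plan, cfg)
    return model, y, est


class TestRecurrentInversion:

    def test_constant_connectivity_recovered_flat(self, static_run):
        _, _, est = static_run
        # during sustained stimulation the track should sit at the true
        # constant with little variation
        mid = est.eff_conn[10:30, 0]
        assert np.abs(mid.mean() - 0.3) < 0.02
        assert mid.std() < 0.05 * abs(mid.mean())

    def test_hand_off_continuity(self, static_run):
        _, _, est = static_run
        for prev, cur in zip(est.params_per_window, est.per_window[1:]):
            if not cur["reinitialized"]:
                np.testing.assert_array_equal(cur["init_params"], prev)

    def test_bit_identical_reruns(self, static_run):
        model, y, est = static_run
        plan = plan_windows(40.0, 5.0, 1.0, 1 / 32)
        cfg = InversionConfig(free_parameters=("edges",))
        est2 = run_recurrent_inversion(model, y, model.stimuli, plan, cfg)
        assert np.array_equal(est.eff_conn, est2.eff_conn)
        assert np.array_equal(est.fitted_bold, est2.fitted_bold)

    def test_fitted_bold_tracks_observations(self, static_run):
        _, y, est = static_run
        resid = est.fitted_bold - y
        assert np.abs(resid).max() < 0.05 * np.abs(y).max()

    def test_relabeling_equivariance(self):
        def run(perm):
            n = int(round(30.0 / (1 / 32))) + 1
            grid = np.arange(n) / 32
            u = make_stimulus("block", grid, 1.0, 2.0, 25.0)
            stim = StimulusSet(dt=1 / 32, duration=30.0, driving=u[None, :],
                               modulatory=np.zeros((0, n)),
                               mu_context=np.zeros((0, n)),
                               lambda_context=np.zeros((0, n)))
            graph = RegionGraphSpec(
                n_regions=3,
                edges={(perm[0], perm[1]): 0.3, (perm[0], perm[2]): 0.2},
                driving_map={(perm[0], 0): 0.1})
            model = validate_model(graph, DEFAULT_PHYSIO, stim)
            y = simulate(model).y
            plan = plan_windows(30.0, 5.0, 1.0, 1 / 32)
            cfg = InversionConfig(free_parameters=("edges",))
            return model, run_recurrent_inversion(model, y, stim, plan, cfg)

        _, est_id = run((0, 1, 2))
        _, est_pm = run((2, 0, 1))
        # edge (0->1) under identity maps to (2->0) under the permutation
        np.testing.assert_allclose(est_id.eff_conn, est_pm.eff_conn,
                                   rtol=1e-8, atol=1e-10)


def test_bold_latency_is_physiological(case_a):
    lat = bold_latency(case_a.model)
    assert 0.5 < lat < 4.0


def test_config_validation():
    with pytest.raises(ValueError):
        InversionConfig(max_iterations=0).check()
    with pytest.raises(ValueError):
        InversionConfig(free_parameters=()).check()
    with pytest.raises(ValueError):
        InversionConfig(gradient_method="adam").check()
    with pytest.raises(ValueError):
        InversionConfig(latency_s=-1.0).check()
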