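import numpy as np
import pytest

from dpdcm.forward import (SimulationDivergence, assemble_connectivity, blood_outflow,
                           bold_affine, bold_signal, hemo_matrix_step,
                           neuronal_transition_matrix, oxygen_extraction,
                           sample_observations, simulate, step_hemodynamics,
                           step_neuronal, step_nvc)
from dpdcm.model import (DEFAULT_PHYSIO, PhysioParams, RegionGraphSpec, StimulusSet,
                         derive_bold_constants, validate_model)

from conftest import random_hemo_states, two_region_model


def _one_region(sigma=0.5, **kw):
    stim = StimulusSet.zeros(dt=1 / 32, duration=2.0)
    graph = RegionGraphSpec(n_regions=1, driving_map={(0, 0): 0.1})
    return validate_model(graph, PhysioParams(sigma=sigma, **kw), stim)


class TestAssembleConnectivity:
    def test_plain_diagonal(self):
        m = _one_region()
        mats = assemble_connectivity(m, {})
        assert mats.psi[0, 0] == pytest.approx(-0.5)

    def test_self_modulated_diagonal(self):
        stim = StimulusSet.zeros(dt=1 / 32, duration=2.0, n_modulatory=1)
        graph = RegionGraphSpec(n_regions=1, driving_map={(0, 0): 0.1},
                                self_mod={(0, 0): 0.2})
        m = validate_model(graph, DEFAULT_PHYSIO, stim)
        mats = assemble_connectivity(m, {}, {"modulatory": np.array([1.0])})
        assert mats.psi[0, 0] == pytest.approx(-0.5 * np.exp(0.2))
        assert mats.psi[0, 0] == pytest.approx(-0.610701, abs=1e-6)

    def test_modulated_off_diagonal_and_zero_gain_off_diagonal(self):
        stim = StimulusSet.zeros(dt=1 / 32, duration=2.0, n_modulatory=1)
        graph = RegionGraphSpec(n_regions=2, edges={(0, 1): 0.3},
                                modulatory_edges={(0, 1, 0): 0.5},
                                driving_map={(0, 0): 0.1})
        m = validate_model(graph, DEFAULT_PHYSIO, stim)
        mats = assemble_connectivity(m, {(0, 1): 0.3},
                                     {"modulatory": np.array([1.0])})
        assert mats.psi[1, 0] == pytest.approx(0.8)
        assert mats.c_mat[1, 0] == 0.0 and mats.c_mat[0, 1] == 0.0
        assert mats.psi_minus[1, 0] == 0.0

    def test_missing_edge_value_raises(self):
        stim = StimulusSet.zeros(dt=1 / 32, duration=2.0)
        graph = RegionGraphSpec(n_regions=2, edges={(0, 1): 0.3},
                                driving_map={(0, 0): 0.1})
        m = validate_model(graph, DEFAULT_PHYSIO, stim)
        with pytest.raises(KeyError):
            assemble_connectivity(m, {})


class TestNeuronalStep:
    def test_rest_is_fixed_point(self, small_model):
        mats = assemble_connectivity(small_model, {(0, 1): 0.3})
        z = np.zeros(2)
        x_e, x_i = step_neuronal(z, z, mats, np.zeros(1), 1 / 32)
        assert np.all(x_e == 0) and np.all(x_i == 0)

    def test_single_region_hand_evaluation(self):
        m = _one_region(sigma=0.5, mu=0.4, lambda_=0.2)
        mats = assemble_connectivity(m, {})
        x_e, x_i = step_neuronal(np.array([1.0]), np.array([0.0]), mats,
                                 np.zeros(1), 1 / 32)
        assert x_e[0] == pytest.approx(0.984375)
        assert x_i[0] == pytest.approx(0.00625)

    def test_superposition(self, small_model):
        rng = np.random.default_rng(3)
        mats = assemble_connectivity(small_model, {(0, 1): 0.3})
        u = rng.normal(size=1)
        s1 = rng.normal(size=(2, 2))
        s2 = rng.normal(size=(2, 2))
        a, b = 0.7, -1.3
        lhs = step_neuronal(a * s1[0] + b * s2[0], a * s1[1] + b * s2[1], mats,
                            (a + b) * u, 1 / 32)
        r1 = step_neuronal(s1[0], s1[1], mats, u, 1 / 32)
        r2 = step_neuronal(s2[0], s2[1], mats, u, 1 / 32)
        np.testing.assert_allclose(lhs[0], a * r1[0] + b * r2[0], atol=1e-14)
        np.testing.assert_allclose(lhs[1], a * r1[1] + b * r2[1], atol=1e-14)

    def test_transition_matrix_matches_stepwise_form(self, small_model):
        rng = np.random.default_rng(11)
        mats = assemble_connectivity(small_model, {(0, 1): 0.3})
        W = neuronal_transition_matrix(mats, 1 / 32)
        x = rng.normal(size=4)
        stepped = step_neuronal(x[:2], x[2:], mats, np.zeros(1), 1 / 32)
        np.testing.assert_allclose(W @ x, np.concatenate(stepped), atol=1e-15)

    def test_euler_update_is_stable_at_default_step(self, case_a):
        mats = assemble_connectivity(case_a.model, {(0, 1): 0.7, (0, 2): 0.7})
        W = neuronal_transition_matrix(mats, 1 / 32)
        assert np.max(np.abs(np.linalg.eigvals(W))) < 1.0


class TestNvcAndHemodynamics:
    def test_nvc_baseline_fixed_point(self, params):
        a, f = step_nvc(np.zeros(1), np.ones(1), np.zeros(1), params, 1 / 32)
        assert a[0] == 0.0 and f[0] == 1.0

    def test_nvc_drive_and_decay(self, params):
        a, _ = step_nvc(np.zeros(1), np.ones(1), np.ones(1), params, 1 / 32)
        assert a[0] == pytest.approx(0.03125)
        a2, _ = step_nvc(np.ones(1), np.ones(1), np.zeros(1),
                         params.with_overrides(phi_decay=0.6), 1 / 32)
        assert a2[0] == pytest.approx(0.98125)

    def test_oxygen_extraction(self):
        assert oxygen_extraction(1.0, 0.4) == pytest.approx(0.4)
        assert oxygen_extraction(2.0, 0.4) == pytest.approx(0.225403, abs=1e-6)
        f = np.linspace(0.2, 8.0, 50)
        e = oxygen_extraction(f, 0.4)
        assert np.all(np.diff(e) < 0) and np.all((0 < e) & (e < 1))
        with pytest.raises(ValueError):
            oxygen_extraction(-1.0, 0.4)

    def test_blood_outflow(self, params):
        assert blood_outflow(1.0, 1.0, params) == pytest.approx(1.0)
        p0 = params.with_overrides(tau=0.0, alpha=0.5)
        assert blood_outflow(1.1, 1.0, p0) == pytest.approx(1.21)
        p1 = params.with_overrides(t_mtt=2.0, tau=4.0)
        assert blood_outflow(1.0, 1.2, p1) == pytest.approx(6.8 / 6)
        with pytest.raises(ValueError):
            blood_outflow(-0.1, 1.0, params)

    def test_hemodynamics_resting_fixed_point(self, params):
        v, q = step_hemodynamics(np.ones(1), np.ones(1), np.ones(1), params, 1 / 32)
        assert v[0] == pytest.approx(1.0) and q[0] == pytest.approx(1.0)

    def test_hemodynamics_hand_evaluation(self):
        p = PhysioParams(t_mtt=2.0, tau=4.0, alpha=0.38, e0=0.4)
        v, q = step_hemodynamics(np.array([1.2]), np.ones(1), np.ones(1), p, 1 / 32)
        assert v[0] == pytest.approx(1.001042, abs=1e-6)
        assert q[0] == pytest.approx(0.998542, abs=1e-6)

    def test_matrix_form_equals_scalar_form(self, params):
        rng = np.random.default_rng(5)
        a, f, v, q = random_hemo_states(rng, 200)
        x_e = rng.normal(0, 0.3, 200)
        a2, f2 = step_nvc(a, f, x_e, params, 1 / 32)
        v2, q2 = step_hemodynamics(f, v, q, params, 1 / 32)
        for i in range(200):
            out = hemo_matrix_step(a[i], f[i], v[i], q[i], x_e[i], params, 1 / 32)
            np.testing.assert_allclose(out, [a2[i], f2[i], v2[i], q2[i]],
                                       rtol=1e-12, atol=1e-14)


class TestBoldSignal:
    def test_baseline_is_zero(self, params):
        k = derive_bold_constants(params)
        assert bold_signal(1.0, 1.0, k, params.v0) == 0.0

    def test_direct_arithmetic(self):
        class K:
            k1, k2, k3 = 4.0, 1.0, 0.4
        y = bold_signal(1.05, 0.9, K, 0.04)
        assert y == pytest.approx(0.020914, abs=1e-6)

    def test_affine_form_equivalence(self, params):
        rng = np.random.default_rng(7)
        k = derive_bold_constants(params)
        _, _, v, q = random_hemo_states(rng, 500)
        for i in range(500):
            np.testing.assert_allclose(bold_signal(v[i], q[i], k, params.v0),
                                       bold_affine(v[i], q[i], k, params.v0),
                                       rtol=1e-13, atol=1e-16)


class TestSimulate:
    def test_zero_input_stays_at_rest(self, small_model):
        stim = StimulusSet.zeros(dt=1 / 32, duration=10.0)
        m = validate_model(small_model.graph, small_model.params, stim)
        traj = simulate(m)
        assert np.all(traj.y == 0.0)
        assert np.all(traj.x_e == 0.0) and np.all(traj.f == 1.0)
        assert np.all(traj.v == 1.0) and np.all(traj.q == 1.0)

    def test_input_propagates_downstream(self, case_a, case_a_truth):
        traj = case_a_truth
        t = traj.time
        onset_idx = int(10.0 / traj.dt)
        # nothing moves before the stimulus starts
        assert np.allclose(traj.y[: onset_idx - 1], 0.0, atol=1e-12)
        # all three regions respond afterwards, R1 first
        peak_order = [np.argmax(np.abs(traj.y[:, r]) > 1e-4) for r in range(3)]
        assert peak_order[0] < peak_order[1] and peak_order[0] < peak_order[2]
        assert np.abs(traj.y).max() > 1e-3

    def test_divergence_reports_step_index(self):
        model = two_region_model()
        graph = RegionGraphSpec(n_regions=2, edges={(0, 1): 5.0, (1, 0): 5.0},
                                driving_map={(0, 0): 0.1})
        looped = validate_model(graph, model.params, model.stimuli)
        # loop gain far above the self-inhibition: exponential blow-up
        with pytest.raises(SimulationDivergence) as exc:
            simulate(looped)
        assert exc.value.step > 0

    def test_trajectory_frame_round_trip(self, case_a_truth):
        df = case_a_truth.to_frame()
        assert list(df.columns[:4]) == ["time", "y.R1", "y.R2", "y.R3"]
        np.testing.assert_array_equal(df["y.R2"].to_numpy(), case_a_truth.y[:, 1])


class TestSampleObservations:
    def test_integer_multiples_select_indices(self, case_a_truth):
        t1, y1 = sample_observations(case_a_truth, 1.0)
        np.testing.assert_array_equal(y1, case_a_truth.y[::32])
        t2, y2 = sample_observations(case_a_truth, 0.25)
        np.testing.assert_array_equal(y2, case_a_truth.y[::8])

    def test_non_multiple_uses_nearest_grid_point(self, case_a_truth):
        t, y = sample_observations(case_a_truth, 0.1)
        # TR = 0.1 s on a 1/32 s grid: sample k sits at round(3.2 k)
        idx = np.floor(np.arange(len(t)) * 0.1 * 32 + 0.5).astype(int)
        np.testing.assert_array_equal(y, case_a_truth.y[idx])

    def test_tr_below_grid_step_rejected(self, case_a_truth):
        with pytest.raises(ValueError):
            sample_observations(case_a_truth, 0.01)
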