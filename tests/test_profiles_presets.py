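import numpy as np
import pytest

from dpdcm.presets import (PRESET_NAMES, preset_models, simulate_preset,
                           true_eff_conn)
from dpdcm.profiles import ConnectivityProfileSpec, make_connectivity_profile, make_stimulus


class TestConnectivityProfile:
    def test_zero_amplitude_is_flat(self):
        spec = ConnectivityProfileSpec(baseline=0.25, amplitude=0.0, period_s=10,
                                       onset_s=5, offset_s=25)
        grid = np.linspace(0, 30, 301)
        track = make_connectivity_profile(spec, grid)
        np.testing.assert_allclose(track, 0.25)

    def test_sinusoid_value_inside_epoch(self):
        spec = ConnectivityProfileSpec(baseline=0.4, amplitude=0.3, period_s=30.0,
                                       onset_s=10.0, offset_s=70.0)
        # a quarter period after onset the sine is at its crest
        assert spec(np.array([17.5]))[0] == pytest.approx(0.7)

    def test_baseline_outside_epoch(self):
        spec = ConnectivityProfileSpec(baseline=0.4, static=0.2, amplitude=0.3,
                                       period_s=20, onset_s=10, offset_s=40, ramp_s=5)
        grid = np.linspace(0, 60, 601)
        track = spec(grid)
        outside = (grid < 10) | (grid > 40)
        np.testing.assert_array_equal(track[outside], 0.4)

    def test_ramp_is_continuous_at_epoch_edges(self):
        spec = ConnectivityProfileSpec(baseline=0.0, static=0.4, amplitude=0.3,
                                       period_s=30, onset_s=10, offset_s=100,
                                       ramp_s=8)
        eps = 1e-6
        assert abs(spec(np.array([10 + eps]))[0]) < 1e-4
        assert abs(spec(np.array([100 - eps]))[0]) < 1e-4

    def test_piecewise_reproduces_knots(self):
        knots = ((0.0, 0.0), (5.0, 1.0), (10.0, 0.5), (20.0, 0.5))
        spec = ConnectivityProfileSpec(baseline=0.1, amplitude=0.2, shape="piecewise",
                                       onset_s=0.0, offset_s=20.0, knots=knots)
        for x, val in knots:
            assert spec(np.array([x]))[0] == pytest.approx(0.1 + 0.2 * val)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ConnectivityProfileSpec(onset_s=5, offset_s=2).check()
        with pytest.raises(ValueError):
            ConnectivityProfileSpec(shape="sinusoid", period_s=0.0,
                                    offset_s=1.0).check()
        with pytest.raises(ValueError):
            ConnectivityProfileSpec(shape="piecewise", offset_s=1.0).check()


class TestMakeStimulus:
    def test_zero_amplitude(self):
        grid = np.linspace(0, 10, 321)
        assert np.all(make_stimulus("sinusoid", grid, 0.0, 1, 9, 4) == 0.0)

    def test_quarter_period_hits_amplitude(self):
        grid = np.arange(0, 40, 1 / 32)
        u = make_stimulus("sinusoid", grid, 0.8, 5.0, 35.0, period_s=20.0)
        k = int(round((5.0 + 5.0) * 32))
        assert u[k] == pytest.approx(0.8)

    def test_zero_outside_interval(self):
        grid = np.arange(0, 40, 1 / 32)
        u = make_stimulus("block", grid, 1.0, 10.0, 20.0)
        assert np.all(u[grid < 10] == 0) and np.all(u[grid > 20] == 0)
        assert np.all(u[(grid >= 10) & (grid <= 20)] == 1.0)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_stimulus("sawtooth", np.arange(4.0))


class TestPresets:
    def test_case_a_structure(self, case_a):
        g = case_a.model.graph
        assert g.n_regions == 3
        assert set(g.edges) == {(0, 1), (0, 2)}
        assert case_a.stimuli.driving.shape[0] == 1
        assert set(case_a.profiles) == {(0, 1), (0, 2)}
        # fast coupling to R2, slow to R3
        assert case_a.profiles[(0, 1)].period_s < case_a.profiles[(0, 2)].period_s

    def test_m1_has_modulated_feedback(self):
        m1 = preset_models("three_region_m1")
        g = m1.model.graph
        assert (1, 0) in g.edges  # feedback R2 -> R1
        assert any(e[:2] == (1, 0) for e in g.modulatory_edges)

    def test_m2_is_the_chain_with_feedback(self):
        m2 = preset_models("three_region_m2")
        g = m2.model.graph
        assert set(g.edges) == {(0, 1), (1, 2), (2, 1)}
        assert any(e[:2] == (1, 2) for e in g.modulatory_edges)

    def test_ten_region_edge_set(self):
        g = preset_models("ten_region_m1").model.graph
        expected_1based = {(1, 3), (3, 8), (1, 5), (1, 6), (1, 7), (2, 6),
                           (2, 4), (4, 9), (4, 10)}
        assert {(s + 1, t + 1) for (s, t) in g.edges} == expected_1based
        assert g.driving_map.keys() == {(0, 0), (1, 1)}

    def test_ten_region_inputs_are_20s_apart(self):
        p = preset_models("ten_region_m1")
        u1, u2 = p.stimuli.driving
        lags = np.arange(-len(u1) + 1, len(u1))
        xc = np.correlate(u2 - u2.mean(), u1 - u1.mean(), "full")
        best_lag_s = lags[np.argmax(xc)] * p.stimuli.dt
        assert best_lag_s == pytest.approx(20.0, abs=0.5)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset_models("four_region")

    def test_true_eff_conn_matches_profiles(self, case_a):
        times = np.arange(0.0, 120.0)
        truth = true_eff_conn(case_a, times)
        for k, e in enumerate(case_a.model.graph.edge_list):
            np.testing.assert_allclose(truth[:, k], case_a.profiles[e](times))

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_all_presets_simulate_physiologically(self, name):
        traj = simulate_preset(preset_models(name))
        assert np.all(np.isfinite(traj.y))
        assert traj.f.min() > 0.3 and traj.f.max() < 3.0
        assert np.abs(traj.y).max() < 0.06  # under 6% signal change
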