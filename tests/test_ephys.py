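"""Input-map charges, layer normalization, TTX subtraction, intrinsics."""

import numpy as np
import pytest

from barrelmap import ephys, synth
from barrelmap.ephys import AnalysisWindow, InputMap, UncagingGrid


def _grid(rows=4, cols=4, planted=(), noise=0.0, seed=0, **kw):
    return synth.simulate_uncaging_grid(grid_shape=(rows, cols),
                                        planted_inputs=list(planted),
                                        noise_sd_pA=noise, seed=seed, **kw)


class TestCalibrationWindow:
    def test_window_spans_first_to_last_peak_plus_margin(self):
        w = ephys.calibration_window([0.105, 0.130], margin_ms=10)
        assert w.start_s == pytest.approx(0.105)
        assert w.end_s == pytest.approx(0.140)

    def test_single_peak(self):
        w = ephys.calibration_window([0.050], margin_ms=10)
        assert (w.start_s, w.end_s) == (0.050, pytest.approx(0.060))

    def test_unsorted_input_sorted_internally(self):
        w1 = ephys.calibration_window([0.130, 0.105])
        w2 = ephys.calibration_window([0.105, 0.130])
        assert (w1.start_s, w1.end_s) == (w2.start_s, w2.end_s)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ephys.calibration_window([])


class TestSiteCharges:
    def test_square_inward_pulse(self):
        grid = _grid(planted=[{"site": (0, 0), "amplitude_pA": -50.0,
                               "onset_ms": 600.0, "dur_ms": 100.0}])
        w = AnalysisWindow(0.55, 0.80)
        exc, inh = ephys.site_charges(grid.sweeps[0, 0], w,
                                      grid.sampling_hz, 0.5)
        assert exc == pytest.approx(5.0, abs=1e-9)
        assert inh == 0.0

    def test_square_outward_pulse(self):
        grid = _grid(planted=[{"site": (1, 1), "amplitude_pA": 30.0,
                               "onset_ms": 600.0, "dur_ms": 50.0}])
        w = AnalysisWindow(0.55, 0.75)
        exc, inh = ephys.site_charges(grid.sweeps[1, 1], w,
                                      grid.sampling_hz, 0.5)
        assert inh == pytest.approx(1.5, abs=1e-9)
        assert exc == 0.0

    def test_zero_mean_noise_splits_symmetrically(self):
        rng = np.random.default_rng(0)
        sweeps = rng.normal(0.0, 5.0, size=(100, 10_000))
        w = AnalysisWindow(0.55, 0.95)
        excs, inhs = [], []
        for sw in sweeps:
            e, i = ephys.site_charges(sw[None], w, 10_000.0, 0.5)
            excs.append(e)
            inhs.append(i)
        diff = np.asarray(excs) - np.asarray(inhs)
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) <= 3 * se

    def test_charge_additivity_without_sign_change(self):
        grid = _grid(planted=[{"site": (0, 0), "amplitude_pA": -20.0,
                               "onset_ms": 600.0, "dur_ms": 100.0}])
        w = AnalysisWindow(0.55, 0.80)
        sw = grid.sweeps[0, 0][0]
        e1, _ = ephys.site_charges(sw[None], w, grid.sampling_hz, 0.5)
        e2, _ = ephys.site_charges((2 * sw)[None], w, grid.sampling_hz, 0.5)
        assert e2 == pytest.approx(2 * e1, abs=1e-9)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            ephys.site_charges(np.zeros((1, 1000)), AnalysisWindow(0.0, 0.05),
                               10_000.0, 0.01)


class TestLayerNormalization:
    def test_uniform_map_normalizes_to_one(self):
        grid = _grid(rows=8, cols=8, site_spacing_um=100.0)
        charges = np.full((8, 8), 3.7)
        vals = ephys.layer_normalized_map(charges, grid)
        for v in vals.values():
            assert v == pytest.approx(1.0)

    def test_single_layer_concentration(self):
        grid = _grid(rows=10, cols=4, site_spacing_um=100.0)
        # rows 1-3 sit in L2/3 with the default bounds
        charges = np.zeros((10, 4))
        l23_rows = [r for r in range(10)
                    if grid.layer_of_row(r) == "L2/3"]
        for r in l23_rows:
            charges[r, :] = 1.0
        vals = ephys.layer_normalized_map(charges, grid)
        f = len(l23_rows) / 10
        assert vals["L2/3"] == pytest.approx(1.0 / f)
        assert vals["L5/6"] == 0.0

    def test_matches_hand_computed_toy_grid(self):
        # 4x4 grid, one row per layer (spacing 250 um over 1000 um depth)
        bounds = {"L1": (0, 250), "L2/3": (250, 500), "L4": (500, 750),
                  "L5/6": (750, 1000)}
        grid = _grid(rows=4, cols=4, site_spacing_um=250.0,
                     layer_bounds_um=bounds)
        charges = np.array([[1.0, 2.0, 3.0, 4.0],
                            [0.0, 0.0, 0.0, 0.0],
                            [2.0, 2.0, 2.0, 2.0],
                            [1.0, 1.0, 1.0, 5.0]])
        vals = ephys.layer_normalized_map(charges, grid)
        fov_mean = charges.mean()  # = 1.625
        assert vals["L1"] == pytest.approx(2.5 / fov_mean)
        assert vals["L2/3"] == pytest.approx(0.0)
        assert vals["L4"] == pytest.approx(2.0 / fov_mean)
        assert vals["L5/6"] == pytest.approx(2.0 / fov_mean)

    def test_normalized_site_map_mean_is_one(self):
        rng = np.random.default_rng(1)
        charges = rng.uniform(0, 5, size=(20, 20))
        norm = ephys.normalize_map(charges)
        assert norm.mean() == pytest.approx(1.0, abs=1e-10)

    def test_zero_map_flagged(self):
        grid = _grid()
        with pytest.raises(ValueError, match="undefined"):
            ephys.layer_normalized_map(np.zeros((4, 4)), grid)


class TestLateralProfile:
    def _grid_20(self):
        return _grid(rows=20, cols=20, soma_xy_um=(500.0, 200.0))

    def test_single_offset_site(self):
        grid = self._grid_20()
        charges = np.zeros((20, 20))
        # site x = 275 um -> 225 um left of the soma at x=500 -> bin 4
        charges[2, 5] = 4.0
        centers, prof = ephys.lateral_profile(charges, grid)
        nz = np.flatnonzero(np.nan_to_num(prof) > 0)
        assert list(nz) == [4]
        assert centers[4] == pytest.approx(225.0)

    def test_symmetric_sites_pool_by_absolute_distance(self):
        grid = self._grid_20()
        charges = np.zeros((20, 20))
        charges[2, 3] = 2.0   # x=175, d=325
        charges[2, 16] = 4.0  # x=825, d=325
        _, prof = ephys.lateral_profile(charges, grid)
        b = int(325 // 50)
        others = np.delete(np.nan_to_num(prof), b)
        # bin mean includes the zero-charge sites that fall in the bin
        assert prof[b] > 0
        assert np.all(others[np.isfinite(others)] >= 0)
        assert np.nansum(others) == 0

    def test_deep_layer_charge_invisible_under_superficial_filter(self):
        grid = self._grid_20()
        charges = np.zeros((20, 20))
        deep_rows = [r for r in range(20)
                     if grid.layer_of_row(r) not in ("L1", "L2/3")]
        for r in deep_rows:
            charges[r, :] = 3.0
        _, prof = ephys.lateral_profile(charges, grid)
        assert np.nansum(prof) == 0


class TestTtxSubtraction:
    def _maps(self, pre, post, grid):
        return (InputMap(excitatory_pC=pre, inhibitory_pC=np.zeros_like(pre),
                         grid=grid),
                InputMap(excitatory_pC=post,
                         inhibitory_pC=np.zeros_like(post), grid=grid))

    def test_identical_maps_cancel(self):
        grid = _grid(rows=20, cols=4)
        pre = np.random.default_rng(0).uniform(0, 2, size=(20, 4))
        a, b = self._maps(pre, pre.copy(), grid)
        syn = ephys.ttx_subtract(a, b)
        assert np.nansum(np.abs(syn)) == 0.0

    def test_planted_synaptic_charge_recovered_exactly(self):
        grid = _grid(rows=20, cols=4)
        direct = np.random.default_rng(1).uniform(0, 1, size=(20, 4))
        synaptic = np.zeros((20, 4))
        synaptic[2, 1] = 3.5  # superficial site
        a, b = self._maps(direct + synaptic, direct, grid)
        syn = ephys.ttx_subtract(a, b)
        assert syn[2, 1] == pytest.approx(3.5)
        sup_rows = [r for r in range(20)
                    if grid.layer_of_row(r) in ("L1", "L2/3")]
        assert np.nansum(syn) == pytest.approx(3.5)
        deep = [r for r in range(20) if r not in sup_rows]
        assert np.all(np.isnan(syn[deep]))

    def test_noise_overshoot_floored_to_zero(self):
        grid = _grid(rows=20, cols=4)
        pre = np.zeros((20, 4))
        post = np.zeros((20, 4))
        post[1, 1] = 0.2
        a, b = self._maps(pre, post, grid)
        syn = ephys.ttx_subtract(a, b)
        assert syn[1, 1] == 0.0

    def test_monotone_in_pre(self):
        grid = _grid(rows=20, cols=4)
        rng = np.random.default_rng(2)
        post = rng.uniform(0, 1, (20, 4))
        pre1 = post + rng.uniform(0, 1, (20, 4))
        pre2 = pre1 + rng.uniform(0, 1, (20, 4))
        a1, b1 = self._maps(pre1, post, grid)
        a2, _ = self._maps(pre2, post, grid)
        s1 = ephys.ttx_subtract(a1, b1)
        s2 = ephys.ttx_subtract(a2, b1)
        ok = np.isfinite(s1)
        assert np.all(s2[ok] >= s1[ok])

    def test_grid_mismatch_rejected(self):
        grid = _grid(rows=20, cols=4)
        a, _ = self._maps(np.zeros((20, 4)), np.zeros((20, 4)), grid)
        b, _ = self._maps(np.zeros((10, 4)), np.zeros((10, 4)), grid)
        with pytest.raises(ValueError, match="mismatch"):
            ephys.ttx_subtract(a, b)


class TestFullChainRecovery:
    def test_planted_site_charge_through_grid_maps(self):
        planted = [{"site": (2, 3), "amplitude_pA": -40.0,
                    "onset_ms": 620.0, "dur_ms": 80.0}]
        grid = _grid(rows=6, cols=6, planted=planted)
        window = ephys.calibration_window([0.61, 0.70], margin_ms=10)
        maps = ephys.grid_charge_maps(grid, window)
        assert maps.excitatory_pC[2, 3] == pytest.approx(3.2, rel=0.05)
        others = maps.excitatory_pC.copy()
        others[2, 3] = 0.0
        assert np.all(others == 0.0)


class TestIntrinsicProperties:
    def test_resistance_from_ohmic_deflection(self):
        rec = synth.simulate_step_recording(step_pA=(-20.0, 200.0),
                                            resistance_Mohm=100.0)
        props = ephys.intrinsic_properties(rec)
        # -20 pA producing -2 mV steady deflection -> 100 MOhm
        assert props.membrane_resistance_Mohm == pytest.approx(100.0)

    def test_planted_spike_parameters_recovered(self):
        rec = synth.simulate_step_recording(
            threshold_mV=-40.0, spike_peak_mV=40.0, half_width_ms=1.0,
            ahp_mV=12.0)
        p = ephys.intrinsic_properties(rec)
        assert p.spike_threshold_mV == pytest.approx(-40.0)
        assert p.spike_height_mV == pytest.approx(80.0)
        assert p.spike_half_width_ms == pytest.approx(1.0, rel=0.05)
        assert p.ahp_amplitude_mV == pytest.approx(12.0)

    def test_threshold_matches_scan_oracle_on_clean_ramp(self):
        # hand-built sweep: slow subthreshold ramp, then a fast spike
        fs = 10_000.0
        v = np.full(4000, -65.0)
        ramp = np.linspace(-65.0, -45.0, 1000)  # 0.2 mV/ms, subthreshold
        v[1000:2000] = ramp
        spike = np.linspace(-45.0, 40.0, 20)  # 42.5 mV/ms rise
        v[2000:2020] = spike
        v[2020:2040] = np.linspace(40.0, -50.0, 20)
        v[2040:] = -50.0
        rec = ephys.StepRecording(voltage_mV=np.stack([-v * 0 - 67.0, v]),
                                  step_pA=np.array([-20.0, 100.0]),
                                  sampling_hz=fs, step_onset_s=0.05,
                                  step_duration_s=0.3)
        p = ephys.intrinsic_properties(rec, dvdt_threshold_mV_per_ms=20.0)
        dvdt = np.gradient(v) * fs / 1000.0
        oracle_idx = np.flatnonzero(dvdt >= 20.0)[0]
        assert p.spike_threshold_mV == pytest.approx(v[oracle_idx], abs=3.0)

    def test_no_spike_leaves_resistance_only(self):
        rec = synth.simulate_step_recording(step_pA=(-40.0, -20.0, 20.0))
        p = ephys.intrinsic_properties(rec)
        assert p.membrane_resistance_Mohm > 0
        assert np.isnan(p.spike_threshold_mV)
        assert np.isnan(p.spike_half_width_ms)
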