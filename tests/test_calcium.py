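"""Trace-level operations: registration, dF/F, correlations, fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barrelmap import calcium, synth
from barrelmap.calcium import TraceMatrix


def _bandlimited_frame(shape=(64, 64), seed=0):
    """Smooth random image (registration-friendly, no aliasing)."""
    from scipy import ndimage
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(size=shape), 3.0)


def _shift_fourier(img, dy, dx):
    from scipy import ndimage
    return np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img),
                                              (dy, dx))).real


def _oracle_subpixel_shift(reference, frame, step=0.01, span=1.0):
    """Brute-force scan of the cross-correlation over a fine shift grid."""
    F_ref = np.fft.fft2(reference)
    F_frm = np.fft.fft2(frame)
    cross = F_ref * np.conj(F_frm)
    # integer peak first
    cc = np.fft.ifft2(cross).real
    peak = np.unravel_index(np.argmax(cc), cc.shape)
    p = [peak[0] if peak[0] <= cc.shape[0] // 2 else peak[0] - cc.shape[0],
         peak[1] if peak[1] <= cc.shape[1] // 2 else peak[1] - cc.shape[1]]
    ky = np.fft.fftfreq(reference.shape[0])[:, None]
    kx = np.fft.fftfreq(reference.shape[1])[None, :]
    best, best_val = None, -np.inf
    for dy in np.arange(p[0] - span, p[0] + span + step / 2, step):
        for dx in np.arange(p[1] - span, p[1] + span + step / 2, step):
            phase = np.exp(2j * np.pi * (ky * dy + kx * dx))
            val = np.real(np.sum(cross * phase))
            if val > best_val:
                best_val, best = val, (dy, dx)
    return np.array(best)


class TestRegisterFrames:
    def test_static_movie_has_zero_shifts(self):
        frame = _bandlimited_frame()
        movie = calcium.FluorescenceMovie(
            green=np.repeat(frame[None], 5, axis=0),
            red=np.repeat(frame[None], 5, axis=0))
        _, shifts, flags = calcium.register_frames(movie)
        np.testing.assert_allclose(shifts, 0.0, atol=1e-9)
        assert not flags.any()

    def test_integer_shift_recovered_exactly(self):
        ref = _bandlimited_frame(seed=1)
        shifted = np.roll(np.roll(ref, 3, axis=0), -2, axis=1)
        stack = np.stack([ref, ref, ref, shifted, ref])
        movie = calcium.FluorescenceMovie(green=stack.copy(), red=stack)
        _, shifts, _ = calcium.register_frames(movie)
        np.testing.assert_allclose(shifts[3], [-3.0, 2.0], atol=1e-6)

    def test_subpixel_shift_matches_bruteforce_oracle(self):
        ref = _bandlimited_frame(seed=2)
        shifted = _shift_fourier(ref, 2.5, -1.25)
        stack = np.stack([ref] * 4 + [shifted])
        movie = calcium.FluorescenceMovie(green=stack.copy(), red=stack)
        _, shifts, _ = calcium.register_frames(movie, upsample_factor=100)
        oracle = _oracle_subpixel_shift(np.median(stack, axis=0), shifted)
        assert abs(shifts[4][0] - (-2.5)) < 0.1
        assert abs(shifts[4][1] - 1.25) < 0.1
        np.testing.assert_allclose(shifts[4], oracle, atol=0.1)

    def test_degenerate_frame_flagged(self):
        stack = np.stack([_bandlimited_frame(seed=3),
                          np.zeros((64, 64))])
        movie = calcium.FluorescenceMovie(green=stack.copy(), red=stack)
        with pytest.warns(UserWarning):
            _, shifts, flags = calcium.register_frames(movie)
        assert flags[1]
        np.testing.assert_array_equal(shifts[1], 0.0)


class TestExtractAndDff:
    def test_uniform_frames_give_constant_traces(self):
        movie = calcium.FluorescenceMovie(green=np.full((4, 8, 8), 7.0),
                                          red=np.zeros((4, 8, 8)))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        tm = calcium.extract_roi_traces(movie, [mask])
        np.testing.assert_array_equal(tm.values, 7.0)

    def test_single_pixel_mask_copies_pixel_series(self):
        rng = np.random.default_rng(0)
        green = rng.uniform(1, 2, size=(10, 6, 6))
        movie = calcium.FluorescenceMovie(green=green,
                                          red=np.zeros_like(green))
        mask = np.zeros((6, 6), dtype=bool)
        mask[3, 4] = True
        tm = calcium.extract_roi_traces(movie, [mask])
        np.testing.assert_array_equal(tm.values[0], green[:, 3, 4])

    def test_empty_mask_rejected(self):
        movie = calcium.FluorescenceMovie(green=np.ones((3, 4, 4)),
                                          red=np.ones((3, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            calcium.extract_roi_traces(movie, [np.zeros((4, 4), dtype=bool)])

    def test_constant_trace_maps_to_zero(self):
        dff = calcium.delta_f_over_f(TraceMatrix(np.full((2, 100), 100.0)))
        np.testing.assert_array_equal(dff.values, 0.0)

    def test_peak_dff_from_known_baseline(self):
        # lowest 5% of samples average 50, max 100 -> peak dF/F = 1
        trace = np.full(100, 80.0)
        trace[:5] = 50.0
        trace[50] = 100.0
        dff = calcium.delta_f_over_f(TraceMatrix(trace[None]))
        assert dff.values[0].max() == pytest.approx(1.0)

    def test_zero_floor_rejected_with_cell_id(self):
        trace = np.ones(100)
        trace[:10] = 0.0
        with pytest.raises(ValueError, match="cell 0"):
            calcium.delta_f_over_f(TraceMatrix(trace[None]))

    @given(gain=st.floats(0.1, 100.0), seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_dff_invariant_under_gain(self, gain, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(50, 150, size=(1, 200))
        a = calcium.delta_f_over_f(TraceMatrix(raw))
        b = calcium.delta_f_over_f(TraceMatrix(raw * gain))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)


class TestNeuropilCorrection:
    def test_zero_alpha_is_identity(self):
        raw = TraceMatrix(np.random.default_rng(0).uniform(1, 2, (3, 50)))
        npil = TraceMatrix(np.ones((3, 50)))
        out = calcium.neuropil_correct(raw, npil,
                                       calcium.CorrectionParams(alpha=0.0))
        np.testing.assert_array_equal(out.values, raw.values)

    def test_full_alpha_cancels_identical_traces(self):
        v = np.random.default_rng(1).uniform(1, 2, (2, 40))
        out = calcium.neuropil_correct(
            TraceMatrix(v.copy()), TraceMatrix(v.copy()),
            calcium.CorrectionParams(alpha=1.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_alpha_is_source_intensity_ratio(self):
        params = calcium.estimate_alpha(20.0, 40.0)
        assert params.alpha == 0.5

    def test_alpha_range_enforced(self):
        with pytest.raises(ValueError):
            calcium.CorrectionParams(alpha=2.0)


class TestEvokedStatistics:
    def test_constant_response_integral(self):
        fr = 11.25
        trace = np.zeros(300)
        trace[100:] = 0.02  # 2 %dF/F from onset onward
        tm = TraceMatrix(trace[None], frame_rate_hz=fr, kind="dff")
        out = calcium.evoked_integral(tm, onset=100, window_s=8.0)
        assert out[0] == pytest.approx(16.0, abs=1e-9)

    def test_zero_trace_integral(self):
        tm = TraceMatrix(np.zeros((1, 300)), kind="dff")
        assert calcium.evoked_integral(tm, 50)[0] == 0.0

    def test_transient_integral_matches_closed_form(self):
        fr = 11.25
        a, b = 0.8, -0.5
        trace = np.zeros(300)
        kern = synth.simulate_transient((a, b, 0, -1), 300 / fr - 100 / fr, fr)
        trace[100:100 + kern.size] = kern
        tm = TraceMatrix(trace[None], frame_rate_hz=fr, kind="dff")
        got = calcium.evoked_integral(tm, 100, window_s=8.0)[0]
        expected = a / abs(b) * (1 - np.exp(b * 8.0)) * 100
        assert got == pytest.approx(expected, rel=0.01)

    def test_integral_linearity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        mk = lambda v: TraceMatrix(v[None], kind="raw")
        ix = calcium.evoked_integral(mk(x), 60)[0]
        iy = calcium.evoked_integral(mk(y), 60)[0]
        ixy = calcium.evoked_integral(mk(x + y), 60)[0]
        assert ixy == pytest.approx(ix + iy, abs=1e-10)

    def test_window_bounds_checked(self):
        tm = TraceMatrix(np.zeros((1, 50)), kind="dff")
        with pytest.raises(ValueError):
            calcium.evoked_integral(tm, 40, window_s=8.0)

    def test_identical_traces_correlate_fully(self):
        v = np.random.default_rng(3).normal(size=400)
        tm = TraceMatrix(np.stack([v, v, v]), kind="dff")
        _, avg = calcium.evoked_correlation(tm, [0, 100], window_s=17.4)
        np.testing.assert_allclose(avg, 1.0, atol=1e-12)

    def test_negated_trace_anticorrelates(self):
        v = np.random.default_rng(4).normal(size=400)
        tm = TraceMatrix(np.stack([v, -v]), kind="dff")
        _, avg = calcium.evoked_correlation(tm, [0], window_s=17.4)
        assert avg[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_pearson_formula(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(5, 400))
        tm = TraceMatrix(vals, kind="dff")
        per_trial, _ = calcium.evoked_correlation(tm, [30], window_s=17.4)
        n = int(np.floor(17.4 * 11.25))
        win = vals[:, 30:30 + n]
        for i in range(5):
            for j in range(5):
                x, y = win[i], win[j]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2)
                              * np.sum((y - y.mean()) ** 2))
                assert per_trial[0, i, j] == pytest.approx(num / den,
                                                           abs=1e-12)

    def test_correlation_matrix_properties(self):
        rng = np.random.default_rng(6)
        tm = TraceMatrix(rng.normal(size=(4, 600)), kind="dff")
        mat, _ = calcium.spontaneous_correlation(tm, n_segments=50, seed=0)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        assert np.nanmax(np.abs(mat)) <= 1.0 + 1e-12

    def test_shared_trace_gives_unit_matrix(self):
        v = np.random.default_rng(7).normal(size=500)
        tm = TraceMatrix(np.stack([v, v]), kind="dff")
        mat, spot = calcium.spontaneous_correlation(tm, n_segments=20, seed=1)
        np.testing.assert_allclose(mat, 1.0, atol=1e-12)
        assert spot == pytest.approx(1.0)

    def test_white_noise_null(self):
        spot_means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tm = TraceMatrix(rng.normal(size=(5, 800)), kind="dff")
            _, spot = calcium.spontaneous_correlation(tm, n_segments=100,
                                                      seed=seed)
            spot_means.append(spot)
        spot_means = np.asarray(spot_means)
        se = spot_means.std(ddof=1) / np.sqrt(spot_means.size)
        assert abs(spot_means.mean()) <= 3 * se + 1e-3

    def test_short_recording_rejected(self):
        tm = TraceMatrix(np.zeros((2, 50)), kind="dff")
        with pytest.raises(ValueError, match="shorter"):
            calcium.spontaneous_correlation(tm)


class TestEventDetection:
    def test_flat_trace_yields_no_events(self):
        ev = calcium.detect_events(np.zeros(200), 11.25)
        assert len(ev) == 0

    def test_single_transient_detected_at_peak(self):
        fr = 11.25
        rng = np.random.default_rng(0)
        kern = synth.simulate_transient((1.0, -0.8, 0, -1), 6.0, fr)
        trace = rng.normal(0, 0.1, size=400)  # SNR 10
        trace[150:150 + kern.size] += kern
        ev = calcium.detect_events(trace, fr, min_snr=5)
        assert len(ev) == 1
        assert abs(ev.peak_frames[0] - 150) <= 1

    def test_two_separated_transients(self):
        fr = 11.25
        rng = np.random.default_rng(1)
        kern = synth.simulate_transient((1.0, -0.8, 0, -1), 6.0, fr)
        trace = rng.normal(0, 0.05, size=600)
        for start in (120, 400):
            trace[start:start + kern.size] += kern
        ev = calcium.detect_events(trace, fr, min_snr=5)
        assert len(ev) == 2


class TestBiexponentialFit:
    def test_single_exponential_tau(self):
        seg = synth.simulate_transient((1.0, -0.5, 0, -1), 10.0, 11.25)
        fit = calcium.fit_biexponential(seg, 11.25)
        assert fit.tau_w == pytest.approx(2.0, rel=0.01)

    def test_known_biexponential_tau(self):
        seg = synth.simulate_transient((0.5, -1.0, 0.5, -0.25), 12.0, 11.25)
        fit = calcium.fit_biexponential(seg, 11.25)
        assert fit.tau_w == pytest.approx(2.5, rel=0.01)
        assert fit.b <= fit.d

    def test_weighted_tau_closed_form(self):
        assert calcium.weighted_tau(0.5, -1.0, 0.5, -0.25) == 2.5
        assert calcium.weighted_tau(1.0, -0.5, 0.0, -1.0) == 2.0
        with pytest.raises(ValueError):
            calcium.weighted_tau(1.0, 0.5, 0.0, -1.0)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            calcium.fit_biexponential(np.ones(5), 11.25)

    @given(a=st.floats(0.2, 1.5), tau_f=st.floats(0.2, 1.0),
           c=st.floats(0.2, 1.5), tau_s=st.floats(1.5, 6.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_tau_bounds_convex_combination(self, a, tau_f, c, tau_s):
        seg = synth.simulate_transient((a, -1 / tau_f, c, -1 / tau_s),
                                       12.0, 11.25)
        fit = calcium.fit_biexponential(seg, 11.25)
        lo = min(-1 / fit.b, -1 / fit.d)
        hi = max(-1 / fit.b, -1 / fit.d)
        assert lo - 1e-9 <= fit.tau_w <= hi + 1e-9


class TestEndToEndRecovery:
    def test_chain_recovers_true_traces(self, recovered_dff):
        dff, params, truth = recovered_dff
        assert params.alpha == pytest.approx(truth.alpha_true, abs=1e-9)
        for i in range(dff.n_cells):
            c = np.corrcoef(dff.values[i], truth.true_traces[i])[0, 1]
            assert c >= 0.99

    def test_chain_with_drift_recovers_traces(self):
        rng = np.random.default_rng(5)
        T = 300
        drift = np.cumsum(rng.normal(0, 0.15, size=(T, 2)), axis=0)
        drift = np.clip(drift, -3, 3)
        cfg = synth.SimConfig(seed=21, movie_shape=(T, 48, 48), n_cells=4,
                              noise_sd=0.0, drift_series=drift)
        movie, truth = synth.simulate_population(cfg)
        registered, shifts, _ = calcium.register_frames(movie)
        raw = calcium.extract_roi_traces(registered, truth.roi_masks)
        dff = calcium.delta_f_over_f(raw)
        for i in range(4):
            c = np.corrcoef(dff.values[i], truth.true_traces[i])[0, 1]
            assert c >= 0.99
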