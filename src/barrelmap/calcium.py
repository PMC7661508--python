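"""Calcium-trace quantification for two-photon movies.

Turns registered two-channel movies plus ROI masks and stimulus logs into
trace-level statistics: ``dF/F`` with a bottom-5% baseline, neuropil-corrected
traces, evoked response integrals, evoked and spontaneous pairwise
correlations, automated event detection, and bi-exponential transient fits
with an amplitude-weighted decay time constant.

Conventions
-----------
* Frame indices are 0-based; time windows are half-open ``[start, start+w)``.
* Movies are ``(T, H, W)`` per channel; channel 0 is the functional (green)
  indicator channel, channel 1 the anatomical (red) channel.
* ``dF/F`` values are fractions; evoked integrals are reported in %*s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal
from skimage.registration import phase_cross_correlation

__all__ = [
    "FluorescenceMovie",
    "RoiSet",
    "TraceMatrix",
    "CorrectionParams",
    "TransientFit",
    "EventList",
    "register_frames",
    "extract_roi_traces",
    "delta_f_over_f",
    "neuropil_correct",
    "estimate_alpha",
    "evoked_integral",
    "evoked_correlation",
    "spontaneous_correlation",
    "detect_events",
    "fit_biexponential",
    "weighted_tau",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceMovie:
    """Two-channel time-ordered frame stack.

    Parameters
    ----------
    green, red : ndarray, shape (T, H, W)
        Functional and anatomical channels.
    frame_rate_hz : float
        Constant acquisition rate (default 11.25 Hz).
    stimulus_log : list of dict, optional
        Entries ``{"onset_frame": int, "paradigm": "single"|"multi"}``.
    spot_id : str
        Identifier of the imaging spot.
    """

    green: np.ndarray
    red: np.ndarray
    frame_rate_hz: float = 11.25
    stimulus_log: list = field(default_factory=list)
    spot_id: str = "spot0"

    def __post_init__(self):
        self.green = np.asarray(self.green, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.green.shape != self.red.shape:
            raise ValueError("green and red channels must share a shape")
        if self.green.ndim != 3:
            raise ValueError("movie channels must be (T, H, W)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.green.shape[1:]


class RoiSet:
    """Somatic ROI masks with classes and derived neuropil annuli.

    Masks of class ``interneuron`` / ``surrounding_cell`` are somatic;
    ``astrocyte`` and somatic masks are excluded from every neuropil annulus;
    ``blood_vessel`` masks supply the contamination source for the neuropil
    correction factor alpha.
    """

    CLASSES = ("interneuron", "surrounding_cell", "astrocyte", "blood_vessel")

    def __init__(self, masks, roi_class=None):
        self.masks = [np.asarray(m, dtype=bool) for m in masks]
        if not self.masks:
            raise ValueError("RoiSet requires at least one mask")
        shape = self.masks[0].shape
        for i, m in enumerate(self.masks):
            if m.shape != shape:
                raise ValueError(f"mask {i} shape {m.shape} != {shape}")
        if roi_class is None:
            roi_class = ["interneuron"] * len(self.masks)
        self.roi_class = list(roi_class)
        for c in self.roi_class:
            if c not in self.CLASSES:
                raise ValueError(f"unknown roi_class {c!r}")
        somatic = self.somatic_indices()
        stacked = np.sum([self.masks[i] for i in somatic], axis=0)
        if np.any(stacked > 1):
            raise ValueError("somatic ROI masks must be pairwise disjoint")

    def __len__(self):
        return len(self.masks)

    def somatic_indices(self):
        return [i for i, c in enumerate(self.roi_class)
                if c in ("interneuron", "surrounding_cell")]

    def neuropil_masks(self, radius_px: float = 12.0):
        """Disk around each somatic centroid minus every annotated mask
        (somata, astrocytes and blood vessels are not neuropil)."""
        excluded = np.zeros(self.masks[0].shape, dtype=bool)
        for m in self.masks:
            excluded |= m
        yy, xx = np.indices(self.masks[0].shape)
        out = []
        for i in self.somatic_indices():
            cy, cx = ndimage.center_of_mass(self.masks[i])
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
            out.append(disk & ~excluded)
        return out


@dataclass
class TraceMatrix:
    """Per-ROI time series, either raw fluorescence or dF/F."""

    values: np.ndarray  # (n_cells, T)
    frame_rate_hz: float = 11.25
    kind: str = "raw"  # "raw" or "dff"
    stimulus_log: list = field(default_factory=list)
    cell_ids: list = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.kind == "dff" and not np.all(np.isfinite(self.values)):
            raise ValueError("dF/F traces must be finite")
        if self.cell_ids is None:
            self.cell_ids = list(range(self.values.shape[0]))

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrectionParams:
    """Neuropil correction factor for one imaging spot.

    ``alpha`` is the ratio of blood-vessel fluorescence (pure contamination,
    the vessel itself carries no indicator) to surrounding-neuropil
    fluorescence, estimated once per imaging spot.
    """

    alpha: float
    f_blood_vessel: float = np.nan
    f_surrounding_neuropil: float = np.nan

    def __post_init__(self):
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if not (0.0 <= self.alpha <= 1.5):
            raise ValueError(f"alpha {self.alpha} outside [0, 1.5]")


@dataclass
class TransientFit:
    """Bi-exponential decay fit f(t) = a*exp(b*t) + c*exp(d*t), b,d < 0."""

    a: float
    b: float
    c: float
    d: float
    tau_w: float
    rss: float
    converged: bool


@dataclass
class EventList:
    """Detected spontaneous transients of one trace."""

    peak_frames: np.ndarray
    peak_amplitudes: np.ndarray
    baseline_spans: list  # (start_frame, end_frame) per event

    def __len__(self):
        return len(self.peak_frames)


# ---------------------------------------------------------------------------
# Registration and extraction
# ---------------------------------------------------------------------------

def register_frames(movie: FluorescenceMovie, reference_channel: str = "red",
                    upsample_factor: int = 20):
    """Rigid subpixel registration by phase correlation on the anatomy channel.

    Per-frame translations are estimated on the reference channel against its
    temporal median image and the same shift is applied to both channels.

    Returns
    -------
    registered : FluorescenceMovie
    shifts : ndarray, shape (T, 2)
        Estimated (dy, dx) displacement of each frame relative to the
        reference; the applied correction is the negation.
    flags : ndarray of bool, shape (T,)
        True where a frame was degenerate (constant) and the shift was
        forced to zero.
    """
    ref_stack = movie.red if reference_channel == "red" else movie.green
    reference = np.median(ref_stack, axis=0)
    T = movie.n_frames
    shifts = np.zeros((T, 2))
    flags = np.zeros(T, dtype=bool)
    for t in range(T):
        frame = ref_stack[t]
        if np.ptp(frame) == 0 or np.ptp(reference) == 0:
            flags[t] = True
            warnings.warn(f"degenerate frame {t}: zero shift assumed")
            continue
        shift, _, _ = phase_cross_correlation(
            reference, frame, upsample_factor=upsample_factor,
            normalization=None)
        shifts[t] = shift

    def _apply(stack):
        out = np.empty_like(stack)
        for t in range(T):
            if np.all(shifts[t] == 0):
                out[t] = stack[t]
            else:
                fr = np.fft.fft2(stack[t])
                out[t] = np.fft.ifft2(
                    ndimage.fourier_shift(fr, shifts[t])).real
        return out

    registered = FluorescenceMovie(
        green=_apply(movie.green), red=_apply(movie.red),
        frame_rate_hz=movie.frame_rate_hz,
        stimulus_log=list(movie.stimulus_log), spot_id=movie.spot_id)
    return registered, shifts, flags


def extract_roi_traces(movie: FluorescenceMovie, rois, masks=None) -> TraceMatrix:
    """Mask-mean traces from the functional channel.

    ``rois`` may be a :class:`RoiSet` (somatic masks are used) or ``None``
    with an explicit list of boolean ``masks`` (e.g. neuropil annuli).
    """
    if masks is None:
        if isinstance(rois, RoiSet):
            masks = [rois.masks[i] for i in rois.somatic_indices()]
        else:
            masks = [np.asarray(m, dtype=bool) for m in rois]
    T = movie.n_frames
    values = np.empty((len(masks), T))
    flat = movie.green.reshape(T, -1)
    for i, m in enumerate(masks):
        idx = np.flatnonzero(m.ravel())
        if idx.size == 0:
            raise ValueError(f"ROI {i} has an empty mask")
        values[i] = flat[:, idx].mean(axis=1)
    return TraceMatrix(values, frame_rate_hz=movie.frame_rate_hz, kind="raw",
                       stimulus_log=list(movie.stimulus_log))


def delta_f_over_f(raw: TraceMatrix, bottom_fraction: float = 0.05) -> TraceMatrix:
    """dF/F = (F - F0)/F0 with F0 the mean of the lowest 5% of samples."""
    T = raw.n_frames
    n_low = max(1, int(round(bottom_fraction * T)))
    out = np.empty_like(raw.values)
    for i in range(raw.n_cells):
        trace = raw.values[i]
        f0 = np.sort(trace)[:n_low].mean()
        if f0 <= 0:
            raise ValueError(f"cell {raw.cell_ids[i]}: baseline F0={f0} <= 0")
        out[i] = (trace - f0) / f0
    return TraceMatrix(out, frame_rate_hz=raw.frame_rate_hz, kind="dff",
                       stimulus_log=list(raw.stimulus_log),
                       cell_ids=list(raw.cell_ids))


def estimate_alpha(f_blood_vessel, f_surrounding_neuropil) -> CorrectionParams:
    """alpha = F_blood_vessel / F_surrounding_neuropil for one imaging spot.

    Scalar intensities or traces (averaged over time) are accepted.
    """
    f_bv = float(np.mean(f_blood_vessel))
    f_np = float(np.mean(f_surrounding_neuropil))
    if f_np <= 0:
        raise ValueError("surrounding-neuropil intensity must be positive")
    return CorrectionParams(alpha=f_bv / f_np, f_blood_vessel=f_bv,
                            f_surrounding_neuropil=f_np)


def neuropil_correct(raw: TraceMatrix, neuropil: TraceMatrix,
                     params: CorrectionParams) -> TraceMatrix:
    """F_corrected = F_neuron - alpha * F_neuropil, on raw fluorescence."""
    if raw.values.shape != neuropil.values.shape:
        raise ValueError("raw and neuropil trace matrices must align "
                         f"({raw.values.shape} vs {neuropil.values.shape})")
    corrected = raw.values - params.alpha * neuropil.values
    return TraceMatrix(corrected, frame_rate_hz=raw.frame_rate_hz, kind="raw",
                       stimulus_log=list(raw.stimulus_log),
                       cell_ids=list(raw.cell_ids))


# ---------------------------------------------------------------------------
# Evoked and spontaneous statistics
# ---------------------------------------------------------------------------

def _window_frames(frame_rate_hz, window_s):
    return int(np.floor(window_s * frame_rate_hz))


def evoked_integral(dff: TraceMatrix, onset: int, window_s: float = 8.0,
                    baseline_s: float = 1.0) -> np.ndarray:
    """Per-cell trapezoidal integral (%*s) of baseline-corrected dF/F.

    The baseline is the mean dF/F in the ``baseline_s`` seconds before
    onset. The integral covers the interval from onset to
    ``onset + window_s``; the sample on the right boundary enters only as
    the closing quadrature node, so a constant c%-trace integrates to
    exactly ``c * window_s``.
    """
    fr = dff.frame_rate_hz
    n_win = _window_frames(fr, window_s)
    n_base = _window_frames(fr, baseline_s)
    if onset + n_win + 1 > dff.n_frames:
        raise ValueError(
            f"window [{onset}, {onset + n_win}] exceeds trace length "
            f"{dff.n_frames}")
    if onset - n_base < 0:
        raise ValueError("baseline window precedes trace start")
    seg = dff.values[:, onset:onset + n_win + 1]
    base = dff.values[:, onset - n_base:onset].mean(axis=1, keepdims=True)
    return np.trapezoid((seg - base) * 100.0, dx=1.0 / fr, axis=1)


def evoked_integrals(dff: TraceMatrix, onsets, window_s: float = 8.0,
                     baseline_s: float = 1.0):
    """Trial-wise integrals and their mean over trials.

    Returns ``(per_trial, mean)`` with shapes ``(n_trials, n_cells)`` and
    ``(n_cells,)``; the mean over the 10 evoked trials is the reported
    response magnitude.
    """
    per_trial = np.stack([evoked_integral(dff, o, window_s, baseline_s)
                          for o in onsets])
    return per_trial, per_trial.mean(axis=0)


def _pearson_matrix(values):
    """Pairwise Pearson correlation with zero-variance traces set to NaN."""
    sd = values.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    bad = sd == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    return corr


def evoked_correlation(dff: TraceMatrix, onsets, window_s: float = 17.4):
    """Zero-lag Pearson correlations on single-trial evoked windows.

    Returns
    -------
    per_trial : ndarray, shape (n_trials, n_cells, n_cells)
    averaged : ndarray, shape (n_cells, n_cells)
        NaN-aware mean over trials; pairs undefined in every trial stay NaN.
    """
    fr = dff.frame_rate_hz
    n_win = _window_frames(fr, window_s)
    mats = []
    for onset in onsets:
        if onset + n_win > dff.n_frames:
            raise ValueError(f"evoked window at onset {onset} exceeds trace")
        mats.append(_pearson_matrix(dff.values[:, onset:onset + n_win]))
    per_trial = np.stack(mats)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        averaged = np.nanmean(per_trial, axis=0)
    return per_trial, averaged


def spontaneous_correlation(dff: TraceMatrix, n_segments: int = 1000,
                            segment_s: float = 17.4, seed: int = 0):
    """Segment-resampled spontaneous pairwise correlations.

    ``n_segments`` window starts are drawn uniformly with replacement from
    the feasible range and the per-pair correlation is the mean over
    segments, removing trace-length-dependent correlation fluctuations so
    spontaneous and evoked correlations are comparable.

    Returns
    -------
    matrix : ndarray (n_cells, n_cells)
    spot_mean : float
        Mean of the off-diagonal entries — the per-imaging-spot summary.
    """
    fr = dff.frame_rate_hz
    L = _window_frames(fr, segment_s)
    if dff.n_frames < L:
        raise ValueError(
            f"recording ({dff.n_frames} frames) shorter than one "
            f"{segment_s} s segment ({L} frames)")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, dff.n_frames - L + 1, size=n_segments)
    acc = np.zeros((dff.n_cells, dff.n_cells))
    cnt = np.zeros_like(acc)
    for s in starts:
        m = _pearson_matrix(dff.values[:, s:s + L])
        ok = np.isfinite(m)
        acc[ok] += m[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        matrix = acc / cnt
    off = ~np.eye(dff.n_cells, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spot_mean = float(np.nanmean(matrix[off])) if dff.n_cells > 1 else np.nan
    return matrix, spot_mean


# ---------------------------------------------------------------------------
# Event detection and transient fitting
# ---------------------------------------------------------------------------

def _robust_noise_sd(trace):
    # MAD of the first difference is insensitive to the transients themselves
    d = np.diff(trace)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2))


def detect_events(trace, frame_rate_hz: float, min_snr: float = 3.0,
                  baseline_flat_s: float = 1.5,
                  max_baseline_slope: float = 2.0,
                  decay_fit_s: float = 4.0,
                  min_r2: float = 0.5) -> EventList:
    """Detect calcium transients: a prominent peak preceded by a flat
    baseline and followed by an exponential-like decay.

    A candidate peak (prominence >= ``min_snr`` * robust noise sd) is
    accepted iff the ``baseline_flat_s`` window before it has
    ``|slope| <= max_baseline_slope * noise_sd`` per second and a
    single-exponential fit of the decay reaches R^2 >= ``min_r2``.
    An empty list is a valid result.
    """
    trace = np.asarray(trace, dtype=float)
    sigma = _robust_noise_sd(trace)
    n_base = max(2, _window_frames(frame_rate_hz, baseline_flat_s))
    if sigma == 0:
        # noiseless: any positive prominence is a real deflection
        prominence = 1e-12
        slope_cap = np.inf
    else:
        prominence = min_snr * sigma
        slope_cap = max_baseline_slope * sigma
    peaks, _ = signal.find_peaks(trace, prominence=prominence)
    n_decay = max(5, _window_frames(frame_rate_hz, decay_fit_s))
    t_ax = np.arange(n_decay) / frame_rate_hz

    kept, amps, spans = [], [], []
    for p in peaks:
        lo = p - n_base
        if lo < 0:
            continue
        base = trace[lo:p]
        tt = np.arange(base.size) / frame_rate_hz
        slope = np.polyfit(tt, base, 1)[0]
        if abs(slope) > slope_cap:
            continue
        seg = trace[p:p + n_decay]
        if seg.size < 5:
            continue
        ts = t_ax[:seg.size]
        floor = seg.min()
        amp0 = max(seg[0] - floor, 1e-12)
        try:
            popt, _ = optimize.curve_fit(
                lambda t, A, tau, off: A * np.exp(-t / tau) + off,
                ts, seg, p0=(amp0, 1.0, floor),
                bounds=([0, 1e-3, -np.inf], [np.inf, 60.0, np.inf]),
                maxfev=2000)
            fit = popt[0] * np.exp(-ts / popt[1]) + popt[2]
            tss = np.sum((seg - seg.mean()) ** 2)
            r2 = 1.0 - np.sum((seg - fit) ** 2) / tss if tss > 0 else 0.0
        except Exception:
            r2 = -np.inf
        if r2 < min_r2:
            continue
        kept.append(p)
        amps.append(trace[p] - base.mean())
        spans.append((lo, p))
    return EventList(np.asarray(kept, dtype=int), np.asarray(amps, dtype=float),
                     spans)


def weighted_tau(a: float, b: float, c: float, d: float) -> float:
    """Amplitude-weighted decay constant of f(t)=a*exp(b*t)+c*exp(d*t).

    tau_w = (a*(-1/b) + c*(-1/d)) / (a + c), with b, d < 0.
    """
    if a + c == 0:
        raise ValueError("a + c must be nonzero")
    terms = 0.0
    if a != 0:
        if b >= 0:
            raise ValueError("rate b must be negative when a != 0")
        terms += a * (-1.0 / b)
    if c != 0:
        if d >= 0:
            raise ValueError("rate d must be negative when c != 0")
        terms += c * (-1.0 / d)
    return terms / (a + c)


def _biexp(t, a, b, c, d):
    return a * np.exp(b * t) + c * np.exp(d * t)


def fit_biexponential(segment, frame_rate_hz: float,
                      init_taus=(0.2, 1.0, 5.0)) -> TransientFit:
    """Nonlinear least-squares bi-exponential fit of a decay segment.

    The segment must start at the transient peak. The model is
    ``f(t) = a*exp(b*t) + c*exp(d*t)`` with ``a, c >= 0`` and ``b, d < 0``;
    initialization is multi-start over a grid of decay-constant pairs with
    amplitudes from a linear solve, the ordering tie is broken by enforcing
    ``b <= d`` (fast component first). On optimizer failure a
    single-exponential fallback populates ``(a, b)`` with ``c = 0``.
    """
    y = np.asarray(segment, dtype=float)
    if y.size < 10:
        raise ValueError(f"decay segment needs >= 10 samples, got {y.size}")
    t = np.arange(y.size) / frame_rate_hz

    lb = np.array([0.0, -100.0, 0.0, -100.0])
    ub = np.array([np.inf, -1e-6, np.inf, -1e-6])

    def residual(p):
        return _biexp(t, *p) - y

    best = None
    for tb in init_taus:
        for td in init_taus:
            if td < tb:
                continue
            b0, d0 = -1.0 / tb, -1.0 / td
            basis = np.column_stack([np.exp(b0 * t), np.exp(d0 * t)])
            amp, _ = optimize.nnls(basis, np.clip(y, 0, None))
            a0 = max(amp[0], 1e-9)
            c0 = max(amp[1], 1e-9)
            p0 = np.clip([a0, b0, c0, d0], lb, ub - 1e-12)
            try:
                res = optimize.least_squares(residual, p0, bounds=(lb, ub),
                                             method="trf", max_nfev=400)
            except Exception:
                continue
            rss = float(2.0 * res.cost)
            if best is None or rss < best[1]:
                best = (res, rss)

    if best is not None and best[0].success:
        a, b, c, d = best[0].x
        if b > d:  # enforce fast rate first
            a, b, c, d = c, d, a, b
        rss = best[1]
        converged = True
    else:
        # single-exponential fallback
        def res1(p):
            return p[0] * np.exp(p[1] * t) - y
        p0 = np.array([max(y[0], 1e-9), -1.0])
        r = optimize.least_squares(res1, p0,
                                   bounds=([0, -100.0], [np.inf, -1e-6]))
        a, b = r.x
        c, d = 0.0, -1.0
        rss = float(2.0 * r.cost)
        converged = False
    tau = weighted_tau(a, b, c if converged else 0.0, d)
    return TransientFit(a=float(a), b=float(b),
                        c=float(c) if converged else 0.0, d=float(d),
                        tau_w=float(tau), rss=rss, converged=converged)
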