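"""Synthetic ground-truth generators for every pipeline arm.

Each generator emulates the statistical structure of the corresponding
recording modality — two-channel ~11.25 Hz calcium movies driven by spiking
with bi-exponential transient kinetics and controllable pairwise
correlation, two-channel 3D puncta stacks with planted colocalized pairs,
clustered-plus-dispersed 2D presynaptic point fields around starter cells,
and 20x20 photostimulation grids with planted inward/outward currents —
with the planted truth returned alongside, so every downstream estimator is
testable without any recorded data. All generators are deterministic given
their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calcium import FluorescenceMovie
from .coloc import PunctaStack
from .ephys import DEFAULT_LAYER_BOUNDS, StepRecording, UncagingGrid
from .tracing import TracingPointSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_transient",
    "simulate_activity",
    "simulate_population",
    "simulate_puncta_stack",
    "simulate_tracing_points",
    "simulate_uncaging_grid",
    "simulate_step_recording",
]


# ---------------------------------------------------------------------------
# Calcium movies
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Conditions for a simulated two-channel population movie.

    The transient kernel is a decaying bi-exponential
    ``a*exp(b*t) + c*exp(d*t)`` (amplitudes in dF/F fraction, rates in 1/s,
    strictly negative); defaults give a weighted decay constant of ~1.1 s,
    in the range of somatic OGB-1 transients. Global network events recruit
    each cell with ``participation_prob``; private events are per-cell
    Poisson. ``neuropil_alpha_true`` scales the shared neuropil signal
    added to somatic pixels.
    """

    seed: int = 0
    frame_rate_hz: float = 11.25
    movie_shape: tuple = (1200, 64, 64)  # (frames, height, width)
    n_cells: int = 8
    transient_kernel: tuple = (0.6, -2.0, 0.4, -0.5)  # (a, b, c, d)
    participation_prob: float = 0.5
    global_event_rate_hz: float = 0.1
    private_event_rate_hz: float = 0.05
    noise_sd: float = 0.0
    drift_series: np.ndarray = None  # (frames, 2) of (dy, dx) px
    neuropil_alpha_true: float = 0.7
    evoked_onset_frames: tuple = ()
    evoked_paradigms: tuple = ()  # "single" | "multi", parallel to onsets
    evoked_gain: dict = field(
        default_factory=lambda: {"single": 1.0, "multi": 1.6})
    cell_baseline: float = 100.0
    neuropil_baseline: float = 40.0
    cell_radius_px: float = 3.0

    def __post_init__(self):
        a, b, c, d = self.transient_kernel
        if (a != 0 and b >= 0) or (c != 0 and d >= 0):
            raise ValueError("kernel rates must be negative where the "
                             "amplitude is nonzero")
        if not 0.0 <= self.participation_prob <= 1.0:
            raise ValueError("participation_prob must lie in [0, 1]")
        if self.private_event_rate_hz < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be nonnegative")
        if not 0.0 <= self.neuropil_alpha_true <= 1.0:
            raise ValueError("neuropil_alpha_true must lie in [0, 1]")
        if len(self.evoked_onset_frames) != len(self.evoked_paradigms):
            raise ValueError("evoked onsets and paradigms must be parallel")


@dataclass
class GroundTruth:
    roi_masks: list                # per-cell boolean (H, W)
    spike_times: list              # per-cell sorted event times, s
    event_labels: list             # per-cell "global"/"private"/"evoked"
    true_traces: np.ndarray        # noiseless per-cell dF/F, (n_cells, T)
    planted_shift_series: np.ndarray
    blood_vessel_mask: np.ndarray = None
    neuropil_signal: np.ndarray = None
    alpha_true: float = np.nan


def simulate_transient(kernel, duration_s, frame_rate_hz, noise_sd=0.0,
                       seed=0):
    """One bi-exponential transient sampled at the frame rate.

    ``trace[k] = a*exp(b*t_k) + c*exp(d*t_k) + eps_k`` with
    ``t_k = k / frame_rate_hz`` and iid Gaussian noise of sd ``noise_sd``.
    """
    a, b, c, d = kernel
    if (a != 0 and b >= 0) or (c != 0 and d >= 0):
        raise ValueError("decay rates must be negative for nonzero amplitudes")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    t = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    trace = a * np.exp(b * t) + c * np.exp(d * t)
    if noise_sd > 0:
        trace = trace + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=t.size)
    return trace


def _kernel_samples(kernel, frame_rate_hz, tail_s=12.0):
    a, b, c, d = kernel
    t = np.arange(0.0, tail_s, 1.0 / frame_rate_hz)
    return a * np.exp(b * t) + c * np.exp(d * t)


def simulate_activity(config: SimConfig):
    """Spike trains and noiseless dF/F traces, without movie rendering.

    Global events occur as a Poisson process and recruit each cell
    independently with ``participation_prob``; private events are per-cell
    Poisson; evoked onsets recruit every cell with a paradigm-dependent
    amplitude gain. Traces are the linear convolution of the frame-binned
    event train with the transient kernel (no saturation).

    Returns ``(true_traces, spike_times, event_labels)``.
    """
    rng = np.random.default_rng(config.seed)
    T = config.movie_shape[0]
    fr = config.frame_rate_hz
    duration = T / fr
    kern = _kernel_samples(config.transient_kernel, fr)

    n_global = rng.poisson(config.global_event_rate_hz * duration)
    global_times = np.sort(rng.uniform(0.0, duration, size=n_global))
    traces = np.zeros((config.n_cells, T))
    spike_times, labels = [], []
    for i in range(config.n_cells):
        times, labs, gains = [], [], []
        joined = rng.random(n_global) < config.participation_prob
        for tt in global_times[joined]:
            times.append(tt)
            labs.append("global")
            gains.append(1.0)
        n_priv = rng.poisson(config.private_event_rate_hz * duration)
        for tt in np.sort(rng.uniform(0.0, duration, size=n_priv)):
            times.append(tt)
            labs.append("private")
            gains.append(1.0)
        for onset, paradigm in zip(config.evoked_onset_frames,
                                   config.evoked_paradigms):
            times.append(onset / fr)
            labs.append("evoked")
            gains.append(config.evoked_gain[paradigm])
        order = np.argsort(times)
        times = np.asarray(times)[order]
        labs = [labs[k] for k in order]
        gains = np.asarray(gains)[order]

        train = np.zeros(T)
        frames = np.minimum((times * fr).astype(int), T - 1)
        np.add.at(train, frames, gains)
        traces[i] = np.convolve(train, kern)[:T]
        spike_times.append(times)
        labels.append(labs)
    return traces, spike_times, labels


def _disk_mask(shape, cy, cx, radius):
    yy, xx = np.indices(shape)
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _place_cells(shape, n_cells, radius, rng, margin=6, min_gap=4):
    """Disjoint disk ROIs by rejection sampling."""
    centers = []
    H, W = shape
    for _ in range(10_000):
        if len(centers) == n_cells:
            break
        cy = rng.uniform(margin, H - margin)
        cx = rng.uniform(margin, W - margin)
        if all(np.hypot(cy - y, cx - x) >= 2 * radius + min_gap
               for y, x in centers):
            centers.append((cy, cx))
    if len(centers) < n_cells:
        raise RuntimeError("could not place all cell ROIs; reduce n_cells "
                           "or enlarge the field")
    return [_disk_mask(shape, cy, cx, radius) for cy, cx in centers], centers


def simulate_population(config: SimConfig):
    """Render a two-channel population movie with full ground truth.

    Channel green (functional): somatic pixels carry
    ``baseline * (1 + dF/F)`` plus ``alpha_true`` times the shared neuropil
    signal; non-somatic pixels carry the neuropil signal alone; a
    blood-vessel stripe carries only the alpha-scaled neuropil signal (the
    contamination source used to estimate alpha). Channel red: static cell
    bodies. Frames are rigidly displaced by ``drift_series`` and Gaussian
    noise of sd ``noise_sd`` (in units of the cell baseline) is added.
    """
    T, H, W = config.movie_shape
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    traces, spike_times, labels = simulate_activity(config)

    masks, centers = _place_cells((H, W), config.n_cells,
                                  config.cell_radius_px, rng)
    vessel = np.zeros((H, W), dtype=bool)
    vessel[:, :2] = True  # vertical vessel stripe at the field edge
    for m in masks:
        vessel &= ~m

    # shared neuropil signal follows the population mean activity
    pop = traces.mean(axis=0) if config.n_cells else np.zeros(T)
    neuropil = config.neuropil_baseline * (1.0 + 0.5 * pop)  # (T,)

    green = np.broadcast_to(neuropil[:, None, None], (T, H, W)).copy()
    alpha = config.neuropil_alpha_true
    green[:, vessel] = alpha * neuropil[:, None]
    for i, m in enumerate(masks):
        soma = config.cell_baseline * (1.0 + traces[i])
        green[:, m] = soma[:, None] + alpha * neuropil[:, None]

    red = np.full((H, W), 10.0)
    for m in masks:
        red[m] = 200.0
    red = np.broadcast_to(red, (T, H, W)).copy()

    drift = (np.zeros((T, 2)) if config.drift_series is None
             else np.asarray(config.drift_series, dtype=float))
    if drift.shape != (T, 2):
        raise ValueError("drift_series must be (frames, 2)")
    if np.any(drift != 0):
        for t in range(T):
            if np.any(drift[t] != 0):
                green[t] = ndimage.shift(green[t], drift[t], order=1,
                                         mode="nearest")
                red[t] = ndimage.shift(red[t], drift[t], order=1,
                                       mode="nearest")
    if config.noise_sd > 0:
        scale = config.noise_sd * config.cell_baseline
        green = green + rng.normal(0.0, scale, size=green.shape)
        red = red + rng.normal(0.0, scale, size=red.shape)

    log = [{"onset_frame": int(o), "paradigm": p}
           for o, p in zip(config.evoked_onset_frames,
                           config.evoked_paradigms)]
    movie = FluorescenceMovie(green=green, red=red,
                              frame_rate_hz=config.frame_rate_hz,
                              stimulus_log=log)
    truth = GroundTruth(roi_masks=masks, spike_times=spike_times,
                        event_labels=labels, true_traces=traces,
                        planted_shift_series=drift,
                        blood_vessel_mask=vessel,
                        neuropil_signal=neuropil, alpha_true=alpha)
    return movie, truth


# ---------------------------------------------------------------------------
# Puncta stacks
# ---------------------------------------------------------------------------

def simulate_puncta_stack(shape_zyx=(16, 96, 96), voxel_size_um=(0.47, 0.2, 0.2),
                          n_coloc=7, n_ch1_only=5, n_ch2_only=5, snr=10.0,
                          seed=0, sigma_vox=(1.0, 1.3, 1.3),
                          amplitude=100.0, max_retries=20_000):
    """Two-channel 3D stack with planted Gaussian puncta.

    Channel 1 holds ``n_coloc + n_ch1_only`` puncta and channel 2
    ``n_coloc + n_ch2_only``; the ``n_coloc`` pairs share a center and thus
    overlap voxel-wise. Planted centers are kept at least three punctum
    diameters apart (diameter = Gaussian FWHM, the punctum's apparent
    size). Punctum depths are stratified across the stack so that every
    optical section contains signal, as in densely immunostained tissue —
    this anchors slice-adaptive thresholds downstream. Gaussian background
    noise has sd ``amplitude / snr``.

    Returns ``(stack, truth)`` with truth a dict carrying planted centers
    per channel and ``overlap_count``.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(shape_zyx)
    sig = np.asarray(sigma_vox, dtype=float)
    diameter = 2.355 * np.max(sig)  # FWHM, in voxels
    min_sep = 3.0 * diameter
    margin_z = sig[0]  # boundary sections still carry strong signal
    margin_xy = 1.5 * np.max(sig)

    n_total = n_coloc + n_ch1_only + n_ch2_only
    # Stratified depths on a shared grid spanning [margin_z, Z - margin_z]
    # (boundaries included): colocalized pairs take interleaved positions
    # and the single-channel puncta fill the remaining depths in each
    # channel, so both channels carry signal in every optical section.
    m = max(1, n_coloc + max(n_ch1_only, n_ch2_only))
    grid_z = (np.linspace(margin_z, shape[0] - margin_z, m) if m > 1
              else np.array([shape[0] / 2.0]))
    # colocalized pairs sit at interior depths (an edge-cut punctum has a
    # fragile thin mask); the single-channel puncta claim the boundary
    # depths and keep the edge sections anchored in both channels
    if n_coloc:
        coloc_idx = np.unique(np.round(
            np.linspace(0, m - 1, n_coloc + 2)).astype(int)[1:-1])
        k = 1
        while coloc_idx.size < n_coloc:  # degenerate small-m fallback
            coloc_idx = np.unique(np.r_[coloc_idx, k])
            k += 1
    else:
        coloc_idx = np.array([], dtype=int)
    other_idx = np.array([i for i in range(m) if i not in set(coloc_idx)],
                         dtype=int)

    def _pick(idx, k):
        if k == 0 or idx.size == 0:
            return np.empty(0)
        sel = np.round(np.linspace(0, idx.size - 1, k)).astype(int)
        return grid_z[idx[sel]]

    z_coords = np.concatenate([grid_z[coloc_idx],
                               _pick(other_idx, n_ch1_only),
                               _pick(other_idx, n_ch2_only)])
    centers = []
    tries = 0
    while len(centers) < n_total:
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"could not place {n_total} puncta with separation "
                f"{min_sep:.1f} vox in shape {shape}")
        k = len(centers)
        cand = np.array([z_coords[k],
                         rng.uniform(margin_xy, shape[1] - margin_xy),
                         rng.uniform(margin_xy, shape[2] - margin_xy)])
        if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
            centers.append(cand)
    centers = np.asarray(centers)
    c_coloc = centers[:n_coloc]
    c_ch1 = centers[n_coloc:n_coloc + n_ch1_only]
    c_ch2 = centers[n_coloc + n_ch1_only:]

    zz, yy, xx = np.indices(shape)

    def render(center_list):
        img = np.zeros(shape)
        for cz, cy, cx in center_list:
            img += amplitude * np.exp(
                -((zz - cz) ** 2 / (2 * sig[0] ** 2)
                  + (yy - cy) ** 2 / (2 * sig[1] ** 2)
                  + (xx - cx) ** 2 / (2 * sig[2] ** 2)))
        return img

    noise_sd = amplitude / snr if snr > 0 else 0.0
    ch1 = render(np.vstack([c_coloc, c_ch1]) if n_coloc + n_ch1_only else
                 np.empty((0, 3)))
    ch2 = render(np.vstack([c_coloc, c_ch2]) if n_coloc + n_ch2_only else
                 np.empty((0, 3)))
    if noise_sd > 0:
        ch1 = np.clip(ch1 + rng.normal(0, noise_sd, shape), 0, None)
        ch2 = np.clip(ch2 + rng.normal(0, noise_sd, shape), 0, None)
    stack = PunctaStack(channel1=ch1, channel2=ch2,
                        voxel_size_um=tuple(voxel_size_um))
    truth = {"centers_coloc": c_coloc, "centers_ch1_only": c_ch1,
             "centers_ch2_only": c_ch2, "overlap_count": int(n_coloc)}
    return stack, truth


# ---------------------------------------------------------------------------
# Tracing point fields
# ---------------------------------------------------------------------------

def simulate_tracing_points(n_starters=5, n_presyn=500, local_sd_um=80.0,
                            dispersed_fraction=0.2, ring_radius_um=600.0,
                            seed=0, starter_field_um=200.0,
                            cell_type="synthetic") -> TracingPointSet:
    """Clustered-plus-dispersed presynaptic field around starter cells.

    Starters are uniform in a central ``starter_field_um`` square. Each
    presynaptic cell is local with probability ``1 - dispersed_fraction``
    (2D Gaussian of sd ``local_sd_um`` around a random starter) and
    dispersed otherwise (area-uniform annulus of outer radius
    ``ring_radius_um``, inner radius half of that, around a random starter).
    Larger dispersed fractions shift the distance CDF rightward.
    """
    if n_starters < 1 or n_presyn < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 <= dispersed_fraction <= 1.0:
        raise ValueError("dispersed_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    half = starter_field_um / 2.0
    starters = rng.uniform(-half, half, size=(n_starters, 2))
    pre = np.empty((n_presyn, 2))
    anchor = starters[rng.integers(0, n_starters, size=n_presyn)]
    dispersed = rng.random(n_presyn) < dispersed_fraction
    n_disp = int(dispersed.sum())
    # local component
    pre[~dispersed] = anchor[~dispersed] + rng.normal(
        0.0, local_sd_um, size=(n_presyn - n_disp, 2))
    # dispersed component: area-uniform radius (r ~ sqrt(u)) avoids center bias
    r_in = ring_radius_um / 2.0
    u = rng.random(n_disp)
    r = np.sqrt(u * (ring_radius_um ** 2 - r_in ** 2) + r_in ** 2)
    theta = rng.uniform(0.0, 2 * np.pi, size=n_disp)
    pre[dispersed] = anchor[dispersed] + np.column_stack(
        [r * np.cos(theta), r * np.sin(theta)])
    return TracingPointSet(starters=starters, presynaptic=pre,
                           cell_type=cell_type)


# ---------------------------------------------------------------------------
# Uncaging grids and step protocols
# ---------------------------------------------------------------------------

def simulate_uncaging_grid(grid_shape=(20, 20), planted_inputs=(),
                           baseline_pA=0.0, noise_sd_pA=0.0,
                           sampling_hz=10_000.0, sweep_duration_s=1.0,
                           illumination_onset_s=0.5, n_sweeps=3,
                           site_spacing_um=50.0, soma_xy_um=(500.0, 200.0),
                           layer_bounds_um=None, holding_mv=-45.0,
                           seed=0) -> UncagingGrid:
    """Photostimulation grid with planted postsynaptic currents.

    ``planted_inputs`` entries are dicts
    ``{"site": (row, col), "amplitude_pA": float, "onset_ms": float,
    "dur_ms": float, "shape": "square"|"alpha"}``; onsets are measured from
    sweep start and must not fall inside the 500 ms pre-illumination
    baseline. Negative amplitudes are inward (excitatory), positive outward
    (inhibitory). Every site holds ``n_sweeps`` sweeps at ``sampling_hz``.
    """
    rows, cols = grid_shape
    n = int(round(sweep_duration_s * sampling_hz))
    base_end_s = illumination_onset_s
    for inp in planted_inputs:
        if inp["onset_ms"] / 1000.0 < base_end_s:
            raise ValueError(
                f"planted onset {inp['onset_ms']} ms falls inside the "
                f"{base_end_s * 1000:.0f} ms baseline window")
        if (inp["onset_ms"] + inp["dur_ms"]) / 1000.0 > sweep_duration_s:
            raise ValueError("planted input extends beyond the sweep")
    rng = np.random.default_rng(seed)
    sweeps = np.full((rows, cols, n_sweeps, n), float(baseline_pA))
    if noise_sd_pA > 0:
        sweeps += rng.normal(0.0, noise_sd_pA, size=sweeps.shape)
    t = np.arange(n) / sampling_hz
    for inp in planted_inputs:
        r, c = inp["site"]
        on = inp["onset_ms"] / 1000.0
        dur = inp["dur_ms"] / 1000.0
        shape = inp.get("shape", "square")
        if shape == "square":
            wave = np.where((t >= on) & (t < on + dur),
                            inp["amplitude_pA"], 0.0)
        elif shape == "alpha":
            tau = dur / 4.0
            s = np.clip(t - on, 0.0, None)
            wave = inp["amplitude_pA"] * (s / tau) * np.exp(1.0 - s / tau)
            wave[t < on] = 0.0
        else:
            raise ValueError("planted input shape must be 'square' or 'alpha'")
        sweeps[r, c] += wave
    return UncagingGrid(sweeps=sweeps, sampling_hz=sampling_hz,
                        illumination_onset_s=illumination_onset_s,
                        site_spacing_um=site_spacing_um,
                        soma_xy_um=tuple(soma_xy_um),
                        layer_bounds_um=dict(layer_bounds_um
                                             or DEFAULT_LAYER_BOUNDS),
                        holding_mv=holding_mv)


def simulate_step_recording(step_pA=(-40, -20, 20, 200), rest_mV=-65.0,
                            resistance_Mohm=100.0, threshold_mV=-40.0,
                            spike_peak_mV=40.0, half_width_ms=1.0,
                            ahp_mV=12.0, rheobase_pA=50.0,
                            sampling_hz=10_000.0,
                            noise_sd_mV=0.0, seed=0) -> StepRecording:
    """Stylized current-clamp step protocol with one planted spike.

    Subthreshold sweeps deflect ohmically by ``I * R``; the largest
    depolarizing sweep at or above ``rheobase_pA`` carries a triangular
    spike of known threshold, peak, base width (2 x half-width) and AHP, so
    the extraction of the five intrinsic properties can be checked against
    planted values.
    """
    step_pA = np.asarray(step_pA, dtype=float)
    fs = sampling_hz
    onset_s, dur_s = 0.1, 0.5
    n = int(round((onset_s + dur_s + 0.1) * fs))
    on = int(round(onset_s * fs))
    off = int(round((onset_s + dur_s) * fs))
    t_spike = on + int(round(0.05 * fs))
    V = np.full((step_pA.size, n), rest_mV)
    rng = np.random.default_rng(seed)
    i_max = int(np.argmax(step_pA))
    for i, I in enumerate(step_pA):
        if I <= 0 or i != i_max or I < rheobase_pA:
            dv = I * 1e-3 * resistance_Mohm  # pA * MOhm -> mV (sub-threshold)
            V[i, on:off] += dv
            continue
        V[i, on:off] += (threshold_mV - rest_mV)
        # symmetric triangular spike (base = 2 x half-width, so the width at
        # half height equals the planted half-width), then an AHP dip
        half_n = max(2, int(round(half_width_ms / 1000.0 * fs)))
        up = np.linspace(threshold_mV, spike_peak_mV, half_n, endpoint=False)
        down = np.linspace(spike_peak_mV, threshold_mV, half_n,
                           endpoint=False)
        dip_n = max(2, half_n)
        dip = np.linspace(threshold_mV, threshold_mV - ahp_mV, dip_n,
                          endpoint=False)
        wave = np.concatenate([up, down, dip, [threshold_mV - ahp_mV]])
        V[i, t_spike:t_spike + wave.size] = wave[:max(0, n - t_spike)]
        # relax AHP back to the step plateau
        k0 = t_spike + wave.size
        relax = np.linspace(threshold_mV - ahp_mV, threshold_mV,
                            max(1, off - k0))
        V[i, k0:off] = relax[:off - k0]
    if noise_sd_mV > 0:
        V += rng.normal(0.0, noise_sd_mV, size=V.shape)
    return StepRecording(voltage_mV=V, step_pA=step_pA, sampling_hz=fs,
                         step_onset_s=onset_s, step_duration_s=dur_s)
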