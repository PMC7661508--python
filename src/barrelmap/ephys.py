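"""Photostimulation input-map analysis and intrinsic membrane properties.

Glutamate-uncaging maps: a slice is divided into a 20x20 grid of
photostimulation sites; per-site voltage-clamp sweeps are baseline-subtracted
(mean of the 500 ms before illumination) and integrated inside a calibration
time window. At -45 mV, deflections below baseline are excitatory and above
baseline inhibitory; charges are reported in pC, normalized per cortical
layer against the field-of-view mean, and profiled against lateral distance
from the recorded soma. The -70 mV / TTX protocol isolates synaptic input by
subtracting the direct (TTX-resistant) map. Current-clamp step protocols
(500 ms, delta +20 pA) yield membrane resistance, spike threshold, height,
half-width and AHP amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UncagingGrid",
    "AnalysisWindow",
    "InputMap",
    "IntrinsicProperties",
    "StepRecording",
    "calibration_window",
    "site_charges",
    "grid_charge_maps",
    "layer_normalized_map",
    "normalize_map",
    "lateral_profile",
    "ttx_subtract",
    "intrinsic_properties",
]

DEFAULT_LAYER_BOUNDS = {
    "L1": (0.0, 100.0),
    "L2/3": (100.0, 350.0),
    "L4": (350.0, 550.0),
    "L5/6": (550.0, 1000.0),
}
SUPERFICIAL_LAYERS = ("L1", "L2/3")


@dataclass
class AnalysisWindow:
    """Seconds from sweep start; [start, end) bounds the evoked-current
    integration, anchored at the first calibration AP peak."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise ValueError("window end must exceed start")


@dataclass
class UncagingGrid:
    """Gridded photostimulation sweeps for one recorded cell.

    ``sweeps`` is (rows, cols, n_sweeps, n_samples) in pA at
    ``sampling_hz``; rows index cortical depth (y), cols lateral position
    (x). Site centers are on a regular grid with ``site_spacing_um`` pitch,
    site (r, c) at ((c + 0.5) * pitch, (r + 0.5) * pitch) in (x, y) um.
    """

    sweeps: np.ndarray
    sampling_hz: float = 10_000.0
    illumination_onset_s: float = 0.5
    site_spacing_um: float = 50.0
    soma_xy_um: tuple = (500.0, 200.0)
    layer_bounds_um: dict = field(
        default_factory=lambda: dict(DEFAULT_LAYER_BOUNDS))
    holding_mv: float = -45.0

    def __post_init__(self):
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 4:
            raise ValueError("sweeps must be (rows, cols, n_sweeps, n_samples)")
        if self.illumination_onset_s * self.sampling_hz < 0.5 * self.sampling_hz:
            raise ValueError("every sweep needs >= 500 ms pre-illumination")

    @property
    def grid_shape(self):
        return self.sweeps.shape[:2]

    def site_depth_um(self, row: int) -> float:
        return (row + 0.5) * self.site_spacing_um

    def site_x_um(self, col: int) -> float:
        return (col + 0.5) * self.site_spacing_um

    def layer_of_row(self, row: int) -> str:
        """Layer of a grid row; a site exactly on a boundary goes to the
        upper (more superficial) layer."""
        depth = self.site_depth_um(row)
        for name, (lo, hi) in self.layer_bounds_um.items():
            if lo < depth <= hi:
                return name
        if depth <= min(lo for lo, _ in self.layer_bounds_um.values()):
            return next(iter(self.layer_bounds_um))
        raise ValueError(f"row {row} (depth {depth} um) outside layer spans")


@dataclass
class InputMap:
    """Per-site excitatory/inhibitory charge (pC) for one recorded cell."""

    excitatory_pC: np.ndarray  # (rows, cols), >= 0
    inhibitory_pC: np.ndarray
    grid: UncagingGrid = None


@dataclass
class IntrinsicProperties:
    membrane_resistance_Mohm: float
    spike_threshold_mV: float
    spike_height_mV: float
    spike_half_width_ms: float
    ahp_amplitude_mV: float


@dataclass
class StepRecording:
    """Current-clamp step protocol: (n_steps, n_samples) voltage sweeps in
    mV for injected step currents ``step_pA`` (500 ms steps by default)."""

    voltage_mV: np.ndarray
    step_pA: np.ndarray
    sampling_hz: float = 10_000.0
    step_onset_s: float = 0.1
    step_duration_s: float = 0.5


# ---------------------------------------------------------------------------
# Input maps
# ---------------------------------------------------------------------------

def calibration_window(ap_peak_times_s, margin_ms: float = 10.0) -> AnalysisWindow:
    """Analysis window from calibration AP peaks: first peak to last peak
    plus a margin. Capturing only this span keeps the charge estimate
    monosynaptic-dominated."""
    times = np.sort(np.asarray(ap_peak_times_s, dtype=float))
    if times.size == 0:
        raise ValueError("at least one AP peak time is required")
    return AnalysisWindow(start_s=float(times[0]),
                          end_s=float(times[-1] + margin_ms / 1000.0))


def site_charges(sweeps, window: AnalysisWindow, sampling_hz: float,
                 illumination_onset_s: float):
    """(excitatory pC, inhibitory pC) of one site, averaged over sweeps.

    Each sweep is baseline-subtracted with the mean of the 500 ms before
    illumination; within the half-open window, negative deviations are
    rectified and integrated into excitatory charge and positive deviations
    into inhibitory charge (1 pA * 1 s = 1 pC). Sweeps are integrated first
    and averaged after.
    """
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    n = sweeps.shape[1]
    fs = sampling_hz
    base_lo = int(round((illumination_onset_s - 0.5) * fs))
    base_hi = int(round(illumination_onset_s * fs))
    if base_lo < 0:
        raise ValueError("missing 500 ms pre-illumination baseline span")
    w_lo = int(round(window.start_s * fs))
    w_hi = int(round(window.end_s * fs))
    if w_hi > n or w_lo < 0:
        raise ValueError(f"analysis window [{window.start_s}, {window.end_s}) s "
                         "outside sweep")
    dt = 1.0 / fs
    exc = np.empty(sweeps.shape[0])
    inh = np.empty(sweeps.shape[0])
    for i, sw in enumerate(sweeps):
        dev = sw[w_lo:w_hi] - sw[base_lo:base_hi].mean()
        exc[i] = -np.sum(np.minimum(dev, 0.0)) * dt
        inh[i] = np.sum(np.maximum(dev, 0.0)) * dt
    return float(exc.mean()), float(inh.mean())


def grid_charge_maps(grid: UncagingGrid, window: AnalysisWindow) -> InputMap:
    """Per-site excitatory/inhibitory charge maps for a whole grid."""
    rows, cols = grid.grid_shape
    exc = np.empty((rows, cols))
    inh = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            exc[r, c], inh[r, c] = site_charges(
                grid.sweeps[r, c], window, grid.sampling_hz,
                grid.illumination_onset_s)
    return InputMap(excitatory_pC=exc, inhibitory_pC=inh, grid=grid)


def normalize_map(charges: np.ndarray) -> np.ndarray:
    """Site map divided by its field-of-view mean (result has mean 1)."""
    charges = np.asarray(charges, dtype=float)
    fov_mean = charges.mean()
    if fov_mean == 0:
        raise ValueError("field-of-view mean charge is zero; "
                         "normalization undefined")
    return charges / fov_mean


def layer_normalized_map(charges: np.ndarray, grid: UncagingGrid) -> dict:
    """Per-layer mean charge normalized to the field-of-view mean charge."""
    charges = np.asarray(charges, dtype=float)
    fov_mean = charges.mean()
    if fov_mean == 0:
        raise ValueError("field-of-view mean charge is zero; "
                         "normalization undefined")
    rows, _ = grid.grid_shape
    layer_vals = {name: [] for name in grid.layer_bounds_um}
    for r in range(rows):
        layer_vals[grid.layer_of_row(r)].extend(charges[r])
    return {name: (float(np.mean(v) / fov_mean) if v else np.nan)
            for name, v in layer_vals.items()}


def lateral_profile(charges: np.ndarray, grid: UncagingGrid,
                    layers=SUPERFICIAL_LAYERS, bin_width_um: float = 50.0):
    """Mean charge vs absolute lateral (x) distance from the recorded soma.

    Sites are restricted to the given layers (default L1-3); both sides of
    the soma are pooled by absolute distance. Empty bins are NaN (missing),
    not zero.

    Returns ``(bin_centers_um, mean_charge)``.
    """
    charges = np.asarray(charges, dtype=float)
    rows, cols = grid.grid_shape
    soma_x = grid.soma_xy_um[0]
    max_d = max(abs(grid.site_x_um(c) - soma_x) for c in range(cols))
    n_bins = int(np.floor(max_d / bin_width_um)) + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for r in range(rows):
        if grid.layer_of_row(r) not in layers:
            continue
        for c in range(cols):
            d = abs(grid.site_x_um(c) - soma_x)
            b = min(int(d // bin_width_um), n_bins - 1)
            sums[b] += charges[r, c]
            counts[b] += 1
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return centers, means


def ttx_subtract(map_pre: InputMap, map_post_ttx: InputMap,
                 superficial_only: bool = True,
                 layers=SUPERFICIAL_LAYERS) -> np.ndarray:
    """Synaptic-only excitatory map: max(pre - post_TTX, 0) per site.

    The post-TTX map contains only direct (AP-independent) photostimulation
    responses of the recorded cell; the floored difference is the synaptically
    evoked component. Only activity originating from the superficial layers
    is kept by default (deep-layer sites are NaN).
    """
    pre, post = map_pre.excitatory_pC, map_post_ttx.excitatory_pC
    if pre.shape != post.shape:
        raise ValueError(f"grid mismatch: {pre.shape} vs {post.shape}")
    syn = np.maximum(pre - post, 0.0)
    if superficial_only:
        grid = map_pre.grid
        if grid is None:
            raise ValueError("superficial restriction requires grid metadata")
        for r in range(pre.shape[0]):
            if grid.layer_of_row(r) not in layers:
                syn[r, :] = np.nan
    return syn


# ---------------------------------------------------------------------------
# Intrinsic membrane properties
# ---------------------------------------------------------------------------

def _steady_state(v, rec: StepRecording):
    fs = rec.sampling_hz
    on = int(round(rec.step_onset_s * fs))
    off = int(round((rec.step_onset_s + rec.step_duration_s) * fs))
    tail = max(1, int(round(0.1 * fs)))  # last 100 ms of the step
    baseline = v[:on].mean() if on > 0 else v[0]
    return v[off - tail:off].mean() - baseline


def _first_spike(v, dvdt_threshold, fs, spike_detect_mV=0.0):
    """(threshold index, peak index) of the first spike, or None.

    The spike peak (first local maximum reaching ``spike_detect_mV``) is
    located first; the threshold is the start of the contiguous run of
    samples with dV/dt >= criterion on that spike's rising phase. Anchoring
    on the peak keeps square-step onset edges from triggering the dV/dt
    criterion.
    """
    dvdt = np.gradient(v) * fs / 1000.0  # mV/ms
    candidates = np.flatnonzero(v >= spike_detect_mV)
    if candidates.size == 0:
        return None
    k = candidates[0]
    while k + 1 < v.size and v[k + 1] > v[k]:
        k += 1
    peak_idx = k
    thr_idx = peak_idx
    while thr_idx > 0 and dvdt[thr_idx - 1] >= dvdt_threshold:
        thr_idx -= 1
    if thr_idx == peak_idx:  # no rapid rise found before the peak
        return None
    return thr_idx, peak_idx


def intrinsic_properties(rec: StepRecording,
                         dvdt_threshold_mV_per_ms: float = 20.0,
                         spike_detect_mV: float = 0.0) -> IntrinsicProperties:
    """Five intrinsic properties from a hyper-/depolarizing step protocol.

    * membrane resistance: steady-state dV/dI on hyperpolarizing steps
      (which do not recruit voltage-gated conductances), in MOhm;
    * spike threshold: voltage at the first dV/dt crossing of
      ``dvdt_threshold_mV_per_ms`` on the first spike of the first
      suprathreshold sweep;
    * spike height: peak minus threshold;
    * half-width: width at half of the spike height, linear-interpolated;
    * AHP amplitude: threshold minus the post-repolarization minimum.

    With no spike in any sweep the spike fields are NaN but the resistance
    is still returned.
    """
    V = np.atleast_2d(np.asarray(rec.voltage_mV, dtype=float))
    I = np.asarray(rec.step_pA, dtype=float)
    fs = rec.sampling_hz

    hyper = I < 0
    if not np.any(hyper):
        raise ValueError("need >= 1 hyperpolarizing sweep for resistance")
    dv = np.array([_steady_state(V[i], rec) for i in np.flatnonzero(hyper)])
    di = I[hyper] * 1e-3  # pA -> nA; mV/nA = MOhm
    r_m = float(np.mean(dv / di))

    thr = height = hw = ahp = np.nan
    for i in np.flatnonzero(I > 0):
        found = _first_spike(V[i], dvdt_threshold_mV_per_ms, fs,
                             spike_detect_mV)
        if found is None:
            continue
        thr_idx, peak_idx = found
        thr = float(V[i][thr_idx])
        peak = float(V[i][peak_idx])
        height = peak - thr
        half = thr + height / 2.0
        v = V[i]
        # rising half-crossing
        up = thr_idx
        while up < peak_idx and v[up] < half:
            up += 1
        t_up = up - (v[up] - half) / (v[up] - v[up - 1]) if up > 0 else up
        # falling half-crossing
        dn = peak_idx
        while dn < v.size - 1 and v[dn] >= half:
            dn += 1
        t_dn = dn - (half - v[dn]) / (v[dn - 1] - v[dn]) if v[dn - 1] != v[dn] \
            else dn
        hw = float((t_dn - t_up) / fs * 1000.0)
        # AHP: minimum after repolarization back through threshold, within
        # the current step (the post-step return to rest is not an AHP)
        off = int(round((rec.step_onset_s + rec.step_duration_s) * fs))
        post = v[peak_idx:max(off, peak_idx + 1)]
        below = np.flatnonzero(post <= thr)
        if below.size:
            ahp = float(thr - post[below[0]:].min())
        else:
            ahp = float(thr - post.min())
        break
    return IntrinsicProperties(membrane_resistance_Mohm=r_m,
                               spike_threshold_mV=thr,
                               spike_height_mV=height,
                               spike_half_width_ms=hw,
                               ahp_amplitude_mV=ahp)
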