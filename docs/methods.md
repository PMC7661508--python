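# Methods

`barrelmap` re-implements, as reusable and tested code, the analysis chain of
a developmental study of barrel-cortex VIP+ and SST+ interneurons: in vivo
two-photon calcium imaging around the onset of active whisking (~P14),
stimulus decoding, VGlut2/tdTomato synaptic-puncta colocalization,
monosynaptic rabies-tracing distance statistics, and glutamate-uncaging
input mapping. Recorded data for such studies are rarely deposited, so every
analysis arm is paired with a synthetic generator that emulates the
statistical structure of the corresponding recording modality and returns
the planted ground truth. This note documents the models, the defaults and
their units, the numerical choices, and what the synthetic data do and do
not establish.

## Calcium arm

**Model.** Somatic fluorescence is treated as a baseline plus activity:
transients are decaying bi-exponentials
`f(t) = a·exp(b·t) + c·exp(d·t)` with amplitudes `a, c ≥ 0` (ΔF/F
fraction) and rates `b, d < 0` (1/s). The amplitude-weighted decay constant

    τ_w = (a·(−1/b) + c·(−1/d)) / (a + c)

summarises a fit with one number; it is a convex combination of the two
component time constants, which the test suite asserts on every fit.

**Registration.** Rigid per-frame translation is estimated on the anatomy
(red) channel by phase correlation against the temporal median image
(subpixel refinement via upsampled cross-correlation, default 20×, 100× in
the validation tests) and applied to both channels through Fourier shifts.
Constant (degenerate) frames get zero shift and a warning flag. Non-rigid
motion is out of scope.

**ΔF/F.** F₀ is the arithmetic mean of the lowest 5% of samples of each
cell's full trace — the mean (rather than the 5th percentile) is less
sensitive to single-sample noise. `F₀ ≤ 0` is an error naming the cell.

**Neuropil correction.** `F_corrected = F_neuron − α·F_neuropil`, applied on
raw fluorescence *before* ΔF/F so α stays a ratio of raw intensities; the
ordering is a documented package choice. The neuropil trace of a cell is the
mean over a disk (default radius 12 px) around its soma centroid excluding
every annotated mask — somata, astrocytes and blood vessels. α is estimated
once per imaging spot as `F_blood_vessel / F_surrounding_neuropil`: a
blood vessel carries no indicator, so its apparent fluorescence is pure
contamination and the ratio calibrates the contamination fraction.

**Evoked statistics.** Response magnitude is the trapezoidal integral of
baseline-corrected ΔF/F (in %·s) over the 8 s after stimulus onset,
baseline = mean ΔF/F of the 1 s before onset (window configurable); the
sample at exactly onset+8 s enters as the closing quadrature node so a
constant c% trace integrates to exactly 8·c. The reported per-stimulus value
averages the 10 trials. Pairwise evoked correlations are zero-lag Pearson
coefficients on single-trial 17.4 s windows, averaged across trials.
Spontaneous correlations average 1000 randomly placed (with replacement,
seeded) 17.4 s segments of a 300 s recording, making spontaneous and evoked
values comparable at equal window length; the per-spot summary is the mean
off-diagonal entry. Sample windows are half-open `[start, start+w)`,
frames 0-based.

**Event detection.** Manual event verification is replaced by explicit
criteria: a candidate peak (prominence ≥ `min_snr` × robust noise sd, where
the noise sd comes from the MAD of the first difference) is accepted iff the
preceding 1–2 s baseline has |slope| ≤ `max_baseline_slope`·noise-sd per
second and a single-exponential decay fit after the peak reaches R² ≥ 0.5.
An empty event list is a valid outcome.

**Bi-exponential fitting.** Bounded trust-region least squares
(`a, c ≥ 0`, `b, d ∈ [−100, 0)`), multi-start over decay-constant pairs from
{0.2, 1, 5} s with amplitudes initialised by non-negative linear solve;
the `(b, d)` ordering tie is broken by enforcing `b ≤ d` (fast component
first). If no start converges, a single-exponential fallback populates
`(a, b)` with `c = 0` and the fit is flagged `converged=False`. The decay
segment runs from the peak to 8 s after it (or trace end); segments shorter
than 10 samples are rejected.

## Decoding arm

One sample per (cell, paradigm): the trial-averaged ΔF/F trace over
baseline + response window, minus its pre-onset baseline mean; the feature
vector is the response-window portion (90 samples at 11.25 Hz and 8 s).
Three classifiers — random forest (50 trees, min leaf 5), Gaussian naive
Bayes, and an error-correcting-output-codes classifier realised as
one-vs-one linear SVMs (for a binary target this reduces to a single linear
learner; the base learner is configurable) — are each retrained 1000 times
on stratified 70/30 splits. Stratification (not in the original recipe,
which says only "randomly setting 70%") prevents empty-class training sets
at small n. `permute_labels=True` re-shuffles labels every repeat and gives
the chance-level permutation null; a single fixed shuffle would retain
finite-sample decodability and is not a calibrated null.

## Colocalization arm

Two-channel 3D stacks (VGlut2-like puncta; tdTomato-like dendrite channel)
are processed per channel: each xy slice is Wiener filtered (3×3, locally
estimated noise power) then bilateral filtered (σ_spatial = 1 px,
σ_range = 0.1 × dynamic range), with intensities handled as floats
normalized to [0, 1] and rescaled. Each slice of each orthogonal
orientation (xy, xz, yz) is binarized by multilevel Otsu (3 classes,
256-bin histograms; foreground = top class; constant slices contribute
all-false and are flagged); the three 3D masks are AND-combined — a
stringent conjunction that suppresses orientation-specific noise. The
channel masks are AND-ed again and 26-connected 3D components are counted
(6-connectivity configurable); components smaller than 2 voxels are
discarded as sub-resolution specks, standard practice in puncta counting. The
density normalizes the count by the tdTomato-positive voxel count, the voxel
analogue of normalizing appositions by labeled-dendrite area (the figure
phrasing; the Methods phrase "total tdTomato signal" is intensity-weighted —
the mask count was chosen and is documented here).

The generator plants Gaussian puncta (σ = (1.0, 1.3, 1.3) voxels,
amplitude 100, background noise sd = amplitude/SNR) separated by at least
three punctum diameters (diameter = FWHM). Punctum depths are stratified on
a shared grid spanning the full z-range, with colocalized pairs at interior
depths and single-channel puncta at the boundary depths of *both* channels:
every optical section of each channel then contains signal, as in densely
immunostained tissue. This matters because slice-adaptive Otsu thresholds
invent foreground in empty sections — a failure mode absent from real
dense stainings and therefore deliberately absent from the emulation.

## Tracing arm

Starter-to-presynaptic connectivity reach is summarised probabilistically
(pairings are unobservable): 2D Euclidean distances from every starter to
every presynaptic cell, cut at 800 µm (inclusive); per-starter empirical
CDFs on a 1 µm grid over [0, 800]; the group profile is the unweighted mean
CDF over starters (starters with no in-radius partner are excluded and
counted). The 800 µm cut is applied before per-starter normalization, so
each CDF is over that starter's in-radius partners. Group comparison is a
two-sample KS test on pooled distances; because pooled distances share
presynaptic cells across starters, a starter-level alternative
(`method="average_cdf"`: sup-difference of average CDFs with a permutation
p-value) is provided for dependence-respecting inference. The decremental
control re-draws, for k = S…1 starters and round(k·ratio)
presynaptic cells (round-half-away-from-zero; draws capped at availability
with a warning), ten seeded iterations per k, and recomputes the profile.

The generator mixes a local component (2D Gaussian, sd 80 µm, around a
random starter) with a dispersed component (area-uniform annulus, inner
radius half the outer 600 µm, `r ∝ √u` to avoid center bias); the dispersed
fraction shifts the distance CDF rightward, giving a controllable contrast
for power checks. Statistical-calibration checks (KS power, type-I error)
use single-starter fields so that pooled distances are iid and the nominal
test level applies.

## Uncaging / ephys arm

A 20×20 photostimulation grid spans the slice; each site holds ≥3
voltage-clamp sweeps (pA, 10 kHz) with ≥500 ms of pre-illumination
baseline. The analysis window comes from calibration: first evoked AP peak
to last peak + 10 ms (margin configurable and reported), chosen to capture
monosynaptic and exclude polysynaptic input. Per sweep, the baseline (mean
of the 500 ms before illumination) is subtracted; within the window,
rectified negative deviations integrate (left-Riemann, 1 pA·s = 1 pC) to
excitatory charge and positive deviations to inhibitory charge — at
−45 mV holding both are visible. Sweeps are integrated first and averaged
after (order matters only when deviations change sign within a sweep).
Layer normalization divides each layer's mean charge by the field-of-view
mean; the site-level normalized map has mean exactly 1. Lateral profiles
restrict to L1–3, pool both sides by absolute horizontal distance from the
recorded soma, and bin at 50 µm; empty bins are missing (NaN), not zero.
Sites exactly on a layer boundary belong to the upper layer. The −70 mV /
TTX protocol subtracts the direct (TTX-resistant) map from the pre-TTX map,
floors at 0 (negative synaptic charge is non-physical, noise-driven), and
keeps superficial-layer origins only.

Intrinsic properties from 500 ms, Δ+20 pA current-clamp steps: membrane
resistance = steady-state ΔV/ΔI on hyperpolarizing steps (last 100 ms of
the step; MΩ = mV/nA); spike threshold = first sample of the contiguous
dV/dt ≥ 20 mV/ms run on the rising phase of the first spike (the
peak-anchored backward search avoids square-step onset edges triggering the
dV/dt criterion); height = peak − threshold; half-width at half height with
linear interpolation; AHP = threshold − post-repolarization minimum within
the step. Without a spike the spike fields are NaN and the resistance is
still returned. The step-protocol generator plants a symmetric triangular
spike (base = 2 × half-width, so the width at half height equals the
planted value) and an ohmic subthreshold response, with a rheobase below
which no spike is planted.

## Synthetic population movies

Spiking is a superposition of global network events (Poisson, default
0.1 Hz; each cell participates with probability `participation_prob`),
per-cell private events (Poisson, 0.05 Hz) and optional evoked onsets with
paradigm-dependent gain (multi-whisker default 1.6× single). Traces are the
linear convolution of the frame-binned event train with the bi-exponential
kernel — no saturation, since the AP-calibration relation is analyzed, not
modeled. Rendering: somatic pixels carry `baseline·(1 + ΔF/F)` plus
α·neuropil; background pixels carry the shared neuropil signal (baseline
40, following half the population-mean activity); a blood-vessel stripe
carries α·neuropil only, so the α-defining ratio is exactly recoverable at
zero noise. Channel 2 is static anatomy. Drift is rigid per-frame
translation (bilinear interpolation); noise is Gaussian (no Poisson photon
statistics — adequate for testing estimators, not for photon-budget
studies). Default kernel (0.6, −2.0, 0.4, −0.5) gives τ_w ≈ 1.1 s, in the
range of somatic OGB-1 transients; evoked-transient amplitudes are free
parameters of the generator, not calibrated to any recording.

**What passing tests show — and don't.** The synthetic movies validate the
estimators' correctness (exact recovery at zero noise, graceful degradation
with noise, calibrated statistics under the generator's assumptions). They
do not establish performance on real tissue: no optical PSF, no Poisson
noise, no non-rigid motion, no overlapping somata, no indicator saturation,
and point fields without barrel micro-structure.

## Pipeline and reproducibility

A single global seed fans out to per-stage child seeds through
`SeedSequence([seed, stage_counter])` with fixed counters, so stages are
independently reproducible. Bundles contain per-stage CSV/JSON, the
resolved config (YAML) and a manifest (config SHA-256, seed, package
version) and are byte-identical for identical config + seed (no timestamps
are written). Stage parameter defaults mirror the study's stated analysis
values (11.25 Hz, 8 s integral, 17.4 s windows, 1000 segments, 1000 decoder
repeats at 70% training, 800 µm radius, 10 subsampling iterations, 20×20
grids at 10 kHz). The bundled demo configuration runs the same analyses at
desk scale (1200-frame movie, 6 cells, 300 segments, 100 decoder repeats,
10×10 grid), sizes chosen so the full bundle completes in seconds;
`scripts/acceptance.py` likewise states its problem sizes explicitly
(100 transients, 20-seed sweeps, 1000 decoder repeats, 100 power / 400 null
KS draws).

## Known limitations

- The concatenated demo movie holds spontaneous and evoked epochs in one
  recording; the study acquired them as separate files. Analysis windows are
  placed so epochs do not overlap, but edge effects of concatenation are the
  user's responsibility with real data.
- The KS test on pooled distances is anti-conservative when multiple
  starters share presynaptic partners; use `method="average_cdf"` for
  dependence-respecting inference.
- The Wiener/bilateral parameters are defaults, not optimized per dataset;
  heavily textured backgrounds may need larger windows.
- Proprietary acquisition formats (ABF, raw scanner files) are out of
  scope; inputs are TIFF/HDF5/CSV with JSON sidecars.
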