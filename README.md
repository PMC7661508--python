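# barrelmap

Analysis tools for developmental interneuron-circuit experiments in the
whisker barrel cortex. The package reimplements, as tested and reusable
code, the bespoke analysis chain used to characterise VIP+ and SST+
interneurons around the onset of active whisking: two-photon calcium-trace
quantification, stimulus-paradigm decoding, 3D synaptic-puncta
colocalization, monosynaptic rabies-tracing distance statistics and
photostimulation (glutamate-uncaging) input maps. Because raw recordings
for such studies are typically available only on request, every analysis
arm ships with a synthetic generator that emulates the corresponding
recording modality with known ground truth, so the whole chain is testable
end to end.

## Who is this for

Systems-neuroscience labs analysing:

- bulk-loaded two-photon calcium movies (ΔF/F with a bottom-5% baseline,
  neuropil correction `F − α·F_neuropil` with
  `α = F_blood_vessel / F_neuropil`, evoked 8-s response integrals,
  17.4-s-window evoked/spontaneous Pearson correlations, event detection,
  bi-exponential transient fits with the amplitude-weighted decay constant
  `τ_w = (a·(−1/b) + c·(−1/d))/(a + c)` for `f(t) = a·e^{bt} + c·e^{dt}`);
- stimulus decoding with resampled classifiers (random forest, naive
  Bayes, ECOC; 1000 stratified 70/30 splits);
- two-channel confocal stacks (Wiener + bilateral denoising, per-slice
  multilevel Otsu along all three orientations AND-combined, 3D
  connected-component counting normalized by tdTomato-positive voxels);
- starter/presynaptic coordinate tables (per-starter distance CDFs within
  800 µm, two-sample Kolmogorov–Smirnov comparison, decremental randomized
  subsampling);
- gridded voltage-clamp photostimulation sweeps (excitatory/inhibitory
  charge split at −45 mV, per-layer normalization, lateral profiles, TTX
  subtraction) and current-clamp step protocols (membrane resistance,
  spike threshold/height/half-width, AHP).

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
import numpy as np
from barrelmap import synth, calcium, coloc, tracing

# 1. fit a noisy bi-exponential calcium transient and report tau_w
seg = synth.simulate_transient((0.5, -1.0, 0.5, -0.25), 12.0, 11.25,
                               noise_sd=0.05, seed=0)
fit = calcium.fit_biexponential(seg, 11.25)
print(f"tau_w = {fit.tau_w:.3f} s (converged={fit.converged})")

# 2. count colocalized puncta through the full denoise/binarize/AND chain
stack, truth = synth.simulate_puncta_stack(n_coloc=7, snr=10, seed=0)
res = coloc.colocalize(stack)
print(f"colocalized puncta: {res.n_components} "
      f"(planted {truth['overlap_count']}), "
      f"density = {res.density:.2e} per tdTomato voxel")

# 3. compare distance profiles of a compact vs a dispersed input field
a = synth.simulate_tracing_points(n_presyn=500, dispersed_fraction=0.1, seed=0)
b = synth.simulate_tracing_points(n_presyn=500, dispersed_fraction=0.6, seed=1)
pa = tracing.cumulative_profile(tracing.pairwise_distances(a))
pb = tracing.cumulative_profile(tracing.pairwise_distances(b))
ks = tracing.compare_profiles(pa, pb)
print(f"KS D = {ks.statistic:.3f}, p = {ks.pvalue:.3g}")
```

prints

```
tau_w = 2.454 s (converged=True)
colocalized puncta: 7 (planted 7), density = 4.27e-02 per tdTomato voxel
KS D = 0.446, p = 9.91e-224
```

The fitted `τ_w` is within 2% of the planted 2.5 s despite 5% noise; the
colocalization chain recovers exactly the 7 planted punctum pairs; and the
KS test resolves the compact from the dispersed presynaptic field — the more
dispersed field's distance CDF sits to the right, the same contrast used to
compare input reach between interneuron types.

## Command line

The pipeline runs end to end on synthetic inputs and writes a reproducible
report bundle (per-stage CSV/JSON, resolved config, manifest):

```sh
barrelmap all --demo --seed 1 --out out/demo      # every stage, desk scale
barrelmap tracing --seed 3 --out out/tracing      # one stage
barrelmap simulate --seed 1 --out out/inputs      # write synthetic inputs
```

Identical config + seed gives a byte-identical bundle. A YAML config
(`--config`) overrides any defaults; unknown keys are rejected.

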