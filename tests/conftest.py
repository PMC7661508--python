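import numpy as np
import pytest

from barrelmap import calcium, synth


@pytest.fixture(scope="session")
def small_population():
    """Drift-free, noise-free rendered movie with ground truth."""
    cfg = synth.SimConfig(seed=11, movie_shape=(600, 48, 48), n_cells=5,
                          noise_sd=0.0)
    movie, truth = synth.simulate_population(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def recovered_dff(small_population):
    """Full register -> extract -> neuropil-correct -> dF/F chain output."""
    _, movie, truth = small_population
    rois = calcium.RoiSet(
        truth.roi_masks + [truth.blood_vessel_mask],
        ["interneuron"] * len(truth.roi_masks) + ["blood_vessel"])
    raw = calcium.extract_roi_traces(movie, rois)
    npil = calcium.extract_roi_traces(movie, None,
                                      masks=rois.neuropil_masks())
    vessel = calcium.extract_roi_traces(movie, None,
                                        masks=[truth.blood_vessel_mask])
    params = calcium.estimate_alpha(vessel.values[0],
                                    npil.values.mean(axis=0))
    corrected = calcium.neuropil_correct(raw, npil, params)
    return calcium.delta_f_over_f(corrected), params, truth


def pearson(x, y):
    return float(np.corrcoef(x, y)[0, 1])
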