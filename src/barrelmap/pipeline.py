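"""End-to-end pipeline: configuration, stage orchestration, report bundle.

Every stage runs on freshly simulated inputs with known ground truth and
writes CSV/JSON outputs plus a run manifest (config hash, seed, package
version). A single global seed fans out to per-stage child seeds through a
fixed counter scheme, so stages are independently reproducible and an
identical config + seed yields a byte-identical bundle (no timestamps are
written).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import calcium, coloc, decode, ephys, synth, tracing
from .io import save_config

__all__ = ["PipelineConfig", "default_config", "demo_config", "run_pipeline"]

PACKAGE_VERSION = "0.1.0"

# Stage parameter defaults mirror the study's stated analysis values:
# 11.25 Hz movies, 8 s evoked integrals, 17.4 s correlation windows, 1000
# spontaneous segments from 300 s, 1000 decoder repeats with 70% training
# and a 50-tree / min-leaf-5 forest, 800 um tracing radius with 10
# subsampling iterations, 20x20 uncaging grids at 10 kHz with 500 ms
# baselines.
DEFAULTS = {
    "seed": 0,
    "stages": ["calcium", "decode", "coloc", "tracing", "ephys"],
    "dump_intermediates": False,
    "calcium": {
        "frame_rate_hz": 11.25,
        # 300 s of spontaneous activity followed by 10 + 10 evoked trials
        "movie_shape": [7650, 48, 48],
        "n_cells": 8,
        "participation_prob": 0.5,
        "private_event_rate_hz": 0.05,
        "noise_sd": 0.02,
        "n_trials_per_paradigm": 10,
        "evoked_window_s": 8.0,
        "baseline_window_s": 1.0,
        "corr_window_s": 17.4,
        "n_segments": 1000,
        "neuropil_radius_px": 12.0,
        "min_snr": 3.0,
    },
    "decode": {
        "n_repeats": 1000,
        "train_fraction": 0.7,
        "response_window_s": 8.0,
        "baseline_window_s": 1.0,
    },
    "coloc": {
        "shape_zyx": [16, 64, 64],
        "n_coloc": 7,
        "n_ch1_only": 5,
        "n_ch2_only": 5,
        "snr": 10.0,
        "n_classes": 3,
        "connectivity": 26,
    },
    "tracing": {
        "n_starters": 5,
        "n_presyn": 500,
        "dispersed_fraction_a": 0.1,
        "dispersed_fraction_b": 0.6,
        "radius_um": 800.0,
        "n_iterations": 10,
    },
    "ephys": {
        "grid_shape": [20, 20],
        "noise_sd_pA": 1.0,
        "margin_ms": 10.0,
        "bin_width_um": 50.0,
    },
}

# fixed fan-out counters: stage name -> child index
_STAGE_COUNTERS = {"calcium": 1, "decode": 2, "coloc": 3, "tracing": 4,
                   "ephys": 5}


class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    def __init__(self, overrides: dict = None):
        cfg = copy.deepcopy(DEFAULTS)
        if overrides:
            self._merge(cfg, overrides, path="")
        self.config = cfg

    @staticmethod
    def _merge(base, overrides, path):
        for key, val in overrides.items():
            where = f"{path}.{key}" if path else key
            if key not in base:
                raise ValueError(f"unknown config key {where!r}")
            if isinstance(base[key], dict):
                if not isinstance(val, dict):
                    raise ValueError(f"{where} must be a mapping")
                PipelineConfig._merge(base[key], val, where)
            else:
                base[key] = val

    def __getitem__(self, key):
        return self.config[key]

    def child_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([int(self.config["seed"]),
                                     _STAGE_COUNTERS[stage]])
        return int(ss.generate_state(1)[0] % (2**31))

    def hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig({"seed": seed})


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale demo: smaller movie and fewer decoder repeats, same
    analysis parameters otherwise."""
    return PipelineConfig({
        "seed": seed,
        "calcium": {"movie_shape": [1200, 48, 48], "n_cells": 6,
                    "n_trials_per_paradigm": 2, "n_segments": 300},
        "decode": {"n_repeats": 100},
        "coloc": {"shape_zyx": [12, 48, 48], "n_ch1_only": 3,
                  "n_ch2_only": 3},
        "tracing": {"n_starters": 4, "n_presyn": 300},
        "ephys": {"grid_shape": [10, 10]},
    })


def _json_dump(path, payload):
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1,
                                     default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _nan_to_none(x):
    return None if (isinstance(x, float) and np.isnan(x)) else x


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_calcium(cfg: PipelineConfig, outdir: Path):
    p = cfg["calcium"]
    seed = cfg.child_seed("calcium")
    T = p["movie_shape"][0]
    fr = p["frame_rate_hz"]
    n_trials = p["n_trials_per_paradigm"]
    # interleave single/multi trials late in the movie, each needing the
    # 17.4 s correlation window after onset
    span = int(np.ceil(p["corr_window_s"] * fr)) + 15
    first = T - 2 * n_trials * span - 10
    if first < int(np.ceil(p["corr_window_s"] * fr)):
        raise ValueError(
            f"movie of {T} frames too short for {2 * n_trials} evoked "
            "trials plus a spontaneous span; enlarge movie_shape or reduce "
            "n_trials_per_paradigm")
    onsets, paradigms = [], []
    for k in range(2 * n_trials):
        onsets.append(first + k * span)
        paradigms.append("single" if k % 2 == 0 else "multi")
    sim = synth.SimConfig(
        seed=seed, frame_rate_hz=fr, movie_shape=tuple(p["movie_shape"]),
        n_cells=p["n_cells"], participation_prob=p["participation_prob"],
        private_event_rate_hz=p["private_event_rate_hz"],
        noise_sd=p["noise_sd"], evoked_onset_frames=tuple(onsets),
        evoked_paradigms=tuple(paradigms))
    movie, truth = synth.simulate_population(sim)

    registered, shifts, _ = calcium.register_frames(movie)
    rois = calcium.RoiSet(truth.roi_masks + [truth.blood_vessel_mask],
                          ["interneuron"] * len(truth.roi_masks)
                          + ["blood_vessel"])
    raw = calcium.extract_roi_traces(registered, rois)
    npil_masks = rois.neuropil_masks(radius_px=p["neuropil_radius_px"])
    npil = calcium.extract_roi_traces(registered, None, masks=npil_masks)
    vessel_trace = calcium.extract_roi_traces(
        registered, None, masks=[truth.blood_vessel_mask])
    params = calcium.estimate_alpha(vessel_trace.values[0],
                                    npil.values.mean(axis=0))
    corrected = calcium.neuropil_correct(raw, npil, params)
    dff = calcium.delta_f_over_f(corrected)

    by_paradigm = {"single": [o for o, q in zip(onsets, paradigms)
                              if q == "single"],
                   "multi": [o for o, q in zip(onsets, paradigms)
                             if q == "multi"]}
    integrals = {}
    for paradigm, ons in by_paradigm.items():
        _, mean_int = calcium.evoked_integrals(
            dff, ons, window_s=p["evoked_window_s"],
            baseline_s=p["baseline_window_s"])
        integrals[paradigm] = mean_int
    _, evoked_avg = calcium.evoked_correlation(
        dff, by_paradigm["multi"], window_s=p["corr_window_s"])
    spont_T = first - 5  # frames before the first stimulus
    spont = calcium.TraceMatrix(dff.values[:, :spont_T], frame_rate_hz=fr,
                                kind="dff")
    _, spot_mean = calcium.spontaneous_correlation(
        spont, n_segments=p["n_segments"], segment_s=p["corr_window_s"],
        seed=seed)

    taus = []
    n_events = []
    for i in range(dff.n_cells):
        ev = calcium.detect_events(dff.values[i, :spont_T], fr,
                                   min_snr=p["min_snr"])
        n_events.append(len(ev))
        if len(ev):
            pk = ev.peak_frames[0]
            seg = dff.values[i, pk:pk + int(8 * fr)]
            if seg.size >= 10:
                taus.append(calcium.fit_biexponential(seg, fr).tau_w)
                continue
        taus.append(np.nan)

    df = pd.DataFrame({
        "cell": list(range(dff.n_cells)),
        "alpha": params.alpha,
        "evoked_integral_single_pct_s": integrals["single"],
        "evoked_integral_multi_pct_s": integrals["multi"],
        "n_events": n_events,
        "tau_w_s": taus,
    })
    df.to_csv(outdir / "calcium_cells.csv", index=False, float_format="%.10g")
    if cfg["dump_intermediates"]:
        pd.DataFrame(dff.values.T).to_csv(outdir / "calcium_dff_traces.csv",
                                          index=False, float_format="%.10g")
    off = ~np.eye(dff.n_cells, dtype=bool)
    summary = {
        "alpha": params.alpha,
        "alpha_true": truth.alpha_true,
        "spot_mean_spontaneous_correlation": _nan_to_none(spot_mean),
        "mean_evoked_correlation": _nan_to_none(
            float(np.nanmean(evoked_avg[off]))),
        "max_registration_shift_px": float(np.abs(shifts).max()),
        "n_cells": dff.n_cells,
    }
    _json_dump(outdir / "calcium_summary.json", summary)
    return {"dff": dff, "onsets_by_paradigm": by_paradigm,
            "summary": summary}


def _stage_decode(cfg: PipelineConfig, outdir: Path, calcium_out):
    p = cfg["decode"]
    seed = cfg.child_seed("decode")
    table = decode.build_feature_matrix(
        calcium_out["dff"], calcium_out["onsets_by_paradigm"],
        response_window_s=p["response_window_s"],
        baseline_window_s=p["baseline_window_s"])
    result = decode.evaluate_decoders(table, n_repeats=p["n_repeats"],
                                      train_fraction=p["train_fraction"],
                                      seed=seed)
    payload = {name: {"accuracies": acc.tolist(),
                      "mean": result.mean[name],
                      "ci95": list(result.ci95[name])}
               for name, acc in result.accuracies.items()}
    _json_dump(outdir / "decode_result.json", payload)
    if cfg["dump_intermediates"]:
        from .io import save_feature_table
        save_feature_table(outdir / "decode_features.csv", table)
    return {"result": result}


def _stage_coloc(cfg: PipelineConfig, outdir: Path):
    p = cfg["coloc"]
    seed = cfg.child_seed("coloc")
    stack, truth = synth.simulate_puncta_stack(
        shape_zyx=tuple(p["shape_zyx"]), n_coloc=p["n_coloc"],
        n_ch1_only=p["n_ch1_only"], n_ch2_only=p["n_ch2_only"],
        snr=p["snr"], seed=seed)
    result = coloc.colocalize(stack, n_classes=p["n_classes"],
                              connectivity=p["connectivity"])
    payload = {
        "n_components": result.n_components,
        "planted_coloc": truth["overlap_count"],
        "tdtomato_positive_voxels": result.tdtomato_positive_voxels,
        "density_per_td_voxel": _nan_to_none(result.density),
    }
    _json_dump(outdir / "coloc_result.json", payload)
    if cfg["dump_intermediates"]:
        import tifffile
        for name, mask in (("ch1", result.mask_ch1),
                           ("ch2", result.mask_ch2),
                           ("conjunction", result.conjunction_mask)):
            tifffile.imwrite(outdir / f"coloc_mask_{name}.tif",
                             mask.astype(np.uint8))
    return {"result": result, "truth": truth}


def _stage_tracing(cfg: PipelineConfig, outdir: Path):
    p = cfg["tracing"]
    seed = cfg.child_seed("tracing")
    sets = {}
    for tag, frac, s_off in (("A", p["dispersed_fraction_a"], 0),
                             ("B", p["dispersed_fraction_b"], 1)):
        sets[tag] = synth.simulate_tracing_points(
            n_starters=p["n_starters"], n_presyn=p["n_presyn"],
            dispersed_fraction=frac, seed=seed + s_off)
    profiles = {}
    rows = []
    for tag, pts in sets.items():
        dists = tracing.pairwise_distances(pts, radius_um=p["radius_um"])
        prof = tracing.cumulative_profile(dists, radius_um=p["radius_um"])
        profiles[tag] = prof
        rows.append(pd.DataFrame({
            "group": tag, "distance_um": prof.grid_um,
            "average_cdf": prof.average_cdf}))
    pd.concat(rows).to_csv(outdir / "tracing_profiles.csv", index=False,
                           float_format="%.10g")
    ks = tracing.compare_profiles(profiles["A"], profiles["B"])
    sub = tracing.randomized_subsampling(sets["A"],
                                         n_iterations=p["n_iterations"],
                                         radius_um=p["radius_um"], seed=seed)
    summary = {
        "ks_statistic": ks.statistic,
        "ks_pvalue": ks.pvalue,
        "n_subsampling_profiles": len(sub),
        "mean_distance_A_um": float(np.mean(profiles["A"].pooled())),
        "mean_distance_B_um": float(np.mean(profiles["B"].pooled())),
    }
    _json_dump(outdir / "tracing_summary.json", summary)
    return {"summary": summary, "profiles": profiles}


def _stage_ephys(cfg: PipelineConfig, outdir: Path):
    p = cfg["ephys"]
    seed = cfg.child_seed("ephys")
    rows, cols = p["grid_shape"]
    planted = [
        {"site": (1, cols // 2), "amplitude_pA": -60.0, "onset_ms": 620.0,
         "dur_ms": 80.0, "shape": "alpha"},
        {"site": (rows // 3, cols // 4), "amplitude_pA": -40.0,
         "onset_ms": 640.0, "dur_ms": 60.0, "shape": "square"},
        {"site": (1, cols // 4), "amplitude_pA": 30.0, "onset_ms": 630.0,
         "dur_ms": 60.0, "shape": "square"},
    ]
    fov_um = rows * 50.0
    bounds = {"L1": (0.0, 0.1 * fov_um), "L2/3": (0.1 * fov_um, 0.35 * fov_um),
              "L4": (0.35 * fov_um, 0.55 * fov_um),
              "L5/6": (0.55 * fov_um, fov_um)}
    grid = synth.simulate_uncaging_grid(
        grid_shape=(rows, cols), planted_inputs=planted,
        noise_sd_pA=p["noise_sd_pA"], layer_bounds_um=bounds,
        soma_xy_um=(cols * 25.0, 0.2 * fov_um), seed=seed)
    window = ephys.calibration_window([0.61, 0.64, 0.67, 0.70],
                                      margin_ms=p["margin_ms"])
    maps = ephys.grid_charge_maps(grid, window)
    layer_norm = ephys.layer_normalized_map(maps.excitatory_pC, grid)
    centers, lateral = ephys.lateral_profile(maps.excitatory_pC, grid,
                                             bin_width_um=p["bin_width_um"])

    # -70 mV / TTX protocol: direct-only map post-TTX
    direct = [{"site": (2, 2), "amplitude_pA": -30.0, "onset_ms": 620.0,
               "dur_ms": 50.0, "shape": "square"}]
    pre_grid = synth.simulate_uncaging_grid(
        grid_shape=(rows, cols), planted_inputs=direct + [
            {"site": (1, 1), "amplitude_pA": -50.0, "onset_ms": 625.0,
             "dur_ms": 50.0, "shape": "square"}],
        layer_bounds_um=bounds, holding_mv=-70.0, seed=seed + 1)
    post_grid = synth.simulate_uncaging_grid(
        grid_shape=(rows, cols), planted_inputs=direct,
        layer_bounds_um=bounds, holding_mv=-70.0, seed=seed + 2)
    pre_map = ephys.grid_charge_maps(pre_grid, window)
    post_map = ephys.grid_charge_maps(post_grid, window)
    synaptic = ephys.ttx_subtract(pre_map, post_map)

    rec = synth.simulate_step_recording(seed=seed)
    props = ephys.intrinsic_properties(rec)

    pd.DataFrame(maps.excitatory_pC).to_csv(
        outdir / "ephys_excitatory_map_pC.csv", index=False,
        float_format="%.10g")
    summary = {
        "layer_normalized_excitation": {k: _nan_to_none(v)
                                        for k, v in layer_norm.items()},
        "lateral_bin_centers_um": centers.tolist(),
        "lateral_mean_charge_pC": [_nan_to_none(float(v)) for v in lateral],
        "ttx_synaptic_total_pC": float(np.nansum(synaptic)),
        "intrinsic": {
            "membrane_resistance_Mohm": props.membrane_resistance_Mohm,
            "spike_threshold_mV": _nan_to_none(props.spike_threshold_mV),
            "spike_height_mV": _nan_to_none(props.spike_height_mV),
            "spike_half_width_ms": _nan_to_none(props.spike_half_width_ms),
            "ahp_amplitude_mV": _nan_to_none(props.ahp_amplitude_mV),
        },
    }
    _json_dump(outdir / "ephys_summary.json", summary)
    return {"summary": summary, "synaptic_map": synaptic}


_STAGE_FUNCS = {"calcium": _stage_calcium, "decode": _stage_decode,
                "coloc": _stage_coloc, "tracing": _stage_tracing,
                "ephys": _stage_ephys}


def run_pipeline(config: PipelineConfig, outdir, strict: bool = True):
    """Execute the selected stages and write the report bundle.

    Returns a dict of per-stage results; on stage failure with
    ``strict=False`` a partial bundle with an error record is written and
    the error is recorded under the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for stage in config["stages"]:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
    save_config(outdir / "resolved_config.yaml", config.config)
    results, errors = {}, {}
    for stage in config["stages"]:
        try:
            if stage == "decode":
                if "calcium" not in results:
                    results["calcium"] = _stage_calcium(config, outdir)
                results[stage] = _stage_decode(config, outdir,
                                               results["calcium"])
            else:
                results[stage] = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # noqa: BLE001 - reported in the bundle
            if strict:
                raise
            errors[stage] = f"{type(exc).__name__}: {exc}"
    manifest = {
        "config_sha256": config.hash(),
        "seed": int(config["seed"]),
        "stages_run": sorted(results),
        "errors": errors,
        "package_version": PACKAGE_VERSION,
    }
    _json_dump(outdir / "manifest.json", manifest)
    if errors and not strict:
        results["_errors"] = errors
    return results
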