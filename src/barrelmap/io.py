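"""File round-tripping for movies, stacks, point tables, grids and configs.

Movies and puncta stacks travel as multi-page TIFF with a JSON sidecar
(frame rate / voxel size / stimulus log); point sets as CSV; uncaging grids
as HDF5; configurations as YAML. Round trips are lossless for integer data
and exact for float32 payloads.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .calcium import FluorescenceMovie
from .coloc import PunctaStack
from .ephys import UncagingGrid
from .tracing import TracingPointSet

__all__ = [
    "save_movie", "load_movie",
    "save_stack", "load_stack",
    "save_points", "load_points",
    "save_grid", "load_grid",
    "save_roi_masks", "load_roi_masks",
    "save_feature_table", "load_feature_table",
    "load_config", "save_config",
    "load_inputs",
]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".json")


# ---------------------------------------------------------------------------
# Movies (TCYX ImageJ TIFF)
# ---------------------------------------------------------------------------

def save_movie(path, movie: FluorescenceMovie):
    data = np.stack([movie.green, movie.red], axis=1).astype(np.float32)
    tifffile.imwrite(path, data, imagej=True, metadata={"axes": "TCYX"})
    meta = {"frame_rate_hz": movie.frame_rate_hz,
            "stimulus_log": movie.stimulus_log,
            "spot_id": movie.spot_id}
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def load_movie(path) -> FluorescenceMovie:
    data = tifffile.imread(path)
    if data.ndim != 4 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected TCYX two-channel movie, "
                         f"got shape {data.shape}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"{path}: missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("frame_rate_hz",):
        if key not in meta:
            raise KeyError(f"{sidecar}: missing field {key!r}")
    return FluorescenceMovie(green=data[:, 0], red=data[:, 1],
                             frame_rate_hz=meta["frame_rate_hz"],
                             stimulus_log=meta.get("stimulus_log", []),
                             spot_id=meta.get("spot_id", "spot0"))


# ---------------------------------------------------------------------------
# Puncta stacks (CZYX TIFF)
# ---------------------------------------------------------------------------

def save_stack(path, stack: PunctaStack):
    data = np.stack([stack.channel1, stack.channel2]).astype(np.float32)
    tifffile.imwrite(path, data, metadata={"axes": "CZYX"})
    meta = {"voxel_size_um": list(stack.voxel_size_um)}
    _sidecar(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def load_stack(path) -> PunctaStack:
    data = tifffile.imread(path)
    if data.ndim != 4 or data.shape[0] != 2:
        raise ValueError(f"{path}: expected CZYX two-channel stack, "
                         f"got shape {data.shape}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"{path}: missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "voxel_size_um" not in meta:
        raise KeyError(f"{sidecar}: missing field 'voxel_size_um'")
    return PunctaStack(channel1=data[0], channel2=data[1],
                       voxel_size_um=tuple(meta["voxel_size_um"]))


# ---------------------------------------------------------------------------
# ROI masks (label-image TIFF: 0 = background, k = ROI k-1)
# ---------------------------------------------------------------------------

def save_roi_masks(path, masks):
    label = np.zeros(np.asarray(masks[0]).shape, dtype=np.uint16)
    for k, m in enumerate(masks, start=1):
        label[np.asarray(m, dtype=bool)] = k
    tifffile.imwrite(path, label)


def load_roi_masks(path):
    label = tifffile.imread(path)
    if label.ndim != 2:
        raise ValueError(f"{path}: expected a 2D label image, "
                         f"got shape {label.shape}")
    n = int(label.max())
    return [label == k for k in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Decoder feature tables (CSV, one row per sample with a label column)
# ---------------------------------------------------------------------------

def save_feature_table(path, table):
    df = pd.DataFrame(table.samples,
                      columns=[f"f{i}" for i in range(
                          table.samples.shape[1])])
    df.insert(0, "label", table.labels)
    if table.cell_ids is not None:
        df.insert(1, "cell", table.cell_ids)
    df.to_csv(path, index=False)


def load_feature_table(path):
    from .decode import FeatureTable

    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing 'label' column")
    feature_cols = [c for c in df.columns if c.startswith("f")]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns (f0, f1, ...)")
    cells = df["cell"].to_numpy() if "cell" in df.columns else None
    return FeatureTable(samples=df[feature_cols].to_numpy(dtype=float),
                        labels=df["label"].to_numpy(),
                        cell_ids=cells)


# ---------------------------------------------------------------------------
# Tracing point tables (CSV)
# ---------------------------------------------------------------------------

POINT_COLUMNS = ["role", "x_um", "y_um", "brain", "cell_type"]


def save_points(path, points: TracingPointSet):
    rows = []
    for role, arr in (("starter", points.starters),
                      ("presynaptic", points.presynaptic)):
        for x, y in arr:
            rows.append({"role": role, "x_um": x, "y_um": y,
                         "brain": points.brain,
                         "cell_type": points.cell_type})
    pd.DataFrame(rows, columns=POINT_COLUMNS).to_csv(path, index=False)


def load_points(path) -> TracingPointSet:
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_role = ~df["role"].isin(["starter", "presynaptic"])
    if bad_role.any():
        row = int(df.index[bad_role][0])
        raise ValueError(f"{path}: row {row} has invalid role "
                         f"{df['role'].iloc[row]!r}")
    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise ValueError(f"{path}: row {row} has malformed {col}")
        df[col] = vals
    starters = df.loc[df.role == "starter", ["x_um", "y_um"]].to_numpy()
    presyn = df.loc[df.role == "presynaptic", ["x_um", "y_um"]].to_numpy()
    brain = str(df["brain"].iloc[0]) if "brain" in df else "brain0"
    cell_type = str(df["cell_type"].iloc[0]) if "cell_type" in df else "unknown"
    return TracingPointSet(starters=starters, presynaptic=presyn,
                           brain=brain, cell_type=cell_type)


# ---------------------------------------------------------------------------
# Uncaging grids (HDF5)
# ---------------------------------------------------------------------------

def save_grid(path, grid: UncagingGrid):
    with h5py.File(path, "w") as f:
        f.create_dataset("sweeps_pA", data=grid.sweeps.astype(np.float32))
        f.attrs["sampling_hz"] = grid.sampling_hz
        f.attrs["illumination_onset_s"] = grid.illumination_onset_s
        f.attrs["site_spacing_um"] = grid.site_spacing_um
        f.attrs["soma_xy_um"] = list(grid.soma_xy_um)
        f.attrs["holding_mv"] = grid.holding_mv
        f.attrs["layer_bounds_um"] = json.dumps(grid.layer_bounds_um,
                                                sort_keys=True)


def load_grid(path) -> UncagingGrid:
    with h5py.File(path, "r") as f:
        if "sweeps_pA" not in f:
            raise KeyError(f"{path}: missing dataset 'sweeps_pA'")
        for attr in ("sampling_hz", "illumination_onset_s"):
            if attr not in f.attrs:
                raise KeyError(f"{path}: missing attribute {attr!r}")
        sweeps = f["sweeps_pA"][...]
        lb_raw = f.attrs.get("layer_bounds_um", "")
        kwargs = {}
        if lb_raw:
            kwargs["layer_bounds_um"] = {
                k: tuple(v) for k, v in json.loads(lb_raw).items()}
        return UncagingGrid(
            sweeps=sweeps,
            sampling_hz=float(f.attrs["sampling_hz"]),
            illumination_onset_s=float(f.attrs["illumination_onset_s"]),
            site_spacing_um=float(f.attrs.get("site_spacing_um", 50.0)),
            soma_xy_um=tuple(f.attrs.get("soma_xy_um", (500.0, 200.0))),
            holding_mv=float(f.attrs.get("holding_mv", -45.0)),
            **kwargs)


# ---------------------------------------------------------------------------
# Configs (YAML)
# ---------------------------------------------------------------------------

def save_config(path, config: dict):
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


# ---------------------------------------------------------------------------
# Kind dispatcher
# ---------------------------------------------------------------------------

_LOADERS = {"movie": load_movie, "stack": load_stack,
            "points": load_points, "grid": load_grid}


def load_inputs(path, kind: str):
    """Load a typed input object; ``kind`` is one of movie / stack /
    points / grid."""
    if kind not in _LOADERS:
        raise ValueError(f"unknown input kind {kind!r}; "
                         f"choose from {sorted(_LOADERS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return _LOADERS[kind](path)
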