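"""Starter-to-presynaptic distance-distribution analysis.

Monosynaptic rabies tracing labels starter cells and their direct
presynaptic partners; because pairings are unobservable, connectivity reach
is summarised probabilistically: the 2D Euclidean distance from every starter
to every presynaptic cell within an 800 um radius, per-starter empirical
CDFs on a fixed grid, group comparison with a two-sample Kolmogorov-Smirnov
test, and a decremental randomized-subsampling control that re-estimates the
profile while shrinking the starter population one cell at a time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import ks_2samp

__all__ = [
    "TracingPointSet",
    "DistanceProfile",
    "KsComparison",
    "pairwise_distances",
    "cumulative_profile",
    "compare_profiles",
    "randomized_subsampling",
]

DEFAULT_RADIUS_UM = 800.0


@dataclass
class TracingPointSet:
    """Starter and presynaptic coordinates (um) in the barrel-field plane."""

    starters: np.ndarray      # (n_starters, 2)
    presynaptic: np.ndarray   # (n_presyn, 2)
    brain: str = "brain0"
    cell_type: str = "unknown"

    def __post_init__(self):
        self.starters = np.atleast_2d(np.asarray(self.starters, dtype=float))
        self.presynaptic = np.atleast_2d(
            np.asarray(self.presynaptic, dtype=float))
        for name, arr in (("starters", self.starters),
                          ("presynaptic", self.presynaptic)):
            if arr.shape[1] != 2:
                raise ValueError(f"{name} must be (n, 2) xy coordinates")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite coordinates")

    @property
    def ratio(self) -> float:
        """Observed presynaptic-per-starter cell ratio."""
        return self.presynaptic.shape[0] / self.starters.shape[0]


@dataclass
class DistanceProfile:
    """Per-starter distances and CDFs on a fixed 1-um grid over [0, radius]."""

    per_starter: list                 # sorted in-radius distance arrays
    grid_um: np.ndarray
    cdfs: np.ndarray                  # (n_starters_with_partners, n_grid)
    average_cdf: np.ndarray
    n_excluded_starters: int = 0

    def pooled(self) -> np.ndarray:
        if not self.per_starter:
            return np.empty(0)
        return np.concatenate(self.per_starter)


@dataclass
class KsComparison:
    statistic: float
    pvalue: float
    unreliable: bool = False
    method: str = "pooled"


def pairwise_distances(points: TracingPointSet,
                       radius_um: float = DEFAULT_RADIUS_UM):
    """Starter-to-presynaptic Euclidean distances, cut at ``radius_um``.

    Returns one sorted array per starter; the radius boundary is inclusive.
    """
    if points.starters.size == 0 or points.presynaptic.size == 0:
        raise ValueError("both starter and presynaptic sets must be non-empty")
    d = cdist(points.starters, points.presynaptic)
    return [np.sort(row[row <= radius_um]) for row in d]


def cumulative_profile(distances, radius_um: float = DEFAULT_RADIUS_UM,
                       grid_step_um: float = 1.0) -> DistanceProfile:
    """Per-starter empirical CDFs and their unweighted average.

    Each starter's CDF is over its own in-radius partners; starters with no
    in-radius partner are excluded from the average and counted.
    """
    grid = np.arange(0.0, radius_um + grid_step_um / 2, grid_step_um)
    kept, cdfs = [], []
    n_excluded = 0
    for d in distances:
        d = np.sort(np.asarray(d, dtype=float))
        if d.size == 0:
            n_excluded += 1
            continue
        kept.append(d)
        cdfs.append(np.searchsorted(d, grid, side="right") / d.size)
    if not kept:
        raise ValueError("no starter has an in-radius presynaptic partner")
    cdfs = np.asarray(cdfs)
    return DistanceProfile(per_starter=kept, grid_um=grid, cdfs=cdfs,
                           average_cdf=cdfs.mean(axis=0),
                           n_excluded_starters=n_excluded)


def compare_profiles(profile_a: DistanceProfile, profile_b: DistanceProfile,
                     method: str = "pooled", n_permutations: int = 1000,
                     seed: int = 0) -> KsComparison:
    """Two-sample KS comparison of two distance distributions.

    The default pools all per-starter distances per group. The
    ``average_cdf`` alternative uses the sup-difference of the per-starter
    average CDFs with a starter-level permutation p-value, which respects
    the within-starter dependence of pooled distances.
    """
    a, b = profile_a.pooled(), profile_b.pooled()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must contain distances")
    unreliable = a.size < 3 or b.size < 3
    if method == "pooled":
        res = ks_2samp(a, b)
        return KsComparison(float(res.statistic), float(res.pvalue),
                            unreliable, "pooled")
    if method != "average_cdf":
        raise ValueError("method must be 'pooled' or 'average_cdf'")
    stat = float(np.max(np.abs(profile_a.average_cdf - profile_b.average_cdf)))
    rng = np.random.default_rng(seed)
    all_cdfs = np.vstack([profile_a.cdfs, profile_b.cdfs])
    na = profile_a.cdfs.shape[0]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(all_cdfs.shape[0])
        pa = all_cdfs[perm[:na]].mean(axis=0)
        pb = all_cdfs[perm[na:]].mean(axis=0)
        if np.max(np.abs(pa - pb)) >= stat:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return KsComparison(stat, float(p), unreliable, "average_cdf")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def randomized_subsampling(points: TracingPointSet, ratio: float = None,
                           n_iterations: int = 10,
                           radius_um: float = DEFAULT_RADIUS_UM,
                           seed: int = 0):
    """Decremental randomized subsampling of the distance profile.

    For starter counts k = S down to 1, draw k starters and
    ``round(k * ratio)`` presynaptic cells uniformly without replacement
    (``ratio`` defaults to the observed presynaptic-per-starter ratio) and
    recompute the cumulative profile; ten iterations per k. The family of
    profiles shows whether the group-level profile is robust to the number
    of starter cells sampled.

    Returns a dict mapping ``(k, iteration)`` to :class:`DistanceProfile`.
    """
    if ratio is None:
        ratio = points.ratio
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    S = points.starters.shape[0]
    P = points.presynaptic.shape[0]
    rng = np.random.default_rng(seed)
    out = {}
    for k in range(S, 0, -1):
        m = _round_half_away(k * ratio)
        if m > P:
            warnings.warn(f"k={k}: requested {m} presynaptic cells, "
                          f"capping at available {P}")
            m = P
        if m == 0:
            warnings.warn(f"k={k}: zero presynaptic cells requested; skipped")
            continue
        for it in range(n_iterations):
            si = rng.choice(S, size=k, replace=False)
            pi = rng.choice(P, size=m, replace=False)
            sub = TracingPointSet(points.starters[si],
                                  points.presynaptic[pi],
                                  brain=points.brain,
                                  cell_type=points.cell_type)
            dists = pairwise_distances(sub, radius_um=radius_um)
            try:
                out[(k, it)] = cumulative_profile(dists, radius_um=radius_um)
            except ValueError:
                out[(k, it)] = None  # no in-radius partner in this draw
    return out
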