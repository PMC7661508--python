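"""Stimulus-paradigm decoding from evoked calcium responses.

Discriminability of the single- versus multi-whisker response is quantified
with three classifiers — a random forest (50 trees, minimum leaf size 5),
Gaussian naive Bayes, and an error-correcting-output-codes classifier
realised as one-vs-one linear SVMs — each retrained 1000 times on random
stratified 70/30 splits of baseline-subtracted trial-averaged response
vectors, reporting the distribution of held-out accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsOneClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import LinearSVC

from .calcium import TraceMatrix, _window_frames

__all__ = [
    "FeatureTable",
    "DecodingResult",
    "build_feature_matrix",
    "evaluate_decoders",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("random_forest", "naive_bayes", "ecoc")


@dataclass
class FeatureTable:
    """Baseline-subtracted response vectors with binary paradigm labels."""

    samples: np.ndarray   # (n, p) response-window vectors
    labels: np.ndarray    # (n,) 0 = single, 1 = multi
    cell_ids: np.ndarray = None
    aligned: np.ndarray = None  # (n, p_base + p) incl. pre-onset segment
    n_baseline_samples: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("feature matrix contains non-finite values")
        if np.unique(self.labels).size < 2:
            raise ValueError("both stimulus classes must be present")


@dataclass
class DecodingResult:
    """Per-classifier held-out accuracies over the resampling repeats."""

    accuracies: dict            # name -> ndarray (n_repeats,)
    mean: dict = field(default_factory=dict)
    ci95: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, acc in self.accuracies.items():
            acc = np.asarray(acc, dtype=float)
            if np.any((acc < 0) | (acc > 1)):
                raise ValueError(f"{name}: accuracies outside [0, 1]")
            self.accuracies[name] = acc
            self.mean[name] = float(acc.mean())
            self.ci95[name] = (float(np.percentile(acc, 2.5)),
                               float(np.percentile(acc, 97.5)))


PARADIGM_CODES = {"single": 0, "multi": 1}


def build_feature_matrix(dff: TraceMatrix, onsets_by_paradigm: dict,
                         response_window_s: float = 8.0,
                         baseline_window_s: float = 1.0) -> FeatureTable:
    """One sample per (cell, paradigm): the trial-averaged dF/F response.

    The trial-averaged trace over ``[onset - baseline, onset + response)``
    has its pre-onset baseline mean subtracted; the feature vector is the
    response-window portion (``floor(response_window_s * frame_rate)``
    samples). The full baseline-included aligned traces are kept on the
    table for inspection.
    """
    for paradigm in PARADIGM_CODES:
        if paradigm not in onsets_by_paradigm or not len(
                onsets_by_paradigm[paradigm]):
            raise ValueError(f"missing stimulus paradigm {paradigm!r}")
    if dff.n_cells < 2:
        raise ValueError("need >= 2 cells to build a feature table")
    fr = dff.frame_rate_hz
    n_resp = _window_frames(fr, response_window_s)
    n_base = _window_frames(fr, baseline_window_s)
    samples, labels, cells, aligned = [], [], [], []
    for paradigm, code in PARADIGM_CODES.items():
        onsets = onsets_by_paradigm[paradigm]
        for i in range(dff.n_cells):
            trials = []
            for o in onsets:
                if o - n_base < 0 or o + n_resp > dff.n_frames:
                    raise ValueError(f"trial at onset {o} exceeds trace")
                trials.append(dff.values[i, o - n_base:o + n_resp])
            avg = np.mean(trials, axis=0)
            avg = avg - avg[:n_base].mean()
            samples.append(avg[n_base:])
            aligned.append(avg)
            labels.append(code)
            cells.append(dff.cell_ids[i])
    return FeatureTable(samples=np.asarray(samples),
                        labels=np.asarray(labels),
                        cell_ids=np.asarray(cells),
                        aligned=np.asarray(aligned),
                        n_baseline_samples=n_base)


def _make_classifiers(rs):
    return {
        "random_forest": RandomForestClassifier(
            n_estimators=50, min_samples_leaf=5, random_state=rs, n_jobs=1),
        "naive_bayes": GaussianNB(),
        "ecoc": OneVsOneClassifier(LinearSVC(random_state=rs,
                                             max_iter=5000)),
    }


def evaluate_decoders(table: FeatureTable, n_repeats: int = 1000,
                      train_fraction: float = 0.7, seed: int = 0,
                      classifiers=CLASSIFIER_NAMES,
                      permute_labels: bool = False) -> DecodingResult:
    """Resampled held-out accuracy of the three classifiers.

    Per repeat a stratified ``train_fraction`` split is drawn, each
    classifier is trained from scratch, and accuracy is measured on the
    held-out remainder. Stratification guarantees both classes in every
    training split. With ``permute_labels`` the labels are freshly permuted
    every repeat, giving the chance-level permutation null. Bit-exact
    reproducible for a fixed seed.
    """
    X, y = table.samples, table.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples for stratified splits")
    rng = np.random.default_rng(seed)
    acc = {name: np.empty(n_repeats) for name in classifiers}
    for rep in range(n_repeats):
        rs = int(rng.integers(0, 2**31 - 1))
        y_rep = rng.permutation(y) if permute_labels else y
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y_rep, train_size=train_fraction, stratify=y_rep,
            random_state=rs)
        models = _make_classifiers(rs)
        for name in classifiers:
            model = models[name]
            model.fit(X_tr, y_tr)
            acc[name][rep] = float(np.mean(model.predict(X_te) == y_te))
    return DecodingResult(accuracies=acc)
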