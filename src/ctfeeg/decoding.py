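"""Backward decoding: per-timepoint k-fold linear discriminant analysis.

For every time sample, a linear discriminant classifier is trained on the
electrode voltages of 90% of trials and tested on the held-out 10%,
cycling through 10 stratified folds so every trial is tested exactly once.
Accuracy is computed per class (the fraction of that class's test trials
assigned correctly), averaged over classes, and then over folds, giving a
class-balanced accuracy time course whose chance level is 1/n_classes.

Classifier weights are not interpretable as neural sources; multiplying
them by the data covariance (the Haufe transformation) yields activation
patterns equivalent to the mass-univariate condition difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold


@dataclass
class FoldAssignment:
    """Stratified fold index (1..K) per trial."""

    folds: np.ndarray
    n_folds: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.folds = np.asarray(self.folds, dtype=int)
        present = np.unique(self.folds)
        if not np.array_equal(present, np.arange(1, self.n_folds + 1)):
            raise ValueError("fold indices must cover 1..K")

    def split(self):
        """Yield (train_idx, test_idx) per fold."""
        for f in range(1, self.n_folds + 1):
            test = np.flatnonzero(self.folds == f)
            train = np.flatnonzero(self.folds != f)
            yield train, test


def assign_folds(labels: np.ndarray, n_folds: int = 10,
                 seed: int | None = None) -> FoldAssignment:
    """Random stratified folds of near-equal size.

    Randomizing the assignment removes any information carried by trial
    acquisition order. Every class must contribute at least one trial to
    every fold, which requires >= K trials per class.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    too_few = classes[counts < n_folds]
    if len(too_few):
        raise ValueError(
            f"classes {too_few.tolist()} have fewer than {n_folds} trials; "
            f"cannot stratify into {n_folds} folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=seed)
    folds = np.zeros(len(labels), dtype=int)
    for i, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels), 1):
        folds[test] = i
    return FoldAssignment(folds=folds, n_folds=n_folds, seed=seed)


@dataclass
class LinearClassifier:
    """Trained LDA: per-class discriminant weights over electrodes."""

    weights: np.ndarray            # (n_classes, m) or (1, m) for 2 classes
    intercepts: np.ndarray
    pooled_covariance: np.ndarray  # (m, m), shrinkage-regularized
    classes: np.ndarray
    shrinkage: float | None = None

    def decision(self, x: np.ndarray) -> np.ndarray:
        return x @ self.weights.T + self.intercepts

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self.decision(np.atleast_2d(x))
        if len(self.classes) == 2 and scores.shape[1] == 1:
            return self.classes[(scores[:, 0] > 0).astype(int)]
        # argmax with ties going to the lowest class index
        return self.classes[np.argmax(scores, axis=1)]


def train_lda(train_data: np.ndarray, labels: np.ndarray,
              shrinkage: str | float | None = "auto") -> LinearClassifier:
    """Fit a linear discriminant classifier at one time sample.

    Uses class means and a pooled covariance with Ledoit-Wolf automatic
    shrinkage by default, which keeps the solution finite even when the
    electrode covariance is rank-deficient. Deterministic given the data.
    """
    train_data = np.asarray(train_data, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train a discriminant")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    lda.fit(train_data, labels)
    return LinearClassifier(
        weights=np.atleast_2d(lda.coef_),
        intercepts=np.atleast_1d(lda.intercept_),
        pooled_covariance=lda.covariance_,
        classes=lda.classes_,
        shrinkage=None if not isinstance(shrinkage, float) else shrinkage,
    )


@dataclass
class DecodingResult:
    """Accuracy time courses of a cross-validated decoder."""

    accuracy: np.ndarray          # (samples, folds, classes): per-class recall
    times: np.ndarray
    classes: np.ndarray
    n_folds: int
    chance: float = field(init=False)
    aggregate: np.ndarray = field(init=False)   # (samples,)

    def __post_init__(self) -> None:
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")
        self.chance = 1.0 / len(self.classes)
        # first average over classes (conditions), then over folds
        self.aggregate = self.accuracy.mean(axis=2).mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        t, f, c = self.accuracy.shape
        ti, fi, ci = np.meshgrid(np.arange(t), np.arange(f), np.arange(c),
                                 indexing="ij")
        return pd.DataFrame({
            "time_ms": self.times[ti.ravel()],
            "accuracy": self.accuracy.ravel(),
            "fold": fi.ravel() + 1,
            "class": self.classes[ci.ravel()],
        })

    def summary(self, window: tuple[float, float] | None = None) -> dict:
        lo = self.times[0] if window is None else window[0]
        hi = self.times[-1] if window is None else window[1]
        latency, value = find_peak(self.aggregate, self.times, (lo, hi))
        return {"peak_latency_ms": float(latency),
                "peak_accuracy": float(value),
                "chance": float(self.chance),
                "n_classes": int(len(self.classes)),
                "n_folds": int(self.n_folds)}

    def export(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2)


def decode_timecourse(epochs, folds: FoldAssignment,
                      labels: np.ndarray | None = None,
                      shrinkage: str | float | None = "auto",
                      ) -> DecodingResult:
    """Cross-validated LDA accuracy at every time sample.

    ``labels`` defaults to ``epochs.labels``; passing an explicit vector
    supports label-permutation controls. Training never sees the held-out
    fold, so test data cannot influence the classifier.
    """
    labels = epochs.labels if labels is None else np.asarray(labels)
    if len(labels) != epochs.n_trials:
        raise ValueError("labels must match trial count")
    if len(folds.folds) != epochs.n_trials:
        raise ValueError("fold assignment must match trial count")
    classes = np.unique(labels)
    n_t = epochs.n_samples
    acc = np.full((n_t, folds.n_folds, len(classes)), np.nan)

    for fi, (train, test) in enumerate(folds.split()):
        y_train, y_test = labels[train], labels[test]
        if len(np.unique(y_train)) != len(classes):
            raise ValueError(f"fold {fi + 1}: training split misses a class")
        for ti in range(n_t):
            clf = train_lda(epochs.data[train, :, ti], y_train,
                            shrinkage=shrinkage)
            pred = clf.predict(epochs.data[test, :, ti])
            for ci, c in enumerate(classes):
                sel = y_test == c
                if not np.any(sel):
                    raise ValueError(
                        f"fold {fi + 1}: no test trials of class {c}")
                acc[ti, fi, ci] = np.mean(pred[sel] == c)
    return DecodingResult(accuracy=acc, times=epochs.times.copy(),
                          classes=classes, n_folds=folds.n_folds)


@dataclass
class ActivationPattern:
    """Per-electrode activation pattern (one value per electrode)."""

    values: np.ndarray
    electrodes: list[str]
    window: tuple[float, float] | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.electrodes),):
            raise ValueError("pattern must hold one value per electrode")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"electrode": self.electrodes,
                             "value": self.values})


def haufe_pattern(classifier: LinearClassifier, data: np.ndarray,
                  electrodes: list[str],
                  window: tuple[float, float] | None = None,
                  contrast: int = 0) -> ActivationPattern:
    """Haufe-transformed activation pattern: data covariance times the
    classifier weight vector.

    ``data`` must be the training trials (trials x electrodes) of the
    classifier's own fold so that the transform stays independent of test
    data. For a two-class classifier there is a single contrast; for
    multi-class, ``contrast`` selects the class-vs-rest weight row.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[1] != classifier.weights.shape[1]:
        raise ValueError("data electrode axis does not match classifier")
    if data.shape[1] != len(electrodes):
        raise ValueError("electrode names do not match data")
    cov = np.cov(data, rowvar=False, ddof=1)
    w = classifier.weights[contrast]
    return ActivationPattern(values=cov @ w, electrodes=list(electrodes),
                             window=window)


def spatial_normalize(pattern: ActivationPattern) -> ActivationPattern:
    """Z-score across electrodes (population SD): mean 0, SD 1.

    Makes patterns comparable across subjects and experiments. Affine
    transformations of the input leave the output unchanged.
    """
    v = pattern.values
    sd = v.std()  # population (divide-by-n) convention
    if sd < 1e-12 * max(1.0, np.abs(v).max()):
        raise ValueError("cannot normalize a pattern with zero spread")
    return ActivationPattern(values=(v - v.mean()) / sd,
                             electrodes=list(pattern.electrodes),
                             window=pattern.window, normalized=True)


def smooth_for_display(aggregate: np.ndarray, times: np.ndarray,
                       target_rate: float = 32.0,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Display-only spline smoothing anchored at the accuracy peak.

    The series is downsampled to ``target_rate`` on a grid that contains
    the peak sample (so the peak height is not diluted), and a cubic
    spline through the retained points is evaluated back on the original
    time axis. Returns ``(smoothed, times)``. Statistics must always use
    the raw series.
    """
    aggregate = np.asarray(aggregate, dtype=float)
    times = np.asarray(times, dtype=float)
    if aggregate.size == 0:
        raise ValueError("empty series")
    if aggregate.size < 4:
        return aggregate.copy(), times.copy()
    sfreq = 1000.0 / (times[1] - times[0])
    step = max(1, int(round(sfreq / target_rate)))
    peak = int(np.argmax(aggregate))
    grid = np.arange(peak % step, len(aggregate), step)
    if grid[0] != 0:
        grid = np.r_[0, grid]
    if grid[-1] != len(aggregate) - 1:
        grid = np.r_[grid, len(aggregate) - 1]
    spline = CubicSpline(times[grid], aggregate[grid])
    return spline(times), times.copy()


def find_peak(series: np.ndarray, times: np.ndarray,
              window: tuple[float, float]) -> tuple[float, float]:
    """Latency (ms) and value of the maximum within ``window``; ties go
    to the earliest sample."""
    series = np.asarray(series, dtype=float)
    times = np.asarray(times, dtype=float)
    lo, hi = window
    mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
    if not np.any(mask):
        raise ValueError(f"window ({lo}, {hi}) ms contains no samples")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(series[idx])]  # argmax returns the first maximum
    return float(times[best]), float(series[best])
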