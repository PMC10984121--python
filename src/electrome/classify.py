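"""Interval-arithmetic feature reduction and the multi-classifier harness.

A 450,000-point series is reduced to 15 non-overlapping windows of 30,000
points, each summarized by the triplet [min, mean, max] — 45 scalars per
series. Labeled triplet vectors feed a roster of six classifiers (KNN, DT,
RF, Gaussian Bayes, SVM, ANN) evaluated by repeated stratified holdout at
training fractions 10-90%, 20 repetitions each, with pooled row-normalized
confusion matrices and paired Wilcoxon comparison of per-repetition
accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ParameterError
from .features import _as_array
from .types import ElectromeSeries

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 30_000
DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))
CLASSIFIER_ROSTER = ("KNN", "DT", "RF", "Bayes", "SVM", "ANN")


# ---------------------------------------------------------------------------
# interval-arithmetic reduction

@dataclass
class IntervalFeatureVector:
    """Per-window [min, center, max] triplets of one series."""

    triplets: np.ndarray          # shape (n_windows, 3)
    window_size: int
    source_meta: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.triplets.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """The 3*n_windows scalar feature vector fed to classifiers."""
        return self.triplets.reshape(-1)


def interval_reduce(series: Union[ElectromeSeries, np.ndarray, Sequence[float]],
                    window_size: int = DEFAULT_WINDOW,
                    center: str = "mean") -> IntervalFeatureVector:
    """Reduce a series to per-window (min, center, max) triplets.

    Consecutive non-overlapping windows of ``window_size`` samples; a
    trailing partial window is dropped. ``center`` is the arithmetic mean
    by default (``"median"`` is available, as the triplet's middle element
    is sometimes defined either way in the plant-electrome literature).
    """
    x = _as_array(series)
    if window_size < 1:
        raise ParameterError("window_size must be >= 1")
    if x.size < window_size:
        raise ParameterError(
            f"series of {x.size} samples shorter than one window "
            f"({window_size})")
    if center not in ("mean", "median"):
        raise ParameterError(f"center must be 'mean' or 'median', got {center!r}")
    n_windows = x.size // window_size
    w = x[:n_windows * window_size].reshape(n_windows, window_size)
    mid = w.mean(axis=1) if center == "mean" else np.median(w, axis=1)
    triplets = np.column_stack([w.min(axis=1), mid, w.max(axis=1)])
    meta = dict(series.meta) if isinstance(series, ElectromeSeries) else {}
    return IntervalFeatureVector(triplets=triplets, window_size=window_size,
                                 source_meta=meta)


def feature_matrix(vectors: Sequence[IntervalFeatureVector],
                   labels: Sequence) -> Tuple[np.ndarray, np.ndarray]:
    """Stack flattened triplet vectors into (X, y) for the harness."""
    if len(vectors) != len(labels):
        raise ParameterError("one label per feature vector required")
    dims = {v.flat.size for v in vectors}
    if len(dims) > 1:
        raise ParameterError(f"inconsistent feature dimensions: {sorted(dims)}")
    X = np.vstack([v.flat for v in vectors])
    return X, np.asarray(labels)


# ---------------------------------------------------------------------------
# classifier roster

def make_classifier(name: str, seed: int = 0):
    """Instantiate a roster classifier with its documented defaults."""
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "Bayes":
        return GaussianNB()
    if name == "SVM":
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0,
                                                   random_state=seed))
    if name == "ANN":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(32,), solver="lbfgs",
                          max_iter=2000, random_state=seed))
    raise ParameterError(f"unknown classifier {name!r}; "
                         f"roster is {CLASSIFIER_ROSTER}")


def _derived_seed(master_seed: int, clf_index: int, frac_index: int,
                  repetition: int) -> int:
    """Reconstructible per-split seed from (master, classifier, fraction, rep)."""
    ss = np.random.SeedSequence([master_seed, clf_index, frac_index,
                                 repetition])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# evaluation containers

@dataclass
class ClassifierEvaluation:
    """Learning-curve and confusion results for one classifier."""

    classifier_name: str
    training_fractions: np.ndarray            # (F,)
    accuracies: np.ndarray                    # (F, repetitions)
    confusion: Optional[np.ndarray] = None    # row-normalized, pooled
    confusion_fraction: Optional[float] = None
    classes: Optional[np.ndarray] = None
    seed: int = 0

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    def accuracy_at(self, fraction: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.training_fractions - fraction)))
        return self.accuracies[idx]


def confusion_matrix(true_labels: Sequence, predicted_labels: Sequence,
                     classes: Sequence) -> np.ndarray:
    """Row-normalized confusion matrix.

    Entry (i, j) is the fraction of class-i items predicted as class j;
    each supported row sums to 1. Rows for classes with zero support are
    left as all-zero (and logged).
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    classes = np.asarray(classes)
    if classes.size == 0:
        raise ParameterError("classes must be non-empty")
    if true_labels.shape != predicted_labels.shape:
        raise ParameterError("label sequences must have equal length")
    known = set(classes.tolist())
    for name, arr in (("true", true_labels), ("predicted", predicted_labels)):
        extra = set(arr.tolist()) - known
        if extra:
            raise ParameterError(f"{name} labels outside classes: {sorted(extra)}")
    counts = sk_confusion(true_labels, predicted_labels,
                          labels=classes).astype(float)
    support = counts.sum(axis=1)
    out = np.zeros_like(counts)
    nz = support > 0
    out[nz] = counts[nz] / support[nz, None]
    if not nz.all():
        log.warning("classes with zero support: %s", classes[~nz])
    return out


def _stratified_split(X, y, fraction, seed, max_redraws: int = 20):
    """Stratified holdout split; re-drawn if a class is missing from train."""
    classes = np.unique(y)
    for attempt in range(max_redraws):
        try:
            Xtr, Xte, ytr, yte = train_test_split(
                X, y, train_size=fraction, stratify=y,
                random_state=(seed + attempt) % (2 ** 31))
        except ValueError as exc:
            raise ParameterError(
                f"cannot stratify {y.size} samples over {classes.size} "
                f"classes at training fraction {fraction}: {exc}") from exc
        if np.isin(classes, ytr).all() and yte.size:
            if attempt:
                log.info("split re-drawn %d time(s)", attempt)
            return Xtr, Xte, ytr, yte
    raise ParameterError(
        f"could not draw a split with all classes at fraction {fraction}")


def run_learning_curve(X: np.ndarray, y: np.ndarray,
                       classifiers: Sequence[str] = CLASSIFIER_ROSTER,
                       fractions: Sequence[float] = DEFAULT_FRACTIONS,
                       repetitions: int = 20, seed: int = 0,
                       confusion_fraction: Optional[float] = None
                       ) -> list[ClassifierEvaluation]:
    """Repeated stratified-holdout learning curves for a classifier roster.

    For every classifier and training fraction, ``repetitions`` stratified
    train/test splits are drawn with seeds derived from
    (master seed, classifier, fraction, repetition), the classifier is
    refit and its test accuracy recorded. A pooled row-normalized
    confusion matrix is assembled at ``confusion_fraction`` (default: the
    fraction with the best mean accuracy for that classifier).

    Deterministic given the master seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("need at least 2 classes")
    if counts.min() < 2:
        raise ParameterError("need at least 2 samples per class")
    if repetitions < 1:
        raise ParameterError("repetitions must be >= 1")
    fractions = np.asarray(sorted(fractions), dtype=float)
    if np.any((fractions <= 0) | (fractions >= 1)):
        raise ParameterError("training fractions must lie in (0, 1)")

    evaluations = []
    for ci, name in enumerate(classifiers):
        acc = np.empty((fractions.size, repetitions))
        preds: dict[int, list] = {fi: [] for fi in range(fractions.size)}
        trues: dict[int, list] = {fi: [] for fi in range(fractions.size)}
        for fi, fraction in enumerate(fractions):
            for rep in range(repetitions):
                split_seed = _derived_seed(seed, ci, fi, rep)
                Xtr, Xte, ytr, yte = _stratified_split(X, y, fraction,
                                                       split_seed)
                clf = make_classifier(name, seed=split_seed)
                if name == "KNN" and ytr.size < 5:
                    clf.set_params(n_neighbors=ytr.size)  # tiny training sets
                clf.fit(Xtr, ytr)
                yp = clf.predict(Xte)
                acc[fi, rep] = float(np.mean(yp == yte))
                preds[fi].append(yp)
                trues[fi].append(yte)
        if confusion_fraction is None:
            best_fi = int(np.argmax(acc.mean(axis=1)))
        else:
            best_fi = int(np.argmin(np.abs(fractions - confusion_fraction)))
        conf = confusion_matrix(np.concatenate(trues[best_fi]),
                                np.concatenate(preds[best_fi]), classes)
        evaluations.append(ClassifierEvaluation(
            classifier_name=name, training_fractions=fractions,
            accuracies=acc, confusion=conf,
            confusion_fraction=float(fractions[best_fi]),
            classes=classes, seed=seed))
    return evaluations


# ---------------------------------------------------------------------------
# paired comparison of two classifiers

@dataclass
class WilcoxonComparison:
    """Wilcoxon signed-rank comparison of paired per-repetition accuracies."""

    statistic: Optional[float]
    p_value: Optional[float]
    n: int
    no_difference: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value is not None and self.p_value <= alpha


def compare_classifiers(accuracy_samples_a: Sequence[float],
                        accuracy_samples_b: Sequence[float]
                        ) -> WilcoxonComparison:
    """Two-sided Wilcoxon signed-rank test on paired accuracy arrays.

    Arrays must be equal length (20 repetitions in the standard harness).
    If every pairwise difference is zero the result is flagged
    ``no_difference`` instead of reporting a p-value.
    """
    a = np.asarray(accuracy_samples_a, dtype=float)
    b = np.asarray(accuracy_samples_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError(
            f"paired accuracy arrays must be 1-D and equal length, got "
            f"{a.shape} vs {b.shape}")
    if a.size < 2:
        raise ParameterError("need at least 2 paired repetitions")
    diffs = a - b
    if np.all(diffs == 0):
        return WilcoxonComparison(statistic=None, p_value=None, n=a.size,
                                  no_difference=True)
    stat, p = sp_stats.wilcoxon(a, b, zero_method="wilcox",
                                alternative="two-sided")
    return WilcoxonComparison(statistic=float(stat), p_value=float(p),
                              n=a.size)
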