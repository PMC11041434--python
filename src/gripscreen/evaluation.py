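"""Grouped cross-validation, ROC analysis, and cutoff selection.

Validation follows the screening-study recipe: 10-fold cross-validation
produces one out-of-fold probability score per sample, a ROC curve is
swept over all score thresholds, its area summarizes discrimination, and
the operating point closest to the upper-left corner of the ROC plane is
reported as the optimal cutoff with its sensitivity and specificity.

Folds are grouped by participant: the two hands and two trials of one
person are strongly correlated, so letting them straddle a train/test
boundary would leak identity information and inflate the AUC. Folds are
additionally stratified by class at the participant level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classifier import ModelConfig, score_samples, train_classifier
from .errors import ConfigurationError, UndefinedROCError


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of samples into k folds, grouped by participant."""

    k: int
    fold_of_sample: np.ndarray  # (n,) fold index per sample
    groups: np.ndarray          # (n,) grouping key per sample

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)


def make_group_folds(groups, labels, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Label-stratified, group-wise k-fold assignment.

    Every distinct group (participant) lands in exactly one fold; within
    each class, groups are shuffled and dealt round-robin so fold sizes
    are as equal as possible and each fold sees both classes when counts
    allow. Deterministic given ``seed``.
    """
    groups = np.asarray(groups)
    labels = np.asarray(labels).astype(int).ravel()
    if groups.shape[0] != labels.shape[0]:
        raise ConfigurationError("groups and labels length mismatch")
    uniq, first = np.unique(groups, return_index=True)
    if uniq.size < k:
        raise ConfigurationError(
            f"need at least k={k} distinct groups, got {uniq.size}")
    group_label = {}
    for g in uniq:
        ls = np.unique(labels[groups == g])
        if ls.size != 1:
            raise ConfigurationError(f"group {g!r} carries multiple labels")
        group_label[g] = int(ls[0])

    rng = np.random.default_rng(seed)
    fold_of_group: dict = {}
    counter = 0
    for cls in sorted(set(group_label.values())):
        members = np.array([g for g in uniq if group_label[g] == cls])
        members = members[rng.permutation(members.size)]
        for g in members:
            fold_of_group[g] = counter % k
            counter += 1
    fold_of_sample = np.array([fold_of_group[g] for g in groups], dtype=int)
    return FoldAssignment(k=k, fold_of_sample=fold_of_sample, groups=groups)


def cross_validate(X, y, groups, model_config: ModelConfig = ModelConfig(),
                   k: int = 10, seed: int = 0) -> np.ndarray:
    """Out-of-fold probability scores from grouped k-fold cross-validation.

    Each sample is scored exactly once, by a model trained without any
    sample of its participant; feature-scaling statistics are refit
    inside every training fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    folds = make_group_folds(groups, y, k=k, seed=seed)
    scores = np.full(y.shape[0], np.nan)
    for fold in range(k):
        test = folds.test_indices(fold)
        if test.size == 0:
            continue
        train = folds.train_indices(fold)
        model = train_classifier(X[train], y[train], model_config)
        scores[test] = score_samples(model, X[test])
    assert not np.isnan(scores).any()
    return scores


@dataclass(frozen=True)
class ROCCurve:
    """Ordered (threshold, FPR, TPR) points from (0, 0) to (1, 1)."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __len__(self) -> int:
        return self.thresholds.size


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise UndefinedROCError("ROC undefined: only one class present")


def roc_points(scores, labels) -> ROCCurve:
    """ROC curve swept over every distinct score (plus an infinite sentinel).

    A sample is called positive when its score is >= the threshold; FPR
    and TPR are both nondecreasing along the returned curve.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    _check_two_classes(labels)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr)


def auc_value(scores, labels) -> float:
    """Trapezoidal area under :func:`roc_points` in [0, 1].

    With the full (undropped) threshold sweep this equals the normalized
    Mann-Whitney pairwise statistic, with ties counting one half.
    """
    curve = roc_points(scores, labels)
    return float(np.trapezoid(curve.tpr, curve.fpr))


def optimal_cutoff(curve: ROCCurve) -> tuple[float, float, float]:
    """The ROC point closest to the upper-left corner (FPR 0, TPR 1).

    Minimizes sqrt(FPR^2 + (1 - TPR)^2) over curve points; exact ties in
    distance are broken toward higher TPR (a screening test favors
    sensitivity). Returns ``(threshold, sensitivity %, specificity %)``.
    """
    if len(curve) == 0:
        raise UndefinedROCError("empty ROC curve")
    d = np.hypot(curve.fpr, 1.0 - curve.tpr)
    dmin = d.min()
    candidates = np.flatnonzero(d <= dmin + 1e-12)
    best = candidates[np.argmax(curve.tpr[candidates])]
    return (float(curve.thresholds[best]),
            float(100.0 * curve.tpr[best]),
            float(100.0 * (1.0 - curve.fpr[best])))


@dataclass(frozen=True)
class MetricsReport:
    """Headline screening metrics at the optimal cutoff."""

    sensitivity: float  # percent
    specificity: float  # percent
    auc: float
    threshold: float
    n_samples: int
    n_positive: int
    n_negative: int

    def to_dict(self) -> dict:
        return {"sensitivity_pct": round(self.sensitivity, 1),
                "specificity_pct": round(self.specificity, 1),
                "auc": round(self.auc, 2),
                "threshold": self.threshold,
                "n_samples": self.n_samples,
                "n_positive": self.n_positive,
                "n_negative": self.n_negative}


def evaluate_scores(scores, labels) -> MetricsReport:
    """ROC -> AUC -> optimal cutoff, bundled into one report."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    curve = roc_points(scores, labels)
    threshold, sens, spec = optimal_cutoff(curve)
    return MetricsReport(sensitivity=sens, specificity=spec,
                         auc=float(np.trapezoid(curve.tpr, curve.fpr)),
                         threshold=threshold,
                         n_samples=int(labels.size),
                         n_positive=int(labels.sum()),
                         n_negative=int(labels.size - labels.sum()))


def plot_roc(curve: ROCCurve, path, title: str = "ROC curve") -> None:
    """Write a ROC plot (optional; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _, sens, spec = optimal_cutoff(curve)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve.fpr, curve.tpr, "-", lw=1.5)
    ax.plot([0, 1], [0, 1], "--", color="gray", lw=0.8)
    ax.plot(1 - spec / 100, sens / 100, "r+", ms=12, mew=2)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
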