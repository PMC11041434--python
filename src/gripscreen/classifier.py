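"""Maximum-margin binary classification with probability scores.

The screening models classify high-dimensional spectral sample vectors
(p ~ 1e5) from small cohorts (n ~ 1e2) with a support vector machine.
Because n << p, a linear kernel with per-feature standardization is the
default; the regularization strength and kernel are configurable.
Scores are probabilities of the positive (disease) class obtained by
Platt sigmoid calibration fitted with internal cross-validation, so
downstream ROC thresholds live on a common [0, 1] scale.

Feature scaling statistics are learned from the training split only;
scoring applies them unchanged to new samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateTrainingError, DimensionError


@dataclass(frozen=True)
class ModelConfig:
    """SVM hyperparameters.

    kernel:
        "linear" (default; appropriate for n << p) or "rbf".
    C:
        Regularization strength (inverse), > 0.
    scaling:
        "standardize" (default) to z-score every feature on the training
        split, or "none".
    calibrate:
        If True (default), emit Platt-calibrated class probabilities;
        if False, emit a logistic squash of the decision value (same
        ranking, uncalibrated).
    class_weight:
        None (default) or "balanced".
    seed:
        Seed for the calibration's internal cross-fitting.
    """

    kernel: str = "linear"
    C: float = 1.0
    scaling: str = "standardize"
    calibrate: bool = True
    class_weight: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        if self.scaling not in ("standardize", "none"):
            raise ValueError(f"unsupported scaling {self.scaling!r}")


@dataclass
class TrainedModel:
    """Fitted classifier plus its configuration."""

    pipeline: Pipeline
    config: ModelConfig
    n_features: int


def _as_xy(X, y):
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int).ravel()
    if X.ndim != 2:
        raise DimensionError(f"X must be 2-D, got shape {X.shape}")
    if y.shape[0] != X.shape[0]:
        raise DimensionError("X and y length mismatch")
    return X, y


def train_classifier(X, y, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit the SVM on sample vectors X with binary labels y (1 = disease).

    Deterministic given (X, y, config). Raises
    :class:`DegenerateTrainingError` unless both classes have at least
    two samples.
    """
    X, y = _as_xy(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise DegenerateTrainingError(
            f"need >= 2 samples of each of two classes, got "
            f"{dict(zip(classes.tolist(), counts.tolist()))}")
    steps = []
    if config.scaling == "standardize":
        steps.append(("scale", StandardScaler()))
    svm = SVC(kernel=config.kernel, C=config.C,
              class_weight=config.class_weight, random_state=config.seed)
    if config.calibrate:
        # Platt sigmoid on cross-fitted decision values; the final
        # probabilities are a monotone transform of one SVM's decision
        # function, so rankings match the uncalibrated model.
        clf = CalibratedClassifierCV(svm, method="sigmoid",
                                     cv=int(min(5, counts.min())),
                                     ensemble=False)
    else:
        clf = svm
    steps.append(("svm", clf))
    pipe = Pipeline(steps)
    pipe.fit(X, y)
    return TrainedModel(pipeline=pipe, config=config, n_features=X.shape[1])


def score_samples(model: TrainedModel, X) -> np.ndarray:
    """Per-sample disease probability scores in [0, 1] (higher = more CM-like).

    The threshold applied later never affects these scores, only the
    binary call derived from them.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise DimensionError(
            f"model expects {model.n_features} features, got {X.shape[1]}")
    clf = model.pipeline.named_steps["svm"]
    if model.config.calibrate:
        proba = model.pipeline.predict_proba(X)
        col = int(np.where(clf.classes_ == 1)[0][0])
        return proba[:, col]
    decision = model.pipeline.decision_function(X)
    return 1.0 / (1.0 + np.exp(-decision))


def classify(model: TrainedModel, X, threshold: float = 0.5) -> np.ndarray:
    """Binary disease call: score >= threshold."""
    return (score_samples(model, X) >= threshold).astype(int)
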