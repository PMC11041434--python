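"""End-to-end experiment orchestration.

Two screening designs are supported, mirroring the study structure:

* ``CM_control`` — participant-level classification of myelopathy
  patients against healthy controls. Each sample concatenates the four
  trials of one participant (2 sides x 2 trials); CTS recordings are
  excluded entirely.
* ``CM_nonCM`` — hand-level classification of myelopathy against the
  pooled non-CM group (CTS plus controls), since CTS can affect a single
  hand. Each sample concatenates the two trials of one hand, with
  optional restriction to right or left hands ("total" pools both as
  separate samples; participant-grouped folds keep a person's two hands
  on the same side of every train/test split).

The per-bone ablation reruns the identical CM/control cross-validation
20 times, each restricted to the 9 channels (x 15 segments x 16 bins)
of a single finger bone, to locate which part of the hand carries the
discriminative signal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .classifier import ModelConfig
from .errors import DesignError
from .evaluation import MetricsReport, auc_value, cross_validate, evaluate_scores
from .recording_io import Recording
from .spectral_features import (
    DESIGNS,
    FEATURE_DIM,
    FeatureOptions,
    SampleVector,
    all_bones,
    bone_feature_indices,
    combine_trials,
    featurize_trial,
)

SIDE_CHOICES = ("total", "right", "left")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings of one experiment run."""

    design: str = "CM_control"
    side: str = "total"  # CM_nonCM only
    features: FeatureOptions = field(default_factory=FeatureOptions)
    model: ModelConfig = field(default_factory=ModelConfig)
    k_folds: int = 10
    cv_seed: int = 0

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise DesignError(f"unknown design {self.design!r}")
        if self.side not in SIDE_CHOICES:
            raise DesignError(f"side must be one of {SIDE_CHOICES}")
        if self.design == "CM_control" and self.side != "total":
            raise DesignError("side restriction is only valid for CM_nonCM")

    def hash(self) -> str:
        payload = json.dumps(
            {"design": self.design, "side": self.side,
             "features": asdict(self.features), "model": asdict(self.model),
             "k_folds": self.k_folds, "cv_seed": self.cv_seed},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class BoneResult:
    finger: str
    bone: str  # display-grid label
    auc: float


@dataclass
class ExperimentReport:
    """Metrics plus provenance for one experiment (and optional ablation)."""

    design: str
    side: str
    metrics: MetricsReport
    n_samples: int
    n_participants: int
    per_bone: Optional[list[BoneResult]] = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"design": self.design, "side": self.side,
               "metrics": self.metrics.to_dict(),
               "n_samples": self.n_samples,
               "n_participants": self.n_participants,
               "provenance": self.provenance}
        if self.per_bone is not None:
            out["per_bone"] = [{"finger": r.finger, "bone": r.bone,
                                "auc": round(r.auc, 2)} for r in self.per_bone]
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def build_samples(recordings: Sequence[Recording], design: str,
                  side: str = "total",
                  features: FeatureOptions = FeatureOptions(),
                  ) -> list[SampleVector]:
    """Featurize and combine recordings into design-specific samples.

    Group filtering is exact: CM/control never touches CTS recordings,
    and side-restricted CM/non-CM runs never touch the other side.
    """
    if design not in DESIGNS:
        raise DesignError(f"unknown design {design!r}")
    wanted_groups = {"CM", "control"} if design == "CM_control" \
        else {"CM", "CTS", "control"}
    selected = [r for r in recordings if r.group in wanted_groups]
    if design == "CM_nonCM" and side != "total":
        selected = [r for r in selected if r.side == side]

    present = {r.group for r in selected}
    if "CM" not in present or not (present - {"CM"}):
        raise DesignError(
            f"design {design} needs CM plus at least one comparison group; "
            f"found {sorted(present)}")

    buckets: dict[tuple, list] = {}
    for rec in selected:
        key = (rec.participant_id,) if design == "CM_control" \
            else (rec.participant_id, rec.side)
        buckets.setdefault(key, []).append(featurize_trial(rec, features))
    return [combine_trials(vectors, design)
            for _, vectors in sorted(buckets.items())]


def _sample_matrix(samples: Sequence[SampleVector]):
    X = np.stack([s.values for s in samples])
    y = np.array([1 if s.group == "CM" else 0 for s in samples], dtype=int)
    groups = np.array([s.participant_id for s in samples])
    return X, y, groups


def run_experiment(config: ExperimentConfig,
                   recordings: Sequence[Recording]) -> ExperimentReport:
    """Featurize -> combine -> grouped CV -> ROC/AUC/optimal cutoff."""
    samples = build_samples(recordings, config.design, config.side,
                            config.features)
    X, y, groups = _sample_matrix(samples)
    scores = cross_validate(X, y, groups, config.model,
                            k=config.k_folds, seed=config.cv_seed)
    metrics = evaluate_scores(scores, y)
    return ExperimentReport(
        design=config.design, side=config.side, metrics=metrics,
        n_samples=len(samples),
        n_participants=int(np.unique(groups).size),
        provenance={"config_hash": config.hash(), "cv_seed": config.cv_seed,
                    "version": __version__})


def per_bone_experiment(config: ExperimentConfig,
                        recordings: Sequence[Recording]) -> list[BoneResult]:
    """CM/control cross-validated AUC restricted to each of the 20 bones.

    Samples and fold assignments are identical across bones (same CV
    seed), so rows differ only in which features the model may use.
    Rows are ordered finger-major (thumb -> little), bone tip -> palm,
    labeled with the display-grid bone names.
    """
    if config.design != "CM_control":
        raise DesignError("the per-bone ablation is defined for CM_control")
    samples = build_samples(recordings, config.design, config.side,
                            config.features)
    X, y, groups = _sample_matrix(samples)
    n_blocks = X.shape[1] // FEATURE_DIM
    results = []
    for finger, bone in all_bones():
        idx = bone_feature_indices(finger, bone)
        tiled = np.concatenate([idx + b * FEATURE_DIM for b in range(n_blocks)])
        scores = cross_validate(X[:, tiled], y, groups, config.model,
                                k=config.k_folds, seed=config.cv_seed)
        results.append(BoneResult(finger=finger, bone=bone,
                                  auc=auc_value(scores, y)))
    return results


def run_full_analysis(recordings: Sequence[Recording],
                      model: ModelConfig = ModelConfig(),
                      k_folds: int = 10, cv_seed: int = 0,
                      ablation: bool = True) -> dict:
    """All experiment designs (and optionally the bone ablation) at once."""
    reports = {}
    cm_control = ExperimentConfig(design="CM_control", model=model,
                                  k_folds=k_folds, cv_seed=cv_seed)
    reports["CM_control"] = run_experiment(cm_control, recordings)
    if ablation:
        reports["CM_control"].per_bone = per_bone_experiment(cm_control,
                                                             recordings)
    for side in SIDE_CHOICES:
        cfg = ExperimentConfig(design="CM_nonCM", side=side, model=model,
                               k_folds=k_folds, cv_seed=cv_seed)
        reports[f"CM_nonCM_{side}"] = run_experiment(cfg, recordings)
    return reports
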