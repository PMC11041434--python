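"""Short-segment spectral featurization of 229-channel recordings.

Each channel waveform is cut into 15 segments of 64 frames with evenly
spaced (possibly overlapping) start offsets, each segment is linearly
detrended, tapered with a symmetric 64-point Hanning window, transformed
with a 64-point FFT, and reduced to the magnitudes of its 16 lowest
frequency bins. Assembling all channels gives a fixed 54,960-dimensional
feature vector per trial (229 channels x 15 segments x 16 bins)
regardless of trial length. Because segmentation adapts to the trial
length, hands that need more frames for their 20 grip-release cycles are
featurized on exactly the same grid as fast hands.

Feature vectors from a participant's trials are concatenated into the
sample vectors that the classifiers consume: all four trials (2 sides x
2 trials) for the participant-level CM/control design, or the two trials
of one hand for the hand-level CM/non-CM design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.signal

from .errors import (
    DesignError,
    InsufficientLengthError,
    RecordingValidationError,
    SchemaError,
)
from .recording_io import (
    BONE_CATEGORIES,
    DISPLAY_BONES,
    FINGERS,
    N_PARAMETERS,
    Recording,
    display_bone,
    find_parameters,
    parameter_index,
    resolve_display_bone,
    validate_recording,
)

N_SEGMENTS = 15
SEGMENT_LENGTH = 64
N_BINS = 16
#: Per-trial feature dimensionality: 229 x 15 x 16.
FEATURE_DIM = N_PARAMETERS * N_SEGMENTS * N_BINS  # 54,960

#: Symmetric Hanning window w[t] = 0.5 (1 - cos(2 pi t / 63)), t = 0..63.
WINDOW = np.hanning(SEGMENT_LENGTH)

_BLOCK = N_SEGMENTS * N_BINS  # features per channel


@dataclass(frozen=True)
class FeatureOptions:
    """Dialect switches for the spectral export.

    include_dc:
        If True (default) the 16 exported bins are DFT bins 0-15; after
        detrending, bin 0 carries only the window-weighted residual mean,
        so including it is harmless. If False, bins 1-16 are exported.
    power:
        Export squared magnitudes instead of magnitudes.
    """

    include_dc: bool = True
    power: bool = False


DEFAULT_OPTIONS = FeatureOptions()


@dataclass(frozen=True)
class SegmentationPlan:
    """Start offsets of the 15 overlapping 64-frame segments."""

    n_frames: int
    offsets: tuple[int, ...]

    def __post_init__(self):
        if len(self.offsets) != N_SEGMENTS:
            raise SchemaError(f"expected {N_SEGMENTS} offsets")


def plan_segments(n_frames: int) -> SegmentationPlan:
    """Evenly spaced segment offsets: offsets[i] = round(i (T-64) / 14).

    The first segment starts at frame 0 and the last ends at the final
    frame; consecutive segments overlap whenever T < 64 * 15. At the
    degenerate minimum T = 64 all 15 segments coincide.
    """
    if n_frames < SEGMENT_LENGTH:
        raise InsufficientLengthError(
            f"need at least {SEGMENT_LENGTH} frames, got {n_frames}")
    span = n_frames - SEGMENT_LENGTH
    offsets = tuple(int(np.floor(i * span / (N_SEGMENTS - 1) + 0.5))
                    for i in range(N_SEGMENTS))
    return SegmentationPlan(n_frames=n_frames, offsets=offsets)


def detrend_segment(segment: np.ndarray) -> np.ndarray:
    """Residual of the least-squares affine fit a + b t over one segment."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.shape != (SEGMENT_LENGTH,):
        raise SchemaError(f"segment must have length {SEGMENT_LENGTH}")
    return scipy.signal.detrend(segment, type="linear")


def segment_spectrum(segment: np.ndarray,
                     options: FeatureOptions = DEFAULT_OPTIONS) -> np.ndarray:
    """Magnitudes of the 16 lowest DFT bins of a Hanning-windowed segment.

    The caller supplies an already-detrended segment (featurize_trial
    enforces the detrend -> window -> transform order). The forward DFT
    is unnormalized; any fixed normalization is absorbed by downstream
    feature standardization.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.shape != (SEGMENT_LENGTH,):
        raise SchemaError(f"segment must have length {SEGMENT_LENGTH}")
    spec = np.abs(np.fft.rfft(segment * WINDOW))
    k0 = 0 if options.include_dc else 1
    out = spec[k0:k0 + N_BINS]
    return out ** 2 if options.power else out


def feature_position(parameter: int, segment: int, bin: int) -> int:
    """Bijective (parameter, segment, bin) -> flat feature position."""
    if not (0 <= parameter < N_PARAMETERS and 0 <= segment < N_SEGMENTS
            and 0 <= bin < N_BINS):
        raise IndexError(f"triple out of range: {(parameter, segment, bin)}")
    return (parameter * N_SEGMENTS + segment) * N_BINS + bin


def feature_triple(position: int) -> tuple[int, int, int]:
    """Inverse of :func:`feature_position`."""
    if not 0 <= position < FEATURE_DIM:
        raise IndexError(f"position out of range: {position}")
    parameter, rest = divmod(position, _BLOCK)
    segment, bin = divmod(rest, N_BINS)
    return parameter, segment, bin


@dataclass(frozen=True)
class FeatureVector:
    """54,960-dimensional spectral features of one trial."""

    values: np.ndarray
    participant_id: str
    group: str
    side: str
    trial: int

    def __post_init__(self):
        if self.values.shape != (FEATURE_DIM,):
            raise SchemaError(
                f"feature vector must have length {FEATURE_DIM}, "
                f"got {self.values.shape}")


def featurize_trial(rec: Recording,
                    options: FeatureOptions = DEFAULT_OPTIONS) -> FeatureVector:
    """Full spectral featurization of one recording.

    For every channel: segment per :func:`plan_segments`, then per
    segment detrend -> Hanning window -> 64-point FFT -> lowest 16 bin
    magnitudes. Features are assembled channel-major, then segment, then
    bin, matching :func:`feature_position`.
    """
    violations = validate_recording(rec)
    if violations:
        raise RecordingValidationError("; ".join(violations))
    plan = plan_segments(rec.n_frames)
    starts = np.asarray(plan.offsets)
    # (segments, 64, channels) -> (channels, segments, 64)
    segs = rec.frames[starts[:, None] + np.arange(SEGMENT_LENGTH)[None, :], :]
    segs = np.ascontiguousarray(np.moveaxis(segs, 2, 0))
    detrended = scipy.signal.detrend(segs, axis=2, type="linear")
    spec = np.abs(np.fft.rfft(detrended * WINDOW, axis=2))
    k0 = 0 if options.include_dc else 1
    values = spec[:, :, k0:k0 + N_BINS]
    if options.power:
        values = values ** 2
    return FeatureVector(values=values.reshape(-1),
                         participant_id=rec.participant_id, group=rec.group,
                         side=rec.side, trial=rec.trial)


@dataclass(frozen=True)
class SampleVector:
    """Concatenated trial features forming one classification sample.

    ``design`` is ``"CM_control"`` (participant-level: 2 sides x 2
    trials, length 219,840) or ``"CM_nonCM"`` (hand-level: 2 trials of
    one side, length 109,920). Blocks follow (side: right, left) x
    (trial: 1, 2) order.
    """

    values: np.ndarray
    design: str
    participant_id: str
    group: str
    sides: tuple[str, ...]
    trials: tuple[int, ...]

    @property
    def n_blocks(self) -> int:
        return self.values.size // FEATURE_DIM


DESIGNS = ("CM_control", "CM_nonCM")
_SIDE_ORDER = {"right": 0, "left": 1}


def combine_trials(vectors: Sequence[FeatureVector], design: str) -> SampleVector:
    """Concatenate a participant's trial features into one sample.

    CM_control requires the four vectors of one participant (both sides,
    trials 1 and 2); CM_nonCM requires the two trials of a single hand.
    Concatenation order is fixed: (right, 1), (right, 2), (left, 1),
    (left, 2) — restricted to the vectors present.
    """
    if design not in DESIGNS:
        raise DesignError(f"unknown design {design!r}; expected one of {DESIGNS}")
    vectors = list(vectors)
    pids = {v.participant_id for v in vectors}
    if len(pids) != 1:
        raise DesignError(f"vectors span multiple participants: {sorted(pids)}")
    keys = sorted((v.side, v.trial) for v in vectors)
    if design == "CM_control":
        expected = sorted((s, t) for s in ("right", "left") for t in (1, 2))
        if keys != expected:
            raise DesignError(
                f"CM_control needs one vector per (side, trial) in "
                f"{{right,left}} x {{1,2}}; got {keys}")
    else:
        sides = {v.side for v in vectors}
        if len(vectors) != 2 or len(sides) != 1 or \
                sorted(v.trial for v in vectors) != [1, 2]:
            raise DesignError(
                f"CM_nonCM needs trials 1 and 2 of a single hand; got {keys}")
    ordered = sorted(vectors, key=lambda v: (_SIDE_ORDER[v.side], v.trial))
    return SampleVector(
        values=np.concatenate([v.values for v in ordered]),
        design=design,
        participant_id=vectors[0].participant_id,
        group=vectors[0].group,
        sides=tuple(v.side for v in ordered),
        trials=tuple(v.trial for v in ordered))


# ---------------------------------------------------------------------------
# Per-bone feature subsetting
# ---------------------------------------------------------------------------

def bone_parameter_indices(finger: str, bone: str) -> np.ndarray:
    """Schema indices of the 9 channels belonging to one bone.

    ``bone`` is a display-grid label (as used when reporting per-bone
    results); for the thumb it is resolved to the anatomical bone first.
    Each bone owns 3 distal-end-position, 3 center-position and 3
    direction channels.
    """
    anatomical = resolve_display_bone(finger, bone)
    idx = [parameter_index(d.name)
           for cat in BONE_CATEGORIES
           for d in find_parameters(category=cat, finger=finger, bone=anatomical)]
    return np.asarray(sorted(idx), dtype=np.intp)


def bone_feature_indices(finger: str, bone: str) -> np.ndarray:
    """Flat feature positions (within one trial vector) of one bone.

    9 channels x 15 segments x 16 bins = 2,160 positions, in ascending
    order (so the relative order of retained features is preserved).
    """
    params = bone_parameter_indices(finger, bone)
    return (params[:, None] * _BLOCK + np.arange(_BLOCK)[None, :]).reshape(-1)


def bone_feature_subset(vector: FeatureVector | SampleVector,
                        finger: str, bone: str) -> np.ndarray:
    """Restrict a trial or sample vector to one bone's features.

    For a multi-trial :class:`SampleVector` the restriction is applied
    blockwise, yielding 2,160 features per constituent trial.
    """
    idx = bone_feature_indices(finger, bone)
    values = vector.values
    if values.size == FEATURE_DIM:
        return values[idx]
    if values.size % FEATURE_DIM != 0:
        raise SchemaError(
            f"vector length {values.size} is not a multiple of {FEATURE_DIM}")
    n_blocks = values.size // FEATURE_DIM
    tiled = np.concatenate([idx + b * FEATURE_DIM for b in range(n_blocks)])
    return values[tiled]


def all_bones() -> list[tuple[str, str]]:
    """The 20 (finger, display bone) pairs in finger-major report order."""
    return [(f, b) for f in FINGERS for b in DISPLAY_BONES]
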