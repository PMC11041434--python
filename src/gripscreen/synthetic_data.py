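"""Synthetic grip-and-release cohorts from a forward-kinematic hand model.

No public data set of sensor-tracked grip-and-release trials exists, so
this module generates labeled cohorts whose recordings have the same
schema and the statistical structure the downstream analysis assumes:
each trial is ~20 rapid open/close cycles of a pronated hand tracked at
60 fps, and diagnosis groups differ in cycle rate, amplitude, timing
regularity, and (for carpal tunnel syndrome) thumb mobility.

The hand is modeled as five planar kinematic chains rooted at the wrist.
Each finger f has a fixed "extended" unit direction e_f fanned in the
horizontal plane; flexion rotates each successive bone of the chain
about the common horizontal axis of that finger's sagittal plane, so a
bone whose cumulative flexion is theta points along
``cos(theta) * e_f - sin(theta) * yhat`` (y is vertical, up from the
sensor). Grip cycles drive every joint with a raised-cosine flexion
profile whose per-cycle period is jittered; class differences enter only
through :class:`ClassProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import DomainError, SchemaError
from .recording_io import (
    AXES,
    FINGERS,
    FRAME_RATE,
    GROUPS,
    N_PARAMETERS,
    CohortManifest,
    ManifestEntry,
    Recording,
    anatomical_bones,
    parameter_index,
    parameter_indices,
)

#: Chain order of bones, palm -> tip (the reverse of schema order).
_CHAINS = {f: tuple(reversed(anatomical_bones(f))) for f in FINGERS}

#: Maximum flexion (radians) per joint, chain order palm -> tip, at
#: amplitude 1. The root joint barely moves; interphalangeal joints
#: dominate, as in a natural fist.
_FLEXION_LIMITS = {
    "thumb": np.array([0.10, 0.55, 0.95, 1.15]),
    "index": np.array([0.15, 1.50, 1.60, 1.00]),
    "middle": np.array([0.15, 1.50, 1.60, 1.00]),
    "ring": np.array([0.15, 1.50, 1.60, 1.00]),
    "little": np.array([0.15, 1.50, 1.60, 1.00]),
}

#: Horizontal fan angle (radians) of each finger's extended direction.
_AZIMUTH = {"thumb": -0.90, "index": -0.18, "middle": 0.0,
            "ring": 0.17, "little": 0.33}

#: A finger whose mean non-root flexion is below this (radians) counts
#: as extended for the extended-finger-count channel.
EXTENDED_FLEXION_THRESHOLD = 0.35

_YHAT = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class HandGeometry:
    """Bone segment lengths (mm) and the fixed wrist position.

    ``lengths`` maps all 20 (finger, anatomical bone) pairs to strictly
    positive lengths. The wrist sits 100 mm above the sensor origin by
    default, matching the measurement protocol.
    """

    lengths: Mapping[tuple[str, str], float]
    palm_width: float = 85.0
    palm_length: float = 95.0
    wrist_position: tuple[float, float, float] = (0.0, 100.0, 0.0)

    def __post_init__(self):
        expected = {(f, b) for f in FINGERS for b in anatomical_bones(f)}
        got = set(self.lengths)
        if got != expected:
            raise SchemaError(
                f"geometry must cover exactly the 20 (finger, bone) segments; "
                f"missing {sorted(expected - got)}, extra {sorted(got - expected)}")
        for key, L in self.lengths.items():
            if not L > 0:
                raise DomainError(f"non-positive length {L} for segment {key}")
        if not (self.palm_width > 0 and self.palm_length > 0):
            raise DomainError("palm dimensions must be positive")


_DEFAULT_LENGTHS = {
    # published average adult segment lengths, mm (palm -> tip per chain)
    ("thumb", "carpal"): 25.0,
    ("thumb", "metacarpus"): 45.0,
    ("thumb", "proximal_phalanx"): 32.0,
    ("thumb", "distal_phalanx"): 22.0,
    ("index", "metacarpus"): 68.0,
    ("index", "proximal_phalanx"): 40.0,
    ("index", "middle_phalanx"): 24.0,
    ("index", "distal_phalanx"): 18.0,
    ("middle", "metacarpus"): 65.0,
    ("middle", "proximal_phalanx"): 45.0,
    ("middle", "middle_phalanx"): 28.0,
    ("middle", "distal_phalanx"): 18.0,
    ("ring", "metacarpus"): 58.0,
    ("ring", "proximal_phalanx"): 42.0,
    ("ring", "middle_phalanx"): 27.0,
    ("ring", "distal_phalanx"): 18.0,
    ("little", "metacarpus"): 54.0,
    ("little", "proximal_phalanx"): 33.0,
    ("little", "middle_phalanx"): 19.0,
    ("little", "distal_phalanx"): 16.0,
}


def default_geometry(scale: float = 1.0) -> HandGeometry:
    """Average adult hand geometry, optionally scaled isotropically."""
    if not scale > 0:
        raise DomainError(f"scale must be positive, got {scale}")
    return HandGeometry(lengths={k: v * scale for k, v in _DEFAULT_LENGTHS.items()},
                        palm_width=85.0 * scale, palm_length=95.0 * scale)


@dataclass(frozen=True)
class ClassProfile:
    """Generative kinematics of one diagnosis group.

    cycle_rate_mean/sd:
        Population mean and between-participant SD of the grip-release
        rate (Hz).
    amplitude_scale:
        Fraction of full flexion reached at the bottom of each grip.
    jitter:
        Cycle-to-cycle coefficient of variation of the period
        (irregularity of the rhythm).
    thumb_impairment:
        Multiplicative amplitude factor on thumb flexion in (0, 1];
        below 1 models the thenar motor deficit of carpal tunnel
        syndrome.
    sensor_noise_sd:
        Additive Gaussian noise (mm) on every position channel.
    n_cycles:
        Grip-release repetitions per trial (the protocol asks for 20).
    """

    cycle_rate_mean: float
    cycle_rate_sd: float = 0.2
    amplitude_scale: float = 1.0
    jitter: float = 0.05
    thumb_impairment: float = 1.0
    sensor_noise_sd: float = 0.5
    n_cycles: int = 20

    def __post_init__(self):
        if not self.cycle_rate_mean > 0:
            raise DomainError("cycle_rate_mean must be positive")
        if not 0 < self.amplitude_scale <= 1:
            raise DomainError("amplitude_scale must be in (0, 1]")
        if not 0 < self.thumb_impairment <= 1:
            raise DomainError("thumb_impairment must be in (0, 1]")
        if self.jitter < 0 or self.cycle_rate_sd < 0 or self.sensor_noise_sd < 0:
            raise DomainError("jitter, cycle_rate_sd, sensor_noise_sd must be >= 0")
        if self.n_cycles < 1:
            raise DomainError("n_cycles must be >= 1")


#: Default group profiles: myelopathy hands are slow, low-amplitude and
#: irregular; CTS hands move like controls except for reduced thumb
#: excursion; controls are fast and regular.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "CM": ClassProfile(cycle_rate_mean=1.5, cycle_rate_sd=0.2,
                       amplitude_scale=0.7, jitter=0.20),
    "CTS": ClassProfile(cycle_rate_mean=2.3, cycle_rate_sd=0.2,
                        amplitude_scale=1.0, jitter=0.05, thumb_impairment=0.6),
    "control": ClassProfile(cycle_rate_mean=2.3, cycle_rate_sd=0.2,
                            amplitude_scale=1.0, jitter=0.05),
}


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"CM": 10, "CTS": 10, "control": 10})
    profiles: Mapping[str, ClassProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    frame_rate: float = FRAME_RATE
    geometry_scale_range: float = 0.05  # per-participant +-5% hand size
    seed: int = 0

    def __post_init__(self):
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise SchemaError(f"unknown groups {sorted(unknown)}")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise DomainError(f"n_per_group[{g!r}] must be >= 1")
            if g not in self.profiles:
                raise SchemaError(f"no profile for group {g!r}")


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def _finger_direction_basis(finger: str) -> np.ndarray:
    a = _AZIMUTH[finger]
    return np.array([np.sin(a), 0.0, np.cos(a)])


def _fk_frames(joint_angles: np.ndarray, geometry: HandGeometry) -> np.ndarray:
    """Vectorized forward kinematics: (T, 5, 4) flexion angles -> (T, 229).

    Fingertip-speed channels are left zero; the caller fills them from
    successive fingertip positions (so they reflect any added noise).
    """
    angles = np.asarray(joint_angles, dtype=np.float64)
    if angles.ndim == 2:
        angles = angles[None]
    T = angles.shape[0]
    if angles.shape != (T, 5, 4):
        raise DomainError(f"joint_angles must have shape (T, 5, 4), got {angles.shape}")
    if np.any(angles < 0) or np.any(angles > np.pi):
        raise DomainError("flexion angles must lie within [0, pi]")

    out = np.zeros((T, N_PARAMETERS))
    wrist = np.asarray(geometry.wrist_position, dtype=np.float64)

    out[:, parameter_indices(category="wrist_position")] = wrist
    out[:, parameter_indices(category="forearm_direction")] = (0.0, 0.0, -1.0)

    mean_flexion = angles[:, :, 1:].mean(axis=2)  # (T, 5), root joint excluded
    out[:, parameter_index("extended_fingers")] = (
        mean_flexion < EXTENDED_FLEXION_THRESHOLD).sum(axis=1)
    # mild reflex wrist extension during grip
    out[:, parameter_index("wrist_extension_angle")] = \
        5.0 + 12.0 * angles.mean(axis=(1, 2))

    middle_distal_end = None
    for fi, finger in enumerate(FINGERS):
        e = _finger_direction_basis(finger)
        chain = _CHAINS[finger]
        L = np.array([geometry.lengths[(finger, b)] for b in chain])
        cum = np.cumsum(angles[:, fi, :], axis=1)          # (T, 4)
        dirs = (np.cos(cum)[..., None] * e
                - np.sin(cum)[..., None] * _YHAT)          # (T, 4, 3) unit
        seg = dirs * L[None, :, None]
        distal = wrist + np.cumsum(seg, axis=1)            # (T, 4, 3)
        center = distal - 0.5 * seg
        if finger == "middle":
            middle_distal_end = distal[:, 0]               # metacarpus head

        tip = distal[:, -1]
        tip_dir = dirs[:, -1]
        for ai, ax in enumerate(AXES):
            out[:, parameter_index(f"fingertip_position_{finger}_{ax}")] = tip[:, ai]
            out[:, parameter_index(f"fingertip_direction_{finger}_{ax}")] = tip_dir[:, ai]
        for ci, bone in enumerate(chain):
            for ai, ax in enumerate(AXES):
                out[:, parameter_index(f"bone_distal_position_{finger}_{bone}_{ax}")] = distal[:, ci, ai]
                out[:, parameter_index(f"bone_center_position_{finger}_{bone}_{ax}")] = center[:, ci, ai]
                out[:, parameter_index(f"bone_direction_{finger}_{bone}_{ax}")] = dirs[:, ci, ai]

    out[:, parameter_indices(category="palm_position")] = \
        0.5 * (wrist + middle_distal_end)
    # palm normal: perpendicular to the middle metacarpus within its
    # sagittal plane, pointing down toward the sensor when pronated
    th0 = angles[:, 2, 0]
    e_mid = _finger_direction_basis("middle")
    out[:, parameter_indices(category="palm_direction")] = (
        -np.sin(th0)[:, None] * e_mid - np.cos(th0)[:, None] * _YHAT)
    return out


def forward_kinematics(joint_angles: np.ndarray, geometry: HandGeometry) -> np.ndarray:
    """Map one (5, 4) flexion-angle frame to a single 229-value frame.

    ``joint_angles[f, j]`` is the flexion (radians, in [0, pi]) at joint
    j of finger f, ordered palm -> tip along the chain. Fingertip-speed
    channels are zero (they are defined from successive frames).
    """
    angles = np.asarray(joint_angles, dtype=np.float64)
    if angles.shape != (5, 4):
        raise DomainError(f"joint_angles must have shape (5, 4), got {angles.shape}")
    return _fk_frames(angles[None], geometry)[0]


# ---------------------------------------------------------------------------
# Trial and cohort simulation
# ---------------------------------------------------------------------------

def _flexion_trajectory(profile: ClassProfile, rate: float, frame_rate: float,
                        rng: np.random.Generator) -> np.ndarray:
    """(T, 5, 4) joint-angle trajectory of one trial."""
    mean_period = 1.0 / rate
    periods = rng.normal(mean_period, profile.jitter * mean_period,
                         size=profile.n_cycles)
    periods = np.clip(periods, 0.3 * mean_period, 3.0 * mean_period)
    ends = np.cumsum(periods)
    starts = ends - periods
    T = max(int(np.ceil(ends[-1] * frame_rate)), 64)
    t = np.arange(T) / frame_rate
    idx = np.clip(np.searchsorted(ends, t, side="right"), 0, profile.n_cycles - 1)
    phase = np.clip((t - starts[idx]) / periods[idx], 0.0, 1.0)
    s = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))  # raised-cosine open<->close

    amp = np.full(5, profile.amplitude_scale)
    amp[FINGERS.index("thumb")] *= profile.thumb_impairment
    limits = np.stack([_FLEXION_LIMITS[f] for f in FINGERS])  # (5, 4)
    return s[:, None, None] * (amp[:, None] * limits)[None]


def simulate_recording(profile: ClassProfile, geometry: HandGeometry,
                       participant_id: str, group: str, side: str, trial: int,
                       seed: int, frame_rate: float = FRAME_RATE) -> Recording:
    """Simulate one grip-and-release trial.

    The trial lasts ``n_cycles`` jittered cycles at a rate drawn from the
    profile, so slower hands produce longer recordings. Sensor noise is
    added to position channels only; fingertip-speed channels are then
    the per-frame displacement magnitude of the (noisy) fingertip, in
    mm/frame. Bit-identical output for identical arguments.
    """
    rng = np.random.default_rng(seed)
    rate = max(0.4, rng.normal(profile.cycle_rate_mean, profile.cycle_rate_sd))
    angles = _flexion_trajectory(profile, rate, frame_rate, rng)
    frames = _fk_frames(angles, geometry)

    if profile.sensor_noise_sd > 0:
        pos_idx = np.concatenate([
            parameter_indices(category=c) for c in
            ("palm_position", "wrist_position", "fingertip_position",
             "bone_distal_position", "bone_center_position")])
        frames[:, pos_idx] += rng.normal(
            0.0, profile.sensor_noise_sd, size=(frames.shape[0], pos_idx.size))

    for finger in FINGERS:
        tip_cols = parameter_indices(category="fingertip_position", finger=finger)
        tip = frames[:, tip_cols]
        speed = np.zeros(frames.shape[0])
        speed[1:] = np.linalg.norm(np.diff(tip, axis=0), axis=1)
        frames[:, parameter_index(f"fingertip_speed_{finger}")] = speed

    return Recording(participant_id=participant_id, group=group, side=side,
                     trial=trial, frames=frames, frame_rate=frame_rate)


def simulate_cohort(config: SimConfig) -> tuple[CohortManifest, list[Recording]]:
    """Simulate a full cohort: 2 sides x 2 trials per participant.

    Per participant, hand size is scaled uniformly within +-5% and a
    personal cycle rate is drawn from the group profile. For CTS
    participants one side is designated as affected; only that hand
    receives the profile's thumb impairment. All randomness flows from
    ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    manifest_entries: list[ManifestEntry] = []
    recordings: list[Recording] = []
    for group in GROUPS:
        if group not in config.n_per_group:
            continue
        profile = config.profiles[group]
        for i in range(config.n_per_group[group]):
            (child,) = root.spawn(1)
            rng = np.random.default_rng(child)
            pid = f"{group}{i + 1:03d}"
            scale = 1.0 + config.geometry_scale_range * rng.uniform(-1.0, 1.0)
            geometry = default_geometry(scale)
            personal_rate = max(0.4, rng.normal(profile.cycle_rate_mean,
                                                profile.cycle_rate_sd))
            affected = rng.choice(SIDES_ARR) if group == "CTS" else None
            for side in ("right", "left"):
                impair = profile.thumb_impairment \
                    if (affected is None or side == affected) else 1.0
                for trial in (1, 2):
                    rec_profile = replace(profile,
                                          cycle_rate_mean=personal_rate,
                                          cycle_rate_sd=0.03 * personal_rate,
                                          thumb_impairment=impair)
                    rec_seed = int(rng.integers(0, 2**31))
                    rec = simulate_recording(rec_profile, geometry, pid, group,
                                             side, trial, rec_seed,
                                             config.frame_rate)
                    recordings.append(rec)
                    manifest_entries.append(
                        ManifestEntry(pid, group, side, trial, ""))
    return CohortManifest(manifest_entries), recordings


SIDES_ARR = np.array(["right", "left"])
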