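"""Canonical 229-channel recording schema, file I/O, and validation.

A noncontact infrared hand-tracking sensor placed below a pronated hand
reports, at 60 frames per second, a fixed set of 229 kinematic channels:
a count of extended fingers, palm and wrist position/direction, wrist
extension angle, forearm direction, and per-finger fingertip speed,
fingertip position/direction, plus position (distal end and center) and
direction for each of the 20 finger bones (5 fingers x 4 bones).

This module defines the canonical, stable ordering of those channels,
reads and writes trial recordings (CSV with a JSON metadata sidecar, or
single-object JSON-Lines), and validates recordings and cohort manifests.

Thumb bone naming: anatomically the thumb has no middle phalanx, so its
four tracked segments are distal phalanx, proximal phalanx, metacarpus
and carpal. Descriptors store the anatomical names; the conventional
display labels used for the other fingers (distal/middle/proximal
phalanx, metacarpus) are exposed through :func:`resolve_display_bone`
and :func:`display_bone` so that per-bone results can be reported on a
uniform 5x4 grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

FINGERS = ("thumb", "index", "middle", "ring", "little")
AXES = ("x", "y", "z")
GROUPS = ("CM", "CTS", "control")
SIDES = ("right", "left")
FRAME_RATE = 60.0
N_PARAMETERS = 229

#: Display-grid bone labels, identical for every finger (tip -> palm).
DISPLAY_BONES = ("distal_phalanx", "middle_phalanx", "proximal_phalanx", "metacarpus")

#: Anatomical thumb bones in the canonical (tip -> palm) order.
THUMB_BONES = ("distal_phalanx", "proximal_phalanx", "metacarpus", "carpal")

_THUMB_DISPLAY_TO_ANATOMICAL = dict(zip(DISPLAY_BONES, THUMB_BONES))
_THUMB_ANATOMICAL_TO_DISPLAY = dict(zip(THUMB_BONES, DISPLAY_BONES))

#: The 12 channel categories in canonical order, with their channel counts.
CATEGORY_COUNTS = {
    "extended_fingers": 1,
    "palm_position": 3,
    "palm_direction": 3,
    "wrist_extension_angle": 1,
    "wrist_position": 3,
    "forearm_direction": 3,
    "fingertip_speed": 5,
    "fingertip_position": 15,
    "fingertip_direction": 15,
    "bone_distal_position": 60,
    "bone_center_position": 60,
    "bone_direction": 60,
}

BONE_CATEGORIES = ("bone_distal_position", "bone_center_position", "bone_direction")

_CATEGORY_UNITS = {
    "extended_fingers": "count",
    "palm_position": "mm",
    "palm_direction": "unit-vector component",
    "wrist_extension_angle": "degrees",
    "wrist_position": "mm",
    "forearm_direction": "unit-vector component",
    "fingertip_speed": "mm/frame",
    "fingertip_position": "mm",
    "fingertip_direction": "unit-vector component",
    "bone_distal_position": "mm",
    "bone_center_position": "mm",
    "bone_direction": "unit-vector component",
}


def anatomical_bones(finger: str) -> tuple[str, ...]:
    """Anatomical bone names of one finger in canonical (tip -> palm) order."""
    return THUMB_BONES if finger == "thumb" else DISPLAY_BONES


def resolve_display_bone(finger: str, bone: str) -> str:
    """Map a display-grid bone label to the anatomical bone it denotes.

    For the thumb, ``middle_phalanx`` denotes the anatomical proximal
    phalanx, ``proximal_phalanx`` the metacarpus, and ``metacarpus`` the
    carpal segment; other fingers map identically.
    """
    if finger not in FINGERS:
        raise SchemaError(f"unknown finger {finger!r}")
    if bone not in DISPLAY_BONES:
        raise SchemaError(f"unknown bone label {bone!r}; expected one of {DISPLAY_BONES}")
    return _THUMB_DISPLAY_TO_ANATOMICAL[bone] if finger == "thumb" else bone


def display_bone(finger: str, anatomical: str) -> str:
    """Inverse of :func:`resolve_display_bone`."""
    if finger == "thumb":
        return _THUMB_ANATOMICAL_TO_DISPLAY[anatomical]
    return anatomical


@dataclass(frozen=True)
class ParameterDescriptor:
    """One of the 229 named waveform channels."""

    name: str
    category: str
    finger: Optional[str] = None
    bone: Optional[str] = None  # anatomical name
    axis: Optional[str] = None
    units: str = "mm"

    @property
    def index(self) -> int:
        return parameter_index(self.name)


def _channel_name(category: str, finger: str | None = None,
                  bone: str | None = None, axis: str | None = None) -> str:
    parts = [category]
    if finger is not None:
        parts.append(finger)
    if bone is not None:
        parts.append(bone)
    if axis is not None:
        parts.append(axis)
    return "_".join(parts)


def _build_schema() -> tuple[ParameterDescriptor, ...]:
    out: list[ParameterDescriptor] = []

    def add(category, finger=None, bone=None, axis=None):
        out.append(ParameterDescriptor(
            name=_channel_name(category, finger, bone, axis),
            category=category, finger=finger, bone=bone, axis=axis,
            units=_CATEGORY_UNITS[category]))

    add("extended_fingers")
    for ax in AXES:
        add("palm_position", axis=ax)
    for ax in AXES:
        add("palm_direction", axis=ax)
    add("wrist_extension_angle")
    for ax in AXES:
        add("wrist_position", axis=ax)
    for ax in AXES:
        add("forearm_direction", axis=ax)
    for f in FINGERS:
        add("fingertip_speed", finger=f)
    for f in FINGERS:
        for ax in AXES:
            add("fingertip_position", finger=f, axis=ax)
    for f in FINGERS:
        for ax in AXES:
            add("fingertip_direction", finger=f, axis=ax)
    for category in BONE_CATEGORIES:
        for f in FINGERS:
            for b in anatomical_bones(f):
                for ax in AXES:
                    add(category, finger=f, bone=b, axis=ax)
    assert len(out) == N_PARAMETERS
    return tuple(out)


_SCHEMA = _build_schema()
_NAME_TO_INDEX = {d.name: i for i, d in enumerate(_SCHEMA)}


def parameter_schema() -> tuple[ParameterDescriptor, ...]:
    """The canonical, stable ordering of all 229 channel descriptors.

    Ordering: category rows in the conventional sensor-report order,
    then finger thumb -> little, then bone tip -> palm, then axis x, y, z.
    Identical across calls and runs.
    """
    return _SCHEMA


def schema_names() -> list[str]:
    return [d.name for d in _SCHEMA]


def parameter_index(name: str) -> int:
    try:
        return _NAME_TO_INDEX[name]
    except KeyError:
        raise SchemaError(f"unknown channel name {name!r}") from None


def find_parameters(category: str | None = None, finger: str | None = None,
                    bone: str | None = None, axis: str | None = None,
                    ) -> list[ParameterDescriptor]:
    """Filter the schema by any combination of fields (``bone`` is anatomical)."""
    return [d for d in _SCHEMA
            if (category is None or d.category == category)
            and (finger is None or d.finger == finger)
            and (bone is None or d.bone == bone)
            and (axis is None or d.axis == axis)]


def parameter_indices(**kwargs) -> np.ndarray:
    """Column indices of the channels matching a :func:`find_parameters` filter."""
    return np.array([parameter_index(d.name) for d in find_parameters(**kwargs)],
                    dtype=np.intp)


@dataclass
class Recording:
    """One trial: a T x 229 frame matrix with participant metadata.

    ``frames`` rows are sampled at ``frame_rate`` (60 fps by default) and
    columns follow :func:`parameter_schema` order exactly.
    """

    participant_id: str
    group: str
    side: str
    trial: int
    frames: np.ndarray
    frame_rate: float = FRAME_RATE

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[1] != N_PARAMETERS:
            raise SchemaError(
                f"frames must be a T x {N_PARAMETERS} matrix, got shape {self.frames.shape}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Trial duration in seconds."""
        return self.n_frames / self.frame_rate

    def channel(self, name: str) -> np.ndarray:
        """The waveform of one named channel."""
        return self.frames[:, parameter_index(name)]


def validate_recording(rec: Recording) -> list[str]:
    """Check every recording invariant; return violations (empty iff valid).

    Violations are data, not exceptions: callers that require validity
    raise on a non-empty report.
    """
    violations: list[str] = []
    if rec.frames.shape[1] != N_PARAMETERS:
        violations.append(
            f"expected {N_PARAMETERS} columns, got {rec.frames.shape[1]}")
    if rec.n_frames < 64:
        violations.append(
            f"insufficient frames for 64-frame segmentation (T={rec.n_frames} < 64)")
    if rec.frame_rate <= 0:
        violations.append(f"non-positive frame rate {rec.frame_rate}")
    if rec.group not in GROUPS:
        violations.append(f"unknown group {rec.group!r}; expected one of {GROUPS}")
    if rec.side not in SIDES:
        violations.append(f"unknown side {rec.side!r}; expected one of {SIDES}")
    if not isinstance(rec.trial, (int, np.integer)) or rec.trial < 1:
        violations.append(f"trial index must be an integer >= 1, got {rec.trial!r}")
    bad = ~np.isfinite(rec.frames)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        violations.append(
            f"non-finite value at (row {r}, column {schema_names()[c]})")
    return violations


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

_META_FIELDS = ("participant_id", "group", "side", "trial", "frame_rate")


def _meta_dict(rec: Recording) -> dict:
    return {"participant_id": rec.participant_id, "group": rec.group,
            "side": rec.side, "trial": int(rec.trial),
            "frame_rate": float(rec.frame_rate)}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".jsonl", ".json"):
        return "jsonl"
    raise ParseError(f"cannot infer recording format from {path.name!r}")


def save_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as CSV (+ JSON metadata sidecar) or JSON-Lines.

    Values are written with 17 significant digits so that a save/load
    round trip is bit-exact.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w") as fh:
            fh.write(",".join(schema_names()) + "\n")
            np.savetxt(fh, rec.frames, fmt="%.17g", delimiter=",")
        _sidecar_path(path).write_text(json.dumps(_meta_dict(rec), indent=1))
    elif fmt == "jsonl":
        obj = {"meta": _meta_dict(rec), "columns": schema_names(),
               "frames": rec.frames.tolist()}
        with open(path, "w") as fh:
            fh.write(json.dumps(obj) + "\n")
    else:
        raise ParseError(f"unknown format {fmt!r}")
    return path


def _check_columns(columns: Sequence[str]) -> None:
    expected = schema_names()
    if list(columns) == expected:
        return
    if len(columns) != len(expected):
        raise SchemaError(
            f"expected {len(expected)} columns, got {len(columns)}")
    for i, (got, want) in enumerate(zip(columns, expected)):
        if got != want:
            raise SchemaError(
                f"column {i} is {got!r}, expected {want!r} (misordered or renamed)")


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording written by :func:`save_recording`.

    Raises :class:`SchemaError` on missing/extra/misordered columns and
    :class:`ParseError` (naming the first offending row) on non-numeric
    cells.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.read_csv(path, header=0, dtype=str)
        _check_columns(df.columns)
        try:
            frames = df.to_numpy(dtype=np.float64)
        except ValueError:
            arr = df.to_numpy(dtype=object)
            for i in range(arr.shape[0]):
                for j in range(arr.shape[1]):
                    try:
                        float(arr[i, j])
                    except (TypeError, ValueError):
                        raise ParseError(
                            f"non-numeric value {arr[i, j]!r} at row {i}, "
                            f"column {schema_names()[j]!r}") from None
            raise
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ParseError(f"missing metadata sidecar {sidecar.name!r}")
        meta = json.loads(sidecar.read_text())
    elif fmt == "jsonl":
        with open(path) as fh:
            line = fh.readline()
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as e:
            raise ParseError(f"invalid JSON in {path.name!r}: {e}") from None
        if "columns" in obj:
            _check_columns(obj["columns"])
        meta = obj["meta"]
        try:
            frames = np.asarray(obj["frames"], dtype=np.float64)
        except ValueError as e:
            raise ParseError(f"non-numeric frame data in {path.name!r}: {e}") from None
        if frames.ndim != 2 or frames.shape[1] != N_PARAMETERS:
            raise SchemaError(
                f"expected {N_PARAMETERS} columns, got {frames.shape[1] if frames.ndim == 2 else frames.shape}")
    else:
        raise ParseError(f"unknown format {fmt!r}")
    missing = [k for k in _META_FIELDS if k not in meta]
    if missing:
        raise ParseError(f"metadata missing fields {missing}")
    return Recording(participant_id=str(meta["participant_id"]),
                     group=str(meta["group"]), side=str(meta["side"]),
                     trial=int(meta["trial"]), frames=frames,
                     frame_rate=float(meta["frame_rate"]))


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    participant_id: str
    group: str
    side: str
    trial: int
    path: str = ""


@dataclass
class CohortManifest:
    """Index of a cohort: one row per (participant, side, trial) recording."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[tuple, ManifestEntry] = {}
        group_of: dict[str, str] = {}
        for e in self.entries:
            key = (e.participant_id, e.side, e.trial)
            if key in seen:
                raise SchemaError(f"duplicate manifest entry {key}")
            seen[key] = e
            prev = group_of.setdefault(e.participant_id, e.group)
            if prev != e.group:
                raise SchemaError(
                    f"participant {e.participant_id!r} labeled both {prev!r} and {e.group!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ManifestEntry]:
        return iter(self.entries)

    @property
    def participants(self) -> list[str]:
        out, seen = [], set()
        for e in self.entries:
            if e.participant_id not in seen:
                seen.add(e.participant_id)
                out.append(e.participant_id)
        return out

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        pd.DataFrame([e.__dict__ for e in self.entries]).to_csv(path, index=False)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CohortManifest":
        df = pd.read_csv(path, dtype={"participant_id": str, "group": str,
                                      "side": str, "path": str})
        required = {"participant_id", "group", "side", "trial", "path"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"manifest missing columns {sorted(missing)}")
        entries = [ManifestEntry(r.participant_id, r.group, r.side,
                                 int(r.trial), "" if pd.isna(r.path) else r.path)
                   for r in df.itertuples()]
        return cls(entries)


def save_cohort(recordings: Sequence[Recording], out_dir: str | Path,
                format: str = "csv") -> CohortManifest:
    """Write every recording plus a ``manifest.csv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if format == "csv" else "jsonl"
    entries = []
    for rec in recordings:
        name = f"{rec.participant_id}_{rec.side}_t{rec.trial}.{ext}"
        save_recording(rec, out_dir / name, format)
        entries.append(ManifestEntry(rec.participant_id, rec.group, rec.side,
                                     rec.trial, name))
    manifest = CohortManifest(entries)
    manifest.save(out_dir / "manifest.csv")
    return manifest


def load_cohort(manifest_path: str | Path) -> list[Recording]:
    """Load every recording listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = CohortManifest.load(manifest_path)
    base = manifest_path.parent
    recs = []
    for e in manifest:
        rec = load_recording(base / e.path)
        if (rec.participant_id, rec.group, rec.side, rec.trial) != \
                (e.participant_id, e.group, e.side, e.trial):
            raise SchemaError(
                f"metadata of {e.path!r} disagrees with its manifest row")
        recs.append(rec)
    return recs
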