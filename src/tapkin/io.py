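"""Trajectory data model and on-disk formats.

A trial is stored as a pair of files sharing one stem: ``<stem>.csv`` holds
the long-format coordinates (columns ``frame,keypoint,x,y``; blank cells are
missing samples) and ``<stem>.json`` holds the sidecar metadata (identifiers,
condition, duration class, sampling rate, keypoint order and beep events).
DeepLabCut-style wide exports are trivially convertible to this dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .keypoints import CONDITIONS, DURATION_CLASSES, KEYPOINT_NAMES

__all__ = [
    "TrialEvents",
    "KeypointTrajectory",
    "read_trajectory",
    "write_trajectory",
]


@dataclass(frozen=True)
class TrialEvents:
    """Beep-event frame indices (0-based into the trial's frame axis)."""

    initiation_frame: int
    termination_frame: int
    nominal_duration: float  # seconds (6.71 or 11.14 in the standard design)

    def __post_init__(self) -> None:
        if self.initiation_frame >= self.termination_frame:
            raise ValueError("initiation_frame must precede termination_frame")
        if self.nominal_duration <= 0:
            raise ValueError("nominal_duration must be positive")


@dataclass(frozen=True)
class KeypointTrajectory:
    """Per-trial keypoint coordinate record.

    ``coords`` has shape ``(n_frames, n_keypoints, 2)`` with the last axis
    (x, y) in pixels; y increases downward (image convention). Missing
    samples are NaN. ``keypoint_names`` fixes the column order.
    """

    participant_id: str
    trial_id: str
    condition: str
    duration_class: str
    coords: np.ndarray
    keypoint_names: tuple[str, ...] = KEYPOINT_NAMES
    sampling_rate: float = 60.0
    events: TrialEvents | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.duration_class not in DURATION_CLASSES:
            raise ValueError(
                f"unknown duration_class {self.duration_class!r}; "
                f"expected one of {DURATION_CLASSES}"
            )
        if len(self.keypoint_names) == 0:
            raise ValueError("keypoint_names must not be empty")
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 3 or c.shape[1] != len(self.keypoint_names) or c.shape[2] != 2:
            raise ValueError(
                f"coords must have shape (n_frames, {len(self.keypoint_names)}, 2); "
                f"got {c.shape}"
            )
        object.__setattr__(self, "coords", c)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.events is not None and self.events.termination_frame >= c.shape[0]:
            raise ValueError("termination_frame beyond the recorded frames")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def y(self, keypoint: str) -> np.ndarray:
        """Vertical (image y) series of one keypoint."""
        return self.coords[:, self.keypoint_names.index(keypoint), 1]

    def x(self, keypoint: str) -> np.ndarray:
        return self.coords[:, self.keypoint_names.index(keypoint), 0]


def _paths(path) -> tuple[Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix in {".csv", ".json"} else p
    return stem.with_suffix(".csv"), stem.with_suffix(".json")


def write_trajectory(traj: KeypointTrajectory, path) -> Path:
    """Write a trajectory as ``<stem>.csv`` + ``<stem>.json``; returns the csv path.

    Coordinates are written with ``repr`` float precision so that a
    read-back reproduces them bit for bit.
    """
    csv_path, json_path = _paths(path)
    n, k, _ = traj.coords.shape
    frames = np.repeat(np.arange(n), k)
    kp = np.tile(np.array(traj.keypoint_names, dtype=object), n)
    df = pd.DataFrame(
        {
            "frame": frames,
            "keypoint": kp,
            "x": traj.coords[:, :, 0].ravel(),
            "y": traj.coords[:, :, 1].ravel(),
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {
        "participant_id": traj.participant_id,
        "trial_id": traj.trial_id,
        "condition": traj.condition,
        "duration_class": traj.duration_class,
        "sampling_rate": traj.sampling_rate,
        "keypoint_names": list(traj.keypoint_names),
        "events": None
        if traj.events is None
        else {
            "initiation_frame": traj.events.initiation_frame,
            "termination_frame": traj.events.termination_frame,
            "nominal_duration": traj.events.nominal_duration,
        },
    }
    json_path.write_text(json.dumps(meta, indent=1))
    return csv_path


def read_trajectory(path, require_events: bool = True) -> KeypointTrajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Blank x/y cells become missing (NaN) samples. Malformed files raise
    ``ValueError`` naming the offending row or field.
    """
    csv_path, json_path = _paths(path)
    if not csv_path.exists():
        raise FileNotFoundError(csv_path)
    if not json_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata file {json_path}")
    meta = json.loads(json_path.read_text())
    for fld in ("participant_id", "trial_id", "condition", "duration_class",
                "sampling_rate", "keypoint_names"):
        if fld not in meta:
            raise ValueError(f"sidecar {json_path} is missing field {fld!r}")
    names = tuple(meta["keypoint_names"])

    df = pd.read_csv(csv_path, float_precision="round_trip")
    expected_cols = ["frame", "keypoint", "x", "y"]
    if list(df.columns) != expected_cols:
        raise ValueError(
            f"malformed header in {csv_path}: expected {expected_cols}, "
            f"got {list(df.columns)}"
        )
    unknown = set(df["keypoint"]) - set(names)
    if unknown:
        bad = df.index[df["keypoint"].isin(unknown)][0]
        raise ValueError(
            f"unknown keypoint label {sorted(unknown)[0]!r} at row {bad + 2} of {csv_path}"
        )
    dup = df.duplicated(subset=["frame", "keypoint"])
    if dup.any():
        raise ValueError(
            f"duplicate (frame, keypoint) entry at row {df.index[dup][0] + 2} of {csv_path}"
        )

    frames = np.sort(df["frame"].unique())
    if len(frames) and (frames[0] != 0 or frames[-1] != len(frames) - 1):
        raise ValueError(f"frame indices in {csv_path} are not contiguous from 0")
    n, k = len(frames), len(names)
    coords = np.full((n, k, 2), np.nan)
    kp_idx = {kp: j for j, kp in enumerate(names)}
    rows_f = df["frame"].to_numpy()
    rows_k = df["keypoint"].map(kp_idx).to_numpy()
    coords[rows_f, rows_k, 0] = df["x"].to_numpy()
    coords[rows_f, rows_k, 1] = df["y"].to_numpy()

    ev_meta = meta.get("events")
    if ev_meta is None:
        if require_events:
            missing = "termination_frame" if ev_meta is None else ""
            raise ValueError(
                f"{json_path} has no trial events (initiation_frame/termination_frame)"
            )
        events = None
    else:
        for fld in ("initiation_frame", "termination_frame", "nominal_duration"):
            if ev_meta.get(fld) is None:
                raise ValueError(f"{json_path} events are missing {fld!r}")
        events = TrialEvents(
            initiation_frame=int(ev_meta["initiation_frame"]),
            termination_frame=int(ev_meta["termination_frame"]),
            nominal_duration=float(ev_meta["nominal_duration"]),
        )
    return KeypointTrajectory(
        participant_id=str(meta["participant_id"]),
        trial_id=str(meta["trial_id"]),
        condition=meta["condition"],
        duration_class=meta["duration_class"],
        coords=coords,
        keypoint_names=names,
        sampling_rate=float(meta["sampling_rate"]),
        events=events,
    )
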