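"""Reading, validation and windowing of marker-trajectory recordings.

Conventions used throughout the package:

* time is expressed in **minutes since recording start**, with a nominal
  sampling step of 3 min (one time-lapse frame every 3 min, i.e. 0.0056 Hz);
  gaps are tolerated and flagged, never silently interpolated;
* positions are in **mm**, axes ``(X, Y, Z)`` with Y the vertical (growth)
  axis and X-Z the horizontal plane in which all planar measures
  (circumnutation center, area, turning angles) are computed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LANDMARKS",
    "NOMINAL_STEP_MIN",
    "SAMPLING_FREQUENCY_HZ",
    "MarkerTrajectory",
    "PlantRecording",
    "LeafWindow",
    "Anomaly",
    "FormatError",
    "ValidationError",
    "EmptyWindowError",
    "read_recording",
    "write_recording",
    "read_metadata",
    "write_metadata",
    "extract_leaf_window",
    "validate_recording",
]

#: Landmarks a marker may be attached to.
LANDMARKS = ("apex", "tendrils", "origin", "internode", "support_low", "support_high")

#: Nominal sampling step of the time-lapse acquisition (minutes).
NOMINAL_STEP_MIN = 3.0

#: Acquisition frequency corresponding to the 3-min cadence, in Hz.
SAMPLING_FREQUENCY_HZ = 1.0 / (NOMINAL_STEP_MIN * 60.0)

#: Experimental conditions.
CONDITIONS = ("Support", "NoSupport")

REQUIRED_COLUMNS = ("plant_id", "landmark", "time_min", "x_mm", "y_mm", "z_mm")


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class ValidationError(ValueError):
    """Raised when data violate a structural invariant."""


class EmptyWindowError(ValueError):
    """Raised when a leaf window selects no samples."""


@dataclass(frozen=True)
class MarkerTrajectory:
    """Timestamped 3D positions of one landmark of one plant.

    Parameters
    ----------
    plant_id : str
        Plant identifier.
    landmark : str
        One of :data:`LANDMARKS`.
    times : ndarray, shape (n,)
        Minutes since recording start, strictly increasing.
    positions : ndarray, shape (n, 3)
        Positions in mm, columns (x, y, z) with y vertical.
    """

    plant_id: str
    landmark: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        if self.landmark not in LANDMARKS:
            raise ValidationError(f"unknown landmark {self.landmark!r}")
        if times.ndim != 1 or positions.shape != (times.size, 3):
            raise ValidationError(
                f"times/positions shape mismatch: {times.shape} vs {positions.shape}"
            )
        if times.size < 2:
            raise ValidationError("trajectory needs at least 2 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(positions)):
            raise ValidationError("non-finite values in trajectory")
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"times not strictly increasing for landmark {self.landmark!r} "
                f"of plant {self.plant_id!r}"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def xz(self) -> np.ndarray:
        """Horizontal-plane coordinates, shape (n, 2)."""
        return self.positions[:, [0, 2]]

    def slice(self, start: int, stop: int) -> "MarkerTrajectory":
        """Sub-trajectory over sample indices ``[start, stop)``."""
        return MarkerTrajectory(
            self.plant_id, self.landmark, self.times[start:stop], self.positions[start:stop]
        )


@dataclass(frozen=True)
class LeafWindow:
    """Time window during which one leaf's movement is analyzed.

    The window of the terminal leaf (``terminal=True``) runs until support
    contact (coiled) or collapse; windows of one landmark must not overlap.
    """

    leaf_ordinal: int
    landmark: str
    start_time: float
    end_time: float
    terminal: bool = False
    coiled: bool = False

    def __post_init__(self) -> None:
        if self.leaf_ordinal < 1:
            raise ValidationError("leaf_ordinal must be >= 1")
        if self.landmark not in LANDMARKS:
            raise ValidationError(f"unknown landmark {self.landmark!r}")
        if not self.start_time < self.end_time:
            raise ValidationError(
                f"leaf window start {self.start_time} must precede end {self.end_time}"
            )

    @property
    def span_min(self) -> float:
        return float(self.end_time - self.start_time)


@dataclass
class PlantRecording:
    """All marker trajectories of one plant plus experiment metadata."""

    plant_id: str
    condition: str
    trajectories: dict[str, MarkerTrajectory] = field(default_factory=dict)
    leaf_windows: list[LeafWindow] = field(default_factory=list)
    support_position: tuple[float, float, float] | None = None  # (x, z, height)
    origin_position: tuple[float, float] | None = None  # (x, z)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        # Missing origin/support are reported by validate_recording rather
        # than rejected here, so incomplete recordings can still be inspected.
        _check_windows(self.leaf_windows)

    @property
    def origin_xz(self) -> tuple[float, float]:
        """Planar plant origin: explicit metadata, else the mean position of
        the origin marker."""
        if self.origin_position is not None:
            return (float(self.origin_position[0]), float(self.origin_position[1]))
        if "origin" not in self.trajectories:
            raise ValidationError(
                f"recording {self.plant_id!r} has no origin marker or metadata"
            )
        xz = self.trajectories["origin"].xz.mean(axis=0)
        return (float(xz[0]), float(xz[1]))

    @property
    def support_xz(self) -> tuple[float, float] | None:
        if self.support_position is not None:
            return (float(self.support_position[0]), float(self.support_position[1]))
        if "support_low" in self.trajectories:
            xz = self.trajectories["support_low"].xz.mean(axis=0)
            return (float(xz[0]), float(xz[1]))
        return None

    def windows_for(self, landmark: str) -> list[LeafWindow]:
        return sorted(
            (w for w in self.leaf_windows if w.landmark == landmark),
            key=lambda w: w.start_time,
        )


def _check_windows(windows: Sequence[LeafWindow]) -> None:
    by_landmark: dict[str, list[LeafWindow]] = {}
    for w in windows:
        by_landmark.setdefault(w.landmark, []).append(w)
    for landmark, group in by_landmark.items():
        group = sorted(group, key=lambda w: w.start_time)
        for a, b in zip(group, group[1:]):
            if b.start_time < a.end_time:
                raise ValidationError(
                    f"overlapping leaf windows for landmark {landmark!r}: "
                    f"[{a.start_time}, {a.end_time}] and [{b.start_time}, {b.end_time}]"
                )


# ---------------------------------------------------------------------------
# file I/O


def read_recording(path: str | Path, meta: Mapping | str | Path | None = None) -> PlantRecording:
    """Read a trajectory CSV (plus optional metadata) into a PlantRecording.

    The CSV must carry columns ``plant_id, landmark, time_min, x_mm, y_mm,
    z_mm`` (an optional ``condition`` column is honoured when metadata gives
    none). ``meta`` may be a mapping or a path to a YAML file as written by
    :func:`write_metadata`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise FormatError(f"{path}: empty trajectory table")
    plant_ids = df["plant_id"].unique()
    if len(plant_ids) != 1:
        raise FormatError(
            f"{path}: expected a single plant per file, found {list(plant_ids)}"
        )

    if meta is not None and not isinstance(meta, Mapping):
        meta = read_metadata(meta)
    meta = dict(meta or {})

    condition = meta.get("condition")
    if condition is None:
        if "condition" in df.columns:
            condition = str(df["condition"].iloc[0])
        else:
            raise FormatError(f"{path}: condition missing from file and metadata")

    trajectories: dict[str, MarkerTrajectory] = {}
    for landmark, group in df.groupby("landmark", sort=False):
        group = group.sort_values("time_min", kind="stable")
        times = group["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"{path}: duplicate or non-monotone time for landmark {landmark!r}"
            )
        positions = group[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
        trajectories[str(landmark)] = MarkerTrajectory(
            str(plant_ids[0]), str(landmark), times, positions
        )

    windows = [_window_from_mapping(w) for w in meta.get("leaf_windows", [])]
    support = meta.get("support")
    support_position = None
    if support is not None:
        support_position = (
            float(support["x"]),
            float(support["z"]),
            float(support.get("height", 0.0)),
        )
    origin = meta.get("origin_xz")
    origin_position = (float(origin[0]), float(origin[1])) if origin is not None else None

    return PlantRecording(
        plant_id=str(plant_ids[0]),
        condition=str(condition),
        trajectories=trajectories,
        leaf_windows=windows,
        support_position=support_position,
        origin_position=origin_position,
    )


def write_recording(rec: PlantRecording, path: str | Path) -> None:
    """Write a recording to the long-format trajectory CSV."""
    frames = []
    for landmark, traj in rec.trajectories.items():
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": rec.plant_id,
                    "condition": rec.condition,
                    "landmark": landmark,
                    "time_min": traj.times,
                    "x_mm": traj.positions[:, 0],
                    "y_mm": traj.positions[:, 1],
                    "z_mm": traj.positions[:, 2],
                }
            )
        )
    # pandas' default float formatting is shortest round-trip, i.e. lossless
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _window_from_mapping(w: Mapping) -> LeafWindow:
    return LeafWindow(
        leaf_ordinal=int(w["leaf"]),
        landmark=str(w.get("landmark", "apex")),
        start_time=float(w["start"]),
        end_time=float(w["end"]),
        terminal=bool(w.get("terminal", False)),
        coiled=bool(w.get("coiled", False)),
    )


def _window_to_mapping(w: LeafWindow) -> dict:
    return {
        "leaf": w.leaf_ordinal,
        "landmark": w.landmark,
        "start": w.start_time,
        "end": w.end_time,
        "terminal": w.terminal,
        "coiled": w.coiled,
    }


def metadata_mapping(rec: PlantRecording) -> dict:
    """Metadata mapping (YAML-serializable) for a recording."""
    meta: dict = {
        "plant_id": rec.plant_id,
        "condition": rec.condition,
        "leaf_windows": [_window_to_mapping(w) for w in rec.leaf_windows],
    }
    if rec.origin_position is not None:
        meta["origin_xz"] = [float(rec.origin_position[0]), float(rec.origin_position[1])]
    if rec.support_position is not None:
        meta["support"] = {
            "x": float(rec.support_position[0]),
            "z": float(rec.support_position[1]),
            "height": float(rec.support_position[2]),
        }
    return meta


def write_metadata(rec: PlantRecording, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(metadata_mapping(rec), fh, sort_keys=False)


def read_metadata(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, Mapping):
        raise FormatError(f"{path}: metadata must be a mapping")
    return dict(meta)


# ---------------------------------------------------------------------------
# windowing and validation


def extract_leaf_window(rec: PlantRecording, win: LeafWindow) -> MarkerTrajectory:
    """Sub-trajectory of ``win.landmark`` with ``start_time <= t <= end_time``.

    Both window edges are inclusive; an empty intersection raises
    :class:`EmptyWindowError`.
    """
    if win.landmark not in rec.trajectories:
        raise EmptyWindowError(
            f"recording {rec.plant_id!r} has no {win.landmark!r} trajectory"
        )
    traj = rec.trajectories[win.landmark]
    mask = (traj.times >= win.start_time) & (traj.times <= win.end_time)
    if not mask.any():
        raise EmptyWindowError(
            f"window [{win.start_time}, {win.end_time}] selects no samples of "
            f"{win.landmark!r}"
        )
    idx = np.flatnonzero(mask)
    return traj.slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass(frozen=True)
class Anomaly:
    """One finding of :func:`validate_recording`."""

    kind: str  # "gap" | "missing_support" | "missing_origin" | "irregular_step"
    landmark: str | None
    time_min: float | None
    detail: str


def validate_recording(
    rec: PlantRecording, nominal_step: float = NOMINAL_STEP_MIN, tol: float = 1e-6
) -> list[Anomaly]:
    """Report sampling gaps and missing reference metadata; never mutates.

    A gap is any inter-sample interval exceeding the nominal 3-min step.
    """
    anomalies: list[Anomaly] = []
    for landmark, traj in rec.trajectories.items():
        steps = np.diff(traj.times)
        for i in np.flatnonzero(steps > nominal_step + tol):
            anomalies.append(
                Anomaly(
                    kind="gap",
                    landmark=landmark,
                    time_min=float(traj.times[i]),
                    detail=f"{steps[i]:g}-min gap after t={traj.times[i]:g}",
                )
            )
    if rec.origin_position is None and "origin" not in rec.trajectories:
        anomalies.append(
            Anomaly("missing_origin", None, None, "no origin marker or metadata")
        )
    if rec.condition == "Support" and rec.support_xz is None:
        anomalies.append(
            Anomaly("missing_support", None, None, "Support condition without support position")
        )
    return anomalies
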