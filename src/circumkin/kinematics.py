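"""Circumnutation kinematics: loop segmentation and dependent measures.

A circumnutating organ (apex or tendrils) traces a roughly helical path;
projected onto the horizontal X-Z plane each revolution is a loop.  This
module turns a leaf-window trajectory into individual circumnutations and
computes, per loop: duration, signed turning-angle sum and rotation
direction, geometric center and its distance from the plant origin, raster
footprint area, and mean speed/acceleration; per leaf: movement time, loop
count and direction-switch counts.

Direction is classified from the turning-angle sum s of a loop:
counterclockwise if ``|s - 2*pi| <= 1.2`` rad, clockwise if
``|s + 2*pi| <= 1.2`` rad, otherwise no direction is assigned.

Growth phases split at 5000 min: the first two leaves (vertical growth,
little or no tendril) fall in PRE, the third leaf onward (consistent
tendrils, pronounced circumnutation) in POST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import LeafWindow, MarkerTrajectory, PlantRecording, extract_leaf_window

__all__ = [
    "DIRECTION_TOLERANCE_RAD",
    "PHASE_BOUNDARY_MIN",
    "LOOP_CLOSURE_SLACK_RAD",
    "PlanarPath",
    "Circumnutation",
    "LeafKinematics",
    "UndefinedAngleError",
    "planar",
    "speed_profile",
    "turning_angles",
    "turning_angle_sum",
    "classify_direction",
    "segment_circumnutations",
    "circumnutation_center_distance",
    "raster_cells",
    "raster_area",
    "count_switches",
    "label_phase",
    "leaf_kinematics",
    "build_kinematic_table",
    "standardize",
    "KINEMATIC_INDICES",
]

#: Half-width (rad) of the classification windows around +/-2*pi.
DIRECTION_TOLERANCE_RAD = 1.2

#: PRE/POST phase boundary, minutes from recording start.
PHASE_BOUNDARY_MIN = 5000.0

#: Minimum loop-closure slack (rad): a loop closes when the magnitude of the
#: running signed turning angle reaches 2*pi minus the slack.  Discrete
#: sampling always leaves the open path of one revolution a couple of angular
#: steps short of 2*pi, so the slack adapts to the observed angular step
#: (2.5 median steps) within [LOOP_CLOSURE_SLACK_RAD, MAX_CLOSURE_SLACK_RAD].
LOOP_CLOSURE_SLACK_RAD = 0.3
MAX_CLOSURE_SLACK_RAD = 1.0

#: Turning angles above this magnitude (rad) are treated as direction-
#: reversal cusps during segmentation: smoothing smears a reversal into a
#: tight hook whose largest angle still far exceeds any regular sampling
#: step, and the turn through a reversal carries no winding information.
CUSP_ANGLE_RAD = 2.0

#: Default centered moving-average window (samples) applied before turning
#: angles are computed for segmentation and direction classification.  At the
#: 3-min cadence 9 samples = 27 min, well below the fastest circumnutation
#: period, so the winding of the underlying loop is preserved while
#: frame-to-frame positional noise (which would otherwise dominate the
#: heading of the small PRE-leaf displacements) is suppressed.
DEFAULT_SMOOTH_WINDOW = 9

#: Names of the four per-circumnutation kinematic indices used in the models.
KINEMATIC_INDICES = (
    "mean_speed_mm_min",
    "mean_accel_mm_min2",
    "center_distance_mm",
    "area_mm2",
)


class UndefinedAngleError(ValueError):
    """Raised when a path has fewer than two nonzero displacements."""


@dataclass(frozen=True)
class PlanarPath:
    """Horizontal-plane (x, z) projection of a trajectory."""

    times: np.ndarray
    points: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        points = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "points", points)
        if points.shape != (times.size, 2):
            raise ValueError("points must be (n, 2) matching times")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(points))):
            raise ValueError("non-finite planar path")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Circumnutation:
    """One detected loop and its dependent measures."""

    index_range: tuple[int, int]  # half-open sample indices into the path
    start_time: float
    duration_min: float
    turning_sum_rad: float
    direction: str  # "clockwise" | "counterclockwise" | "none"
    center_xz_mm: tuple[float, float]
    center_distance_mm: float
    area_mm2: float
    mean_speed_mm_min: float
    mean_accel_mm_min2: float


@dataclass(frozen=True)
class LeafKinematics:
    """Per-leaf summary: all loops of one leaf window plus leaf-level counts."""

    plant_id: str
    leaf_ordinal: int
    landmark: str
    condition: str
    phase: str  # "PRE" | "POST"
    movement_time_min: float
    circumnutations: tuple[Circumnutation, ...]
    n_switches_cw: int
    n_switches_ccw: int

    @property
    def n_circumnutations(self) -> int:
        return len(self.circumnutations)


# ---------------------------------------------------------------------------
# elementary transforms


def planar(traj: MarkerTrajectory) -> PlanarPath:
    """Project a 3D trajectory onto the horizontal X-Z plane."""
    return PlanarPath(traj.times, traj.xz)


def speed_profile(
    times: np.ndarray, positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval speeds (mm/min) and accelerations (mm/min^2).

    ``speed[i] = ||p[i+1] - p[i]|| / (t[i+1] - t[i])`` over 3D displacement;
    ``accel[j] = (speed[j+1] - speed[j]) / dt_j`` with ``dt_j`` the spacing
    of interval midpoints.  Speed needs >= 2 samples, acceleration >= 3.
    """
    times = np.asarray(times, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if times.size < 2:
        raise ValueError("speed profile needs at least 2 samples")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("zero or negative time step")
    disp = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    speeds = disp / dt
    if times.size >= 3:
        mid = (times[:-1] + times[1:]) / 2.0
        accels = np.diff(speeds) / np.diff(mid)
    else:
        accels = np.empty(0)
    return speeds, accels


def _nonzero_displacements(
    points: np.ndarray, atol: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Displacement vectors with zero-length ones dropped.

    Returns (vectors, start_index_of_each_vector)."""
    v = np.diff(points, axis=0)
    norms = np.linalg.norm(v, axis=1)
    keep = norms > atol
    return v[keep], np.flatnonzero(keep)


def turning_angles(points: np.ndarray) -> np.ndarray:
    """Signed angles (rad) between consecutive nonzero displacement vectors.

    Counterclockwise positive in the (x, z) plane.  Zero-length
    displacements are skipped.
    """
    v, _ = _nonzero_displacements(np.asarray(points, dtype=float))
    if v.shape[0] < 2:
        raise UndefinedAngleError("need at least 2 nonzero displacements")
    a, b = v[:-1], v[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    return np.arctan2(cross, dot)


def turning_angle_sum(
    path: PlanarPath, index_range: tuple[int, int] | None = None
) -> float:
    """Signed turning-angle sum (rad) over a sample range.

    For an open path this is the sum of angles between consecutive
    displacement vectors.  If the (sub)path is exactly closed (last point
    equals first), the wrap-around angle is included so that a simple loop
    sums to exactly +/-2*pi (its turning number times 2*pi).
    """
    s, e = index_range if index_range is not None else (0, len(path))
    pts = path.points[s:e]
    if pts.shape[0] < 3:
        raise UndefinedAngleError("need at least 3 points")
    closed = bool(np.all(pts[0] == pts[-1]))
    if closed:
        pts = np.vstack([pts[:-1], pts[:2]])  # wrap two points to close angles
    angles = turning_angles(pts)
    return float(np.sum(angles))


def classify_direction(
    turning_sum: float, tol: float = DIRECTION_TOLERANCE_RAD
) -> str:
    """Rotation direction of a loop from its signed turning-angle sum.

    Counterclockwise iff within ``tol`` of +2*pi, clockwise iff within
    ``tol`` of -2*pi, otherwise ``"none"``.  Interval edges belong to the
    directional class.
    """
    if not np.isfinite(turning_sum):
        raise ValueError("turning sum must be finite")
    two_pi = 2.0 * np.pi
    if abs(turning_sum - two_pi) <= tol:
        return "counterclockwise"
    if abs(turning_sum + two_pi) <= tol:
        return "clockwise"
    return "none"


# ---------------------------------------------------------------------------
# loop segmentation


def _quadratic_pad(points: np.ndarray, h: int) -> np.ndarray:
    """Extend a path by ``h`` samples at each end via least-squares
    quadratic extrapolation, so that edge tangents and curvature survive
    subsequent smoothing."""
    n = points.shape[0]
    chunk = min(max(5, 2 * h + 1), n)
    deg = 2 if chunk >= 4 else 1
    t_fit = np.arange(chunk)
    c_head = np.polyfit(t_fit, points[:chunk], deg)
    c_tail = np.polyfit(t_fit, points[n - chunk :], deg)
    t_head = np.arange(-h, 0)
    t_tail = np.arange(chunk, chunk + h)
    head = np.column_stack([np.polyval(c_head[:, j], t_head) for j in range(2)])
    tail = np.column_stack([np.polyval(c_tail[:, j], t_tail) for j in range(2)])
    return np.vstack([head, points, tail])


def smooth_path(path: PlanarPath, window: int = DEFAULT_SMOOTH_WINDOW) -> PlanarPath:
    """Centered moving average over ``window`` samples (odd).

    The path is first extended by quadratic extrapolation over half a
    window at each end, so the smoothed path keeps the original sample
    count and does not lose turning at its ends."""
    if window <= 1:
        return path
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    n = len(path)
    h = window // 2
    padded = _quadratic_pad(path.points, h)
    kernel = np.ones(window) / window
    sm = np.column_stack(
        [np.convolve(padded[:, j], kernel, mode="valid") for j in range(2)]
    )
    assert sm.shape[0] == n
    return PlanarPath(path.times, sm)


def segment_circumnutations(
    path: PlanarPath,
    closure_slack: float | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> list[tuple[int, int]]:
    """Split a planar path into consecutive loops (circumnutations).

    The path is lightly smoothed (:func:`smooth_path`), then the signed
    turning angles between consecutive displacement vectors are accumulated
    along the whole path; a loop closes at the first sample where the
    winding magnitude ``|sum|`` since the previous closure reaches
    ``2*pi - slack``.  Because the signed sum telescopes (it equals the
    heading change of the displacement vector plus full windings),
    measurement noise does not accumulate along a loop.  The slack absorbs
    the discrete-sampling shortfall of an open revolution; by default it
    adapts to the observed angular step.  The trailing partial loop is
    discarded.  Ranges are half-open, non-overlapping, in time order.
    """
    sm = smooth_path(path, smooth_window)
    pts = sm.points
    if pts.shape[0] < 3:
        return []
    v, starts = _nonzero_displacements(pts)
    if v.shape[0] < 2:
        return []
    # angle[k-1] is between vectors v[k-1] and v[k]
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    dot = np.einsum("ij,ij->i", v[:-1], v[1:])
    angles = np.arctan2(cross, dot)
    regular = np.abs(angles) <= CUSP_ANGLE_RAD
    if not regular.any():
        return []
    step = float(np.median(np.abs(angles[regular]))) or 0.1
    if closure_slack is None:
        closure_slack = float(
            np.clip(2.5 * step, LOOP_CLOSURE_SLACK_RAD, MAX_CLOSURE_SLACK_RAD)
        )
    threshold = 2.0 * np.pi - closure_slack
    # at a reversal or at the path end the smoothed path flattens about half
    # a window of turning on each side; loops ending there get this allowance
    boundary_allowance = float(np.clip((smooth_window + 2) * step, 0.3, 1.2))

    n = pts.shape[0]
    ranges: list[tuple[int, int]] = []
    start_pt = 0  # current loop start (sample index)
    cum = 0.0

    def emit(end_pt: int) -> None:
        nonlocal start_pt
        if end_pt - start_pt >= 3:
            ranges.append((start_pt, end_pt))
        start_pt = end_pt

    for k in range(1, v.shape[0]):
        a = angles[k - 1]
        if abs(a) > CUSP_ANGLE_RAD:
            # direction reversal: a circumnutation boundary.  Close the
            # current loop if its winding is within the allowance, and never
            # carry winding across the reversal.
            if abs(cum) >= threshold - boundary_allowance:
                emit(int(starts[k]) + 1)  # up to the reversal point
            cum = 0.0
            continue
        cum += a
        if abs(cum) >= threshold:
            emit(int(starts[k]) + 2)  # include both endpoints of v[k]
            # carry the winding residual so successive closures stay
            # phase-locked to the underlying revolutions
            cum -= np.sign(cum) * 2.0 * np.pi
    if abs(cum) >= threshold - boundary_allowance:
        emit(n)  # trailing loop cut short only by the path end
    return ranges


def circumnutation_center_distance(
    path: PlanarPath,
    index_range: tuple[int, int],
    origin_xz: tuple[float, float],
) -> tuple[tuple[float, float], float]:
    """Loop center (coordinate-wise mean over the loop's points, the
    "geometric center of gravity" in the X-Z plane) and its planar
    Euclidean distance (mm) from the plant origin."""
    if origin_xz is None:
        raise ValueError("plant origin required for center distance")
    s, e = index_range
    if e <= s:
        raise ValueError("empty index range")
    center = path.points[s:e].mean(axis=0)
    dist = float(np.hypot(center[0] - origin_xz[0], center[1] - origin_xz[1]))
    return (float(center[0]), float(center[1])), dist


# ---------------------------------------------------------------------------
# raster area


def raster_cells(
    points: np.ndarray, pixel_size: float = 1.0
) -> set[tuple[int, int]]:
    """Grid cells covered by a polyline (supercover rasterization).

    A cell ``(i, j)`` covers ``[i*s, (i+1)*s) x [j*s, (j+1)*s)``; every cell
    containing any point of the polyline is returned.  Cells are found by
    cutting each segment at its grid-line crossings and sampling each
    resulting piece at its parameter midpoint.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    pts = np.asarray(points, dtype=float) / pixel_size
    cells: set[tuple[int, int]] = set()
    for p in (pts[0], pts[-1]):
        cells.add((int(np.floor(p[0])), int(np.floor(p[1]))))
    for a, b in zip(pts[:-1], pts[1:]):
        cells.add((int(np.floor(a[0])), int(np.floor(a[1]))))
        cells.add((int(np.floor(b[0])), int(np.floor(b[1]))))
        d = b - a
        ts = [0.0, 1.0]
        for axis in range(2):
            if d[axis] != 0.0:
                lo, hi = sorted((a[axis], b[axis]))
                first = np.ceil(lo)
                lines = np.arange(first, np.floor(hi) + 1.0)
                ts.extend(((lines - a[axis]) / d[axis]).tolist())
        ts = np.clip(np.unique(ts), 0.0, 1.0)
        mids = (ts[:-1] + ts[1:]) / 2.0
        for t in mids:
            p = a + t * d
            cells.add((int(np.floor(p[0])), int(np.floor(p[1]))))
    return cells


def raster_area(
    path: PlanarPath,
    index_range: tuple[int, int] | None = None,
    pixel_size: float = 1.0,
) -> float:
    """Footprint area (mm^2) of the loop's trajectory.

    The polyline is binarized onto a square grid of side ``pixel_size`` and
    the area is the number of occupied pixels times the pixel area — the
    footprint of the traced curve, not the filled region it encloses.
    """
    s, e = index_range if index_range is not None else (0, len(path))
    pts = path.points[s:e]
    if pts.shape[0] < 1:
        raise ValueError("empty index range")
    return len(raster_cells(pts, pixel_size)) * pixel_size**2


# ---------------------------------------------------------------------------
# leaf-level measures


def count_switches(directions: Sequence[str]) -> tuple[int, int]:
    """Count direction switches in an ordered sequence of loop directions.

    A switch occurs at each loop whose (non-``none``) direction differs
    from the most recent preceding non-``none`` direction, and is
    attributed to the new direction.  Undetermined (``none``) loops are
    skipped and never generate switches.  Returns ``(n_cw, n_ccw)``.
    """
    n_cw = n_ccw = 0
    prev: str | None = None
    for d in directions:
        if d == "none":
            continue
        if d not in ("clockwise", "counterclockwise"):
            raise ValueError(f"unknown direction label {d!r}")
        if prev is not None and d != prev:
            if d == "clockwise":
                n_cw += 1
            else:
                n_ccw += 1
        prev = d
    return n_cw, n_ccw


def label_phase(time_min: float, boundary: float = PHASE_BOUNDARY_MIN) -> str:
    """Growth phase of a time point: PRE before the boundary, POST at or
    after it (boundary default 5000 min, the passage from the second to the
    third leaf)."""
    if time_min < 0:
        raise ValueError("time must be nonnegative")
    return "POST" if time_min >= boundary else "PRE"


def leaf_kinematics(
    traj: MarkerTrajectory,
    window: LeafWindow,
    origin_xz: tuple[float, float],
    condition: str,
    pixel_size: float = 1.0,
    phase_boundary: float = PHASE_BOUNDARY_MIN,
    closure_slack: float | None = None,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
) -> LeafKinematics:
    """All dependent measures for one leaf window of one landmark.

    Loop boundaries are found on the lightly smoothed path (stable
    headings); every dependent measure — turning sum, direction, duration,
    center, area, speeds — is then computed from the raw samples of the
    detected range.
    """
    mask = (traj.times >= window.start_time) & (traj.times <= window.end_time)
    if not mask.any():
        raise ValueError("window selects no samples")
    idx = np.flatnonzero(mask)
    sub = traj.slice(int(idx[0]), int(idx[-1]) + 1)
    path = planar(sub)
    speeds, accels = speed_profile(sub.times, sub.positions)

    loops: list[Circumnutation] = []
    for s, e in segment_circumnutations(
        path, closure_slack=closure_slack, smooth_window=smooth_window
    ):
        tsum = turning_angle_sum(path, (s, e))
        center, dist = circumnutation_center_distance(path, (s, e), origin_xz)
        loop_speeds = speeds[s : e - 1]
        loop_accels = accels[s : max(s, e - 2)]
        loops.append(
            Circumnutation(
                index_range=(s, e),
                start_time=float(sub.times[s]),
                duration_min=float(sub.times[e - 1] - sub.times[s]),
                turning_sum_rad=tsum,
                direction=classify_direction(tsum),
                center_xz_mm=center,
                center_distance_mm=dist,
                area_mm2=raster_area(path, (s, e), pixel_size),
                mean_speed_mm_min=float(loop_speeds.mean()) if loop_speeds.size else np.nan,
                mean_accel_mm_min2=float(loop_accels.mean()) if loop_accels.size else np.nan,
            )
        )
    n_cw, n_ccw = count_switches([c.direction for c in loops])
    return LeafKinematics(
        plant_id=traj.plant_id,
        leaf_ordinal=window.leaf_ordinal,
        landmark=window.landmark,
        condition=condition,
        phase=label_phase(window.start_time, phase_boundary),
        movement_time_min=window.span_min,
        circumnutations=tuple(loops),
        n_switches_cw=n_cw,
        n_switches_ccw=n_ccw,
    )


def _rank_labels(ordinals: Sequence[int], depth: int = 3) -> dict[int, str]:
    """Map the last ``depth`` leaf ordinals to rank labels from the end."""
    names = ["Last", "Second last", "Third last"]
    ranked = sorted(ordinals)[-depth:]
    return {o: names[len(ranked) - 1 - i] for i, o in enumerate(ranked)}


def build_kinematic_table(
    rec: PlantRecording,
    pixel_size: float = 1.0,
    phase_boundary: float = PHASE_BOUNDARY_MIN,
    landmarks: Iterable[str] = ("apex", "tendrils"),
    rank_depth: int = 3,
) -> pd.DataFrame:
    """Long-format table: one row per circumnutation of one leaf window.

    ``leaf_rank`` labels the plant's last ``rank_depth`` leaves ("Third
    last", "Second last", "Last"); earlier leaves get an empty rank.
    """
    origin = rec.origin_xz
    rows = []
    ordinals = sorted({w.leaf_ordinal for w in rec.leaf_windows})
    ranks = _rank_labels(ordinals, rank_depth)
    for landmark in landmarks:
        if landmark not in rec.trajectories:
            continue
        for window in rec.windows_for(landmark):
            lk = leaf_kinematics(
                rec.trajectories[landmark],
                window,
                origin,
                rec.condition,
                pixel_size=pixel_size,
                phase_boundary=phase_boundary,
            )
            for c in lk.circumnutations:
                rows.append(
                    {
                        "plant_id": rec.plant_id,
                        "condition": rec.condition,
                        "landmark": landmark,
                        "leaf_ordinal": window.leaf_ordinal,
                        "leaf_rank": ranks.get(window.leaf_ordinal, ""),
                        "phase": lk.phase,
                        "movement_time_min": lk.movement_time_min,
                        "start_time_min": c.start_time,
                        "duration_min": c.duration_min,
                        "turning_sum_rad": c.turning_sum_rad,
                        "direction": c.direction,
                        "center_x_mm": c.center_xz_mm[0],
                        "center_z_mm": c.center_xz_mm[1],
                        "center_distance_mm": c.center_distance_mm,
                        "area_mm2": c.area_mm2,
                        "mean_speed_mm_min": c.mean_speed_mm_min,
                        "mean_accel_mm_min2": c.mean_accel_mm_min2,
                        "n_circumnutations": lk.n_circumnutations,
                        "n_switches_cw": lk.n_switches_cw,
                        "n_switches_ccw": lk.n_switches_ccw,
                    }
                )
    return pd.DataFrame(rows)


def standardize(values: pd.Series | np.ndarray) -> np.ndarray:
    """z-score over all observations entering a model (ddof=1)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd
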