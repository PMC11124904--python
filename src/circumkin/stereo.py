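"""Pinhole cameras and linear (DLT) stereo triangulation.

The time-lapse rig is a pair of calibrated cameras; each frame's 2D marker
positions are triangulated independently into a 3D point.  Only the linear
least-squares (DLT) solution is provided: inputs are assumed
distortion-free, and at the working distances involved (about a metre, with
a ~45 cm baseline) the linear solution is accurate to well under the marker
placement error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CameraModel",
    "StereoRig",
    "BehindCameraError",
    "DegenerateGeometryError",
    "project_point",
    "project_points",
    "triangulate_point",
    "triangulate_track",
    "look_at_camera",
    "default_rig",
]


class BehindCameraError(ValueError):
    """Point has non-positive depth in a camera."""


class DegenerateGeometryError(ValueError):
    """Stereo geometry does not constrain the 3D point (e.g. parallel rays)."""


@dataclass(frozen=True)
class CameraModel:
    """Calibrated pinhole camera: ``x ~ K (R X + t)``.

    intrinsics ``K`` is 3x3 upper-triangular with positive focal lengths in
    pixels; ``rotation``/``translation`` map world (mm) to camera
    coordinates.
    """

    intrinsics: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.intrinsics, dtype=float)
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "intrinsics", K)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if K.shape != (3, 3) or R.shape != (3, 3):
            raise ValueError("intrinsics and rotation must be 3x3")
        if not np.allclose(np.tril(K, -1), 0.0, atol=1e-12):
            raise ValueError("intrinsics must be upper-triangular")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ValueError("focal lengths must be positive")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R^T R = I within 1e-9)")

    @property
    def projection_matrix(self) -> np.ndarray:
        """3x4 matrix ``P = K [R | t]``."""
        return self.intrinsics @ np.hstack([self.rotation, self.translation[:, None]])

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates (mm)."""
        return -self.rotation.T @ self.translation

    def to_mapping(self) -> dict:
        return {
            "intrinsics": self.intrinsics.ravel().tolist(),
            "rotation": self.rotation.ravel().tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_mapping(cls, m: dict) -> "CameraModel":
        return cls(
            np.asarray(m["intrinsics"], dtype=float).reshape(3, 3),
            np.asarray(m["rotation"], dtype=float).reshape(3, 3),
            np.asarray(m["translation"], dtype=float).reshape(3),
        )


@dataclass(frozen=True)
class StereoRig:
    """A calibrated camera pair with distinct centers."""

    camera_a: CameraModel
    camera_b: CameraModel

    def __post_init__(self) -> None:
        if np.linalg.norm(self.camera_a.center - self.camera_b.center) < 1e-9:
            raise DegenerateGeometryError("stereo cameras must have distinct centers")

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(self.camera_a.center - self.camera_b.center))

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"camera_a": self.camera_a.to_mapping(), "camera_b": self.camera_b.to_mapping()},
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, path: str | Path) -> "StereoRig":
        with open(path, encoding="utf-8") as fh:
            m = json.load(fh)
        return cls(CameraModel.from_mapping(m["camera_a"]), CameraModel.from_mapping(m["camera_b"]))


def project_points(points: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Project world points (n, 3) mm to pixel coordinates (n, 2)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cam_pts = points @ cam.rotation.T + cam.translation
    depth = cam_pts[:, 2]
    if np.any(depth <= 0):
        raise BehindCameraError("point(s) at non-positive depth")
    uvw = cam_pts @ cam.intrinsics.T
    return uvw[:, :2] / uvw[:, 2:3]


def project_point(p: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Project a single world point (mm) to a pixel 2-vector."""
    return project_points(np.asarray(p, dtype=float)[None, :], cam)[0]


def _ray_direction(px: np.ndarray, cam: CameraModel) -> np.ndarray:
    d = np.linalg.solve(cam.intrinsics, np.array([px[0], px[1], 1.0]))
    d = cam.rotation.T @ d
    return d / np.linalg.norm(d)


def triangulate_point(
    px_a: np.ndarray,
    px_b: np.ndarray,
    rig: StereoRig,
    min_ray_angle_rad: float = 1e-8,
) -> np.ndarray:
    """DLT triangulation of one point from its two pixel observations.

    Solves the homogeneous linear system built from both projection
    matrices by SVD, minimizing the algebraic error.  Rays closer to
    parallel than ``min_ray_angle_rad`` raise
    :class:`DegenerateGeometryError`.
    """
    ra = _ray_direction(np.asarray(px_a, float), rig.camera_a)
    rb = _ray_direction(np.asarray(px_b, float), rig.camera_b)
    cross = np.linalg.norm(np.cross(ra, rb))
    if cross < min_ray_angle_rad:
        raise DegenerateGeometryError(
            f"viewing rays nearly parallel (sin angle = {cross:.2e})"
        )
    A = np.empty((4, 4))
    for i, (px, cam) in enumerate([(px_a, rig.camera_a), (px_b, rig.camera_b)]):
        P = cam.projection_matrix
        A[2 * i] = px[0] * P[2] - P[0]
        A[2 * i + 1] = px[1] * P[2] - P[1]
    _, _, vt = np.linalg.svd(A)
    h = vt[-1]
    if abs(h[3]) < 1e-15:
        raise DegenerateGeometryError("triangulated point at infinity")
    return h[:3] / h[3]


def triangulate_track(
    px_a: np.ndarray, px_b: np.ndarray, rig: StereoRig
) -> np.ndarray:
    """Framewise triangulation of paired 2D tracks, shape (n, 2) each."""
    px_a = np.atleast_2d(np.asarray(px_a, float))
    px_b = np.atleast_2d(np.asarray(px_b, float))
    if px_a.shape != px_b.shape:
        raise ValueError("paired tracks must have identical shapes")
    return np.array([triangulate_point(a, b, rig) for a, b in zip(px_a, px_b)])


def look_at_camera(
    center_mm: np.ndarray,
    target_mm: np.ndarray,
    focal_px: float = 1400.0,
    principal_px: tuple[float, float] = (960.0, 540.0),
) -> CameraModel:
    """Camera at ``center_mm`` with the optical axis through ``target_mm``."""
    center = np.asarray(center_mm, dtype=float)
    forward = np.asarray(target_mm, dtype=float) - center
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 1.0, 0.0])
    if abs(forward @ up) > 0.999:
        up = np.array([1.0, 0.0, 0.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    R = np.vstack([right, down, forward])  # rows: camera x, y, z in world
    t = -R @ center
    K = np.array(
        [[focal_px, 0.0, principal_px[0]], [0.0, focal_px, principal_px[1]], [0.0, 0.0, 1.0]]
    )
    return CameraModel(K, R, t)


def default_rig(
    baseline_mm: float = 450.0,
    height_mm: float = 1100.0,
    standoff_mm: float = 900.0,
    target_mm: tuple[float, float, float] = (0.0, 300.0, 0.0),
) -> StereoRig:
    """Synthetic rig mimicking the acquisition geometry: two cameras 110 cm
    above the ground, spaced 45 cm, aimed at the plant."""
    target = np.asarray(target_mm, dtype=float)
    cam_a = look_at_camera(np.array([-baseline_mm / 2, height_mm, -standoff_mm]), target)
    cam_b = look_at_camera(np.array([+baseline_mm / 2, height_mm, -standoff_mm]), target)
    return StereoRig(cam_a, cam_b)
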