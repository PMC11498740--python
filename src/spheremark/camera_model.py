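"""Pinhole camera model with Brown–Conrady lens distortion.

A camera is an intrinsic block (focal lengths, principal point, distortion
coefficients, sensor size) plus a rigid pose mapping world coordinates into
the camera frame, ``X_cam = R @ X_world + t``.  The camera frame is
right-handed with +z pointing forward (in front of the lens); pixel
coordinates have their origin at the top-left corner, x right, y down,
0-based, with integer coordinates at pixel centers.

The two primitives everything else builds on are :func:`project` (world
point -> pixel) and :func:`back_project` (pixel -> viewing ray), inverse to
each other up to the depth lost in projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoConvergence, NonPositiveDepth

__all__ = [
    "Intrinsics",
    "Pose",
    "Camera",
    "Ray",
    "camera_center",
    "distort",
    "undistort",
    "project",
    "back_project",
]


@dataclass(frozen=True)
class Intrinsics:
    """Camera-internal parameters.

    fx, fy, cx, cy are in pixels; k1, k2, k3 (radial) and p1, p2
    (tangential) are the dimensionless Brown–Conrady coefficients and
    default to zero (no distortion).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths fx, fy must be positive")
        if not (int(self.width) > 0 and int(self.height) > 0):
            raise ValueError("image width and height must be positive")


@dataclass(frozen=True)
class Pose:
    """World-to-camera rigid transform: ``X_cam = R @ X_world + t``.

    R must be a proper rotation (orthonormal, det +1); t is in model units.
    The camera center in world coordinates is ``C = -R.T @ t``.
    """

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float).reshape(3, 3)
        t = np.asarray(self.t, dtype=float).reshape(3)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "t", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("R must have determinant +1 (proper rotation)")
        if not np.all(np.isfinite(t)):
            raise ValueError("t must be finite")


@dataclass(frozen=True)
class Camera:
    """One node of the image sphere: an oriented, calibrated photograph."""

    id: str
    image_ref: str
    intrinsics: Intrinsics
    pose: Pose


@dataclass(frozen=True)
class Ray:
    """A half-line from a camera center through a pixel's viewing direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.origin, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-12:
            raise ValueError("ray direction must be unit-norm within 1e-12")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d)

    def point_at(self, s: float) -> np.ndarray:
        return self.origin + s * self.direction

    def distance_to(self, point: np.ndarray) -> float:
        """Orthogonal distance from a point to the (infinite) ray line."""
        v = np.asarray(point, dtype=float) - self.origin
        return float(np.linalg.norm(v - (v @ self.direction) * self.direction))


def camera_center(pose: Pose) -> np.ndarray:
    """World-space camera center ``C = -R.T @ t`` (so that R C + t = 0)."""
    return -pose.R.T @ pose.t


def distort(intr: Intrinsics, p_norm: np.ndarray) -> np.ndarray:
    """Apply Brown–Conrady distortion to normalized image coordinates.

    With r^2 = x^2 + y^2, the radial factor is (1 + k1 r^2 + k2 r^4 + k3 r^6)
    and the tangential shift is (2 p1 x y + p2 (r^2 + 2 x^2),
    p1 (r^2 + 2 y^2) + 2 p2 x y).  With all coefficients zero this is the
    identity map.
    """
    x, y = float(p_norm[0]), float(p_norm[1])
    r2 = x * x + y * y
    radial = 1.0 + r2 * (intr.k1 + r2 * (intr.k2 + r2 * intr.k3))
    x_d = x * radial + 2.0 * intr.p1 * x * y + intr.p2 * (r2 + 2.0 * x * x)
    y_d = y * radial + intr.p1 * (r2 + 2.0 * y * y) + 2.0 * intr.p2 * x * y
    return np.array([x_d, y_d])


def _pixel_to_distorted_norm(intr: Intrinsics, pixel: np.ndarray) -> np.ndarray:
    return np.array(
        [
            (float(pixel[0]) - intr.cx) / intr.fx,
            (float(pixel[1]) - intr.cy) / intr.fy,
        ]
    )


def undistort(
    intr: Intrinsics,
    pixel: np.ndarray,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Normalized undistorted coordinates of a pixel.

    Inverts :func:`distort` by fixed-point iteration
    ``p <- p_d - (distort(p) - p)`` starting from the distorted value; for
    the moderate coefficients of real lenses this contracts quickly.

    Raises
    ------
    NoConvergence
        If the update does not fall below ``tol`` within ``max_iter``
        iterations (pathologically strong coefficients).
    """
    p_d = _pixel_to_distorted_norm(intr, pixel)
    if intr.k1 == intr.k2 == intr.k3 == intr.p1 == intr.p2 == 0.0:
        return p_d
    p = p_d.copy()
    for _ in range(max_iter):
        p_new = p_d - (distort(intr, p) - p)
        step = np.max(np.abs(p_new - p))
        p = p_new
        if step < tol:
            return p
    raise NoConvergence(
        f"undistortion did not converge to {tol} in {max_iter} iterations"
    )


def project(camera: Camera, point_world: np.ndarray) -> np.ndarray:
    """Project a world point into pixel coordinates.

    Raises
    ------
    NonPositiveDepth
        If the point is on or behind the camera plane (z_cam <= 0).
    """
    X = np.asarray(point_world, dtype=float).reshape(3)
    X_cam = camera.pose.R @ X + camera.pose.t
    z = X_cam[2]
    if z <= 0:
        raise NonPositiveDepth(f"point has non-positive depth z_cam={z!r}")
    p_norm = X_cam[:2] / z
    x_d, y_d = distort(camera.intrinsics, p_norm)
    intr = camera.intrinsics
    return np.array([intr.fx * x_d + intr.cx, intr.fy * y_d + intr.cy])


def back_project(camera: Camera, pixel: np.ndarray) -> Ray:
    """Back-project a pixel to the world-space viewing ray through it.

    The ray starts at the camera center and passes through the pixel on the
    image plane; any scene point imaging onto this pixel lies on the ray.
    """
    x_u, y_u = undistort(camera.intrinsics, pixel)
    d_cam = np.array([x_u, y_u, 1.0])
    d_world = camera.pose.R.T @ d_cam
    d_world /= np.linalg.norm(d_world)
    return Ray(origin=camera_center(camera.pose), direction=d_world)
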