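"""Least-squares triangulation of a landmark from >= 2 pixel observations.

Each observation of a landmark back-projects to a ray through the observing
camera; with noise the rays do not meet, so the landmark is taken as the 3D
point minimizing the sum of squared orthogonal distances to all rays.  That
minimizer has a closed form: with unit directions d_i and origins o_i,

    sum_i (I - d_i d_i^T) x = sum_i (I - d_i d_i^T) o_i

is a 3x3 symmetric positive semi-definite linear system.  It is singular
exactly when all rays are parallel, which is reported as degenerate
geometry.  An optional Gauss–Newton polish minimizing pixel reprojection
error is available behind a flag; the linear solve is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .camera_model import Camera, Ray, back_project, project
from .errors import DegenerateGeometry, NonPositiveDepth, TooFewRays, UnknownCamera

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .project_io import Project

__all__ = [
    "Observation",
    "TriangulationResult",
    "triangulate_rays",
    "triangulate_landmark",
    "reprojection_error",
]

#: relative eigenvalue cutoff below which the normal matrix is treated as
#: rank deficient (near-parallel rays)
DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class Observation:
    """One 2D pick of a landmark: the camera it was made in and the pixel."""

    camera_id: str
    pixel: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "pixel", np.asarray(self.pixel, dtype=float).reshape(2)
        )


@dataclass(frozen=True)
class TriangulationResult:
    """Triangulated 3D point with its per-view consistency diagnostic."""

    point: np.ndarray
    rms_reprojection_error: float
    n_views: int


def triangulate_rays(rays: Sequence[Ray]) -> np.ndarray:
    """Closest point to a set of rays in the least-squares sense.

    Solves ``sum_i (I - d_i d_i^T) x = sum_i (I - d_i d_i^T) o_i`` for x.
    The accumulation is symmetric in the rays, so their order is irrelevant.

    Raises
    ------
    TooFewRays
        Fewer than two rays.
    DegenerateGeometry
        All rays (near-)parallel: smallest eigenvalue of the system matrix
        below ``DEGENERACY_RTOL`` times the largest.
    """
    if len(rays) < 2:
        raise TooFewRays(f"need >= 2 rays, got {len(rays)}")
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for ray in rays:
        P = np.eye(3) - np.outer(ray.direction, ray.direction)
        A += P
        b += P @ ray.origin
    eigvals = np.linalg.eigvalsh(A)
    if eigvals[0] < DEGENERACY_RTOL * eigvals[-1]:
        raise DegenerateGeometry(
            "rays are (near-)parallel; triangulation is ill-posed"
        )
    return np.linalg.solve(A, b)


def _resolve(project_: "Project", obs: Observation) -> Camera:
    cam = project_.camera(obs.camera_id)
    if cam is None:
        raise UnknownCamera(f"observation references unknown camera {obs.camera_id!r}")
    return cam


def reprojection_error(
    project_: "Project",
    observations: Sequence[Observation],
    point: np.ndarray,
) -> float:
    """RMS pixel distance between observations and the reprojected point."""
    point = np.asarray(point, dtype=float).reshape(3)
    sq = 0.0
    for obs in observations:
        cam = _resolve(project_, obs)
        reproj = project(cam, point)
        sq += float(np.sum((reproj - obs.pixel) ** 2))
    return float(np.sqrt(sq / len(observations)))


def _refine_gauss_newton(
    project_: "Project",
    observations: Sequence[Observation],
    x0: np.ndarray,
    max_iter: int = 20,
) -> np.ndarray:
    """Polish a 3D point by minimizing reprojection error (numeric Jacobian)."""
    x = x0.copy()
    cams = [_resolve(project_, o) for o in observations]
    pixels = np.array([o.pixel for o in observations])

    def residuals(p: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [project(c, p) - px for c, px in zip(cams, pixels)]
        )

    h = 1e-6 * max(1.0, float(np.linalg.norm(x0)))
    for _ in range(max_iter):
        try:
            r = residuals(x)
            J = np.empty((r.size, 3))
            for j in range(3):
                dx = np.zeros(3)
                dx[j] = h
                J[:, j] = (residuals(x + dx) - r) / h
        except NonPositiveDepth:  # stepped behind a camera; keep last iterate
            break
        step, *_ = np.linalg.lstsq(J, -r, rcond=None)
        x = x + step
        if np.linalg.norm(step) < 1e-12:
            break
    return x


def triangulate_landmark(
    project_: "Project",
    observations: Sequence[Observation],
    *,
    refine: bool = False,
) -> TriangulationResult:
    """Triangulate one landmark from its pixel observations.

    Back-projects every observation to a ray, intersects the rays in the
    least-squares sense, and reports the RMS reprojection error of the
    solution over the observing views.  With ``refine=True`` the linear
    solution is polished by a short Gauss–Newton descent on reprojection
    error (at most 20 iterations).

    Raises
    ------
    TooFewRays, DegenerateGeometry, UnknownCamera
    """
    if len(observations) < 2:
        raise TooFewRays(
            f"a landmark needs observations in >= 2 images, got {len(observations)}"
        )
    rays = [back_project(_resolve(project_, o), o.pixel) for o in observations]
    point = triangulate_rays(rays)
    if refine:
        point = _refine_gauss_newton(project_, observations, point)
    err = reprojection_error(project_, observations, point)
    return TriangulationResult(
        point=point, rms_reprojection_error=err, n_views=len(observations)
    )
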