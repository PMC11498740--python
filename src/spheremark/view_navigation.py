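"""Headless pseudo-3D viewer logic.

The acquired photographs sit on a sphere around the specimen.  Navigation
means: given a query viewing direction, return the camera whose direction
from the sphere center is angularly closest, so the caller can display that
photograph.  Named standard views (frontal, posterior, superior, inferior,
left/right lateral) are a small mapping from view name to camera id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .camera_model import camera_center
from .errors import (
    DegenerateSphere,
    EmptyProject,
    LatitudeOutOfRange,
    ZeroVectorQuery,
)

if TYPE_CHECKING:  # pragma: no cover
    from .project_io import Project

__all__ = [
    "STANDARD_VIEW_NAMES",
    "ViewSphere",
    "StandardViews",
    "build_sphere",
    "nearest_view",
    "direction_from_angles",
]

STANDARD_VIEW_NAMES = (
    "frontal",
    "posterior",
    "superior",
    "inferior",
    "left_lateral",
    "right_lateral",
)


@dataclass(frozen=True)
class ViewSphere:
    """Unit directions from the sphere center to every camera."""

    center: np.ndarray
    camera_ids: tuple[str, ...]
    directions: np.ndarray  # shape (n, 3), rows unit-norm


@dataclass
class StandardViews:
    """Mapping from canonical anatomical view names to camera ids."""

    views: dict[str, str] = field(default_factory=dict)

    def assign(self, name: str, camera_id: str) -> None:
        if name not in STANDARD_VIEW_NAMES:
            raise KeyError(
                f"unknown view {name!r}; expected one of {STANDARD_VIEW_NAMES}"
            )
        self.views[name] = camera_id

    def get(self, name: str) -> str | None:
        return self.views.get(name)


def build_sphere(project_: "Project") -> ViewSphere:
    """Build the view sphere of a project.

    The center is the centroid of the camera centers; each camera's stored
    direction is the unit vector from the center to that camera.

    Raises
    ------
    EmptyProject
        No cameras in the project.
    DegenerateSphere
        A camera coincides with the centroid (zero-length direction) — e.g.
        a single-camera project.
    """
    if not project_.cameras:
        raise EmptyProject("project has no cameras")
    ids = tuple(cam.id for cam in project_.cameras)
    centers = np.array([camera_center(cam.pose) for cam in project_.cameras])
    center = centers.mean(axis=0)
    offsets = centers - center
    norms = np.linalg.norm(offsets, axis=1)
    if np.any(norms < 1e-12):
        raise DegenerateSphere(
            "a camera center coincides with the sphere center"
        )
    return ViewSphere(
        center=center, camera_ids=ids, directions=offsets / norms[:, None]
    )


def nearest_view(sphere: ViewSphere, query: np.ndarray) -> str:
    """Camera id of the view angularly closest to the query direction.

    Maximizes the dot product with the stored unit directions (equivalently
    minimizes the angle); the query is normalized, so its magnitude is
    irrelevant.  Ties go to the lexicographically smallest camera id so the
    result is deterministic.
    """
    q = np.asarray(query, dtype=float).reshape(3)
    n = np.linalg.norm(q)
    if n < 1e-15:
        raise ZeroVectorQuery("query direction must be non-zero")
    dots = sphere.directions @ (q / n)
    best = np.max(dots)
    candidates = [
        cid for cid, d in zip(sphere.camera_ids, dots) if d >= best - 1e-12
    ]
    return min(candidates)


def direction_from_angles(longitude_deg: float, latitude_deg: float) -> np.ndarray:
    """Unit vector for spherical angles (math convention).

    (lon, lat) -> (cos lat cos lon, cos lat sin lon, sin lat), angles in
    degrees, latitude in [-90, 90].
    """
    if not -90.0 <= latitude_deg <= 90.0:
        raise LatitudeOutOfRange(f"latitude {latitude_deg} outside [-90, 90]")
    lon = np.deg2rad(longitude_deg)
    lat = np.deg2rad(latitude_deg)
    return np.array(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )
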