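"""Ground-truth synthetic worlds for end-to-end testing.

Emulates a sphere-of-images acquisition rig: cameras on a Fibonacci
lattice over a sphere, all aimed at the origin, imaging a virtual specimen
(random points inside an ellipsoid) plus a two-point calibration token of
exactly known physical separation.  Every pixel observation is a true
projection plus optional isotropic Gaussian noise, so triangulation,
calibration and measurement can be validated against exact ground truth.

The default preset loosely mirrors a macro rig (20-megapixel-class sensor
behind a long lens) but the geometry under test only depends on ratios:
specimen extent versus sphere radius sets the field angle, focal length in
pixels sets the magnification of triangulation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .camera_model import Camera, Intrinsics, Pose, project
from .errors import InvalidSpec, NonPositiveDepth
from .measurement import (
    DEFAULT_TOKEN_MM,
    Landmark,
    ScaleCalibration,
    apply_scale,
    distance,
    scale_factor,
)
from .project_io import Project
from .triangulation import Observation, triangulate_landmark
from .view_navigation import StandardViews

__all__ = ["SceneSpec", "GroundTruth", "default_intrinsics", "generate_scene",
           "recovery_report", "pairwise_distance_errors"]

TOKEN_LABELS = ("TOKEN_A", "TOKEN_B")


def default_intrinsics() -> Intrinsics:
    """20 Mpx-class sensor (5472x3648) behind a long lens (~14500 px focal)."""
    return Intrinsics(
        fx=14500.0, fy=14500.0, cx=2736.0, cy=1824.0, width=5472, height=3648
    )


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic acquisition.

    Units: the world is in model units; ``mm_per_unit`` is the ground-truth
    scale that converts them to millimeters.  Defaults place 30 cameras at
    radius 50 around a specimen of extent 5 (a ~10 mm insect imaged from
    ~100 mm away at mm_per_unit=2), with the 6.69 mm token.
    """

    n_cameras: int = 30
    sphere_radius: float = 50.0
    n_points: int = 20
    specimen_extent: float = 5.0
    token_separation_mm: float = DEFAULT_TOKEN_MM
    mm_per_unit: float = 2.0
    pixel_noise_sigma: float = 0.0
    rng_seed: int = 0
    intrinsics: Intrinsics = field(default_factory=default_intrinsics)

    def __post_init__(self) -> None:
        if self.n_cameras < 2:
            raise InvalidSpec("n_cameras must be >= 2")
        if not self.sphere_radius > self.specimen_extent:
            raise InvalidSpec("sphere_radius must exceed specimen_extent")
        if self.pixel_noise_sigma < 0:
            raise InvalidSpec("pixel_noise_sigma must be >= 0")
        if not (self.token_separation_mm > 0 and self.mm_per_unit > 0):
            raise InvalidSpec("token separation and scale must be positive")
        if self.n_points < 1:
            raise InvalidSpec("n_points must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    points: dict[str, np.ndarray]  # label -> true position, model units
    mm_per_unit: float
    token_labels: tuple[str, str] = TOKEN_LABELS


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-angle spiral lattice).

    The raw lattice's centroid sits O(1/n) off the sphere center; a short
    recenter-and-renormalize iteration pulls it onto the center so camera
    centers are exactly equidistant from their centroid.
    """
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    d = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    for _ in range(200):
        mean = d.mean(axis=0)
        if np.linalg.norm(mean) < 1e-13:
            break
        d = d - mean
        d /= np.linalg.norm(d, axis=1)[:, None]
    return d


def _look_at_pose(center: np.ndarray, target: np.ndarray) -> Pose:
    """World-to-camera pose for a camera at `center` aimed at `target`.

    +z (forward) points at the target; the up reference is world +z with a
    fallback for the poles.
    """
    fwd = target - center
    fwd = fwd / np.linalg.norm(fwd)
    up_ref = np.array([0.0, 0.0, 1.0])
    if abs(fwd @ up_ref) > 0.999:
        up_ref = np.array([0.0, 1.0, 0.0])
    right = np.cross(fwd, up_ref)
    right /= np.linalg.norm(right)
    down = np.cross(fwd, right)
    R = np.vstack([right, down, fwd])  # rows = camera axes in world coords
    return Pose(R=R, t=-R @ center)


def generate_scene(spec: SceneSpec) -> tuple[Project, GroundTruth]:
    """Generate a project with observations plus its ground truth.

    Cameras sit on a Fibonacci lattice of radius ``sphere_radius`` looking
    at the origin.  Specimen points are sampled uniformly inside an
    ellipsoid of semi-axes (1, 0.75, 0.5) x ``specimen_extent``; the token
    pair is placed symmetrically about the origin at exactly
    ``token_separation_mm / mm_per_unit`` model units.  Each point is
    observed in every camera where it projects in-frame with positive
    depth, with i.i.d. Gaussian pixel noise of ``pixel_noise_sigma``.

    Deterministic: the same spec (including seed) yields identical output.
    """
    rng = np.random.default_rng(spec.rng_seed)
    dirs = _fibonacci_sphere(spec.n_cameras)
    cameras = [
        Camera(
            id=f"cam_{i:03d}",
            image_ref=f"images/cam_{i:03d}.jpg",
            intrinsics=spec.intrinsics,
            pose=_look_at_pose(spec.sphere_radius * d, np.zeros(3)),
        )
        for i, d in enumerate(dirs)
    ]

    semi_axes = spec.specimen_extent * np.array([1.0, 0.75, 0.5])
    points: dict[str, np.ndarray] = {}
    n = 0
    while n < spec.n_points:  # rejection-sample the ellipsoid interior
        p = rng.uniform(-1.0, 1.0, size=3)
        if p @ p <= 1.0:
            points[f"P{n:03d}"] = semi_axes * p
            n += 1
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    half = 0.5 * spec.token_separation_mm / spec.mm_per_unit
    points[TOKEN_LABELS[0]] = half * axis
    points[TOKEN_LABELS[1]] = -half * axis

    landmarks = []
    w, h = spec.intrinsics.width, spec.intrinsics.height
    for label, pt in points.items():
        obs = []
        for cam in cameras:
            try:
                px = project(cam, pt)
            except NonPositiveDepth:
                continue
            if spec.pixel_noise_sigma > 0:
                px = px + rng.normal(scale=spec.pixel_noise_sigma, size=2)
            if 0.0 <= px[0] <= w - 1 and 0.0 <= px[1] <= h - 1:
                obs.append(Observation(camera_id=cam.id, pixel=px))
        landmarks.append(Landmark(label=label, observations=tuple(obs)))

    project_ = Project(
        cameras=cameras,
        landmarks=landmarks,
        scale_calibration=ScaleCalibration(
            landmark_a=TOKEN_LABELS[0],
            landmark_b=TOKEN_LABELS[1],
            known_distance_mm=spec.token_separation_mm,
        ),
        standard_views=StandardViews(),
    )
    return project_, GroundTruth(points=points, mm_per_unit=spec.mm_per_unit)


def recovery_report(project_: Project, truth: GroundTruth) -> pd.DataFrame:
    """Triangulate every landmark and tabulate errors against ground truth.

    Runs the full pipeline — triangulation, scale calibration on the token
    pair, rescaling — and returns one row per landmark with the 3D error in
    model units and mm, plus columns for the recovered scale.  Pairwise
    distance errors are summarized by the caller from the positions.
    """
    triangulated: dict[str, np.ndarray] = {}
    for lm in project_.landmarks:
        if len(lm.observations) < 2:
            continue
        res = triangulate_landmark(project_, lm.observations)
        triangulated[lm.label] = res.point
        project_.replace_landmark(
            Landmark(label=lm.label, observations=lm.observations, position=res.point)
        )

    a, b = truth.token_labels
    s = scale_factor(
        distance(triangulated[a], triangulated[b], rounded=False),
        project_.scale_calibration.known_distance_mm,
    )
    project_.landmarks[:] = apply_scale(project_.landmarks, s)

    rows = []
    for label, est in triangulated.items():
        err = float(np.linalg.norm(est - truth.points[label]))
        rows.append(
            {
                "label": label,
                "error_units": err,
                "error_mm": err * truth.mm_per_unit,
                "n_views": len(project_.landmark(label).observations),
                "scale_mm_per_unit": s,
            }
        )
    return pd.DataFrame(rows)


def pairwise_distance_errors(project_: Project, truth: GroundTruth) -> pd.DataFrame:
    """Measured-vs-true inter-landmark distances in mm, one row per pair.

    Expects a project already triangulated and rescaled (as left behind by
    :func:`recovery_report`).  The relative error column divides the mm
    error by the true mm distance.
    """
    labeled = [
        lm for lm in project_.landmarks if lm.position_mm is not None
    ]
    rows = []
    for i, la in enumerate(labeled):
        for lb in labeled[i + 1:]:
            true_mm = truth.mm_per_unit * float(
                np.linalg.norm(truth.points[la.label] - truth.points[lb.label])
            )
            meas_mm = distance(la.position_mm, lb.position_mm, rounded=False)
            rows.append(
                {
                    "pair": f"{la.label}/{lb.label}",
                    "true_mm": true_mm,
                    "measured_mm": meas_mm,
                    "error_mm": meas_mm - true_mm,
                    "rel_error": abs(meas_mm - true_mm) / true_mm,
                }
            )
    return pd.DataFrame(rows)
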