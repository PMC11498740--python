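"""Project file, calibration import, and landmark CSV input/output.

The canonical on-disk representation is a single versioned JSON document
holding the cameras (intrinsics + poses), landmarks, optional scale
calibration and standard-view assignments.  Photographs are referenced by
relative path and never opened: all geometry works on pixel coordinates
supplied as observations.

Photogrammetry packages typically export two separate files — one with the
camera-internal (intrinsic) parameters per sensor and one with the per-image
(extrinsic) poses.  :func:`import_calibration` reads that two-file layout
and converts it into project cameras; a dialect flag declares whether the
extrinsic rotations map world-to-camera (our convention) or camera-to-world
(in which case they are inverted on import).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .camera_model import Camera, Intrinsics, Pose
from .errors import (
    MissingIntrinsics,
    NothingToExport,
    ParseError,
    SchemaError,
    VersionUnsupported,
)
from .measurement import Landmark, ScaleCalibration, round_mm
from .triangulation import Observation
from .view_navigation import StandardViews

__all__ = [
    "SCHEMA_VERSION",
    "Project",
    "read_project",
    "write_project",
    "import_calibration",
    "export_landmarks_csv",
    "read_landmarks_csv",
    "read_observations_csv",
    "write_observations_csv",
]

SCHEMA_VERSION = 1

PathLike = Union[str, Path]

_INTRINSICS_FIELDS = (
    "fx", "fy", "cx", "cy", "width", "height", "k1", "k2", "k3", "p1", "p2",
)


@dataclass
class Project:
    """An oriented-image project: the sphere of cameras plus its landmarks."""

    cameras: list[Camera] = field(default_factory=list)
    landmarks: list[Landmark] = field(default_factory=list)
    scale_calibration: Optional[ScaleCalibration] = None
    standard_views: StandardViews = field(default_factory=StandardViews)
    image_dir: str = "."

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.id for c in self.cameras]
        if len(set(ids)) != len(ids):
            raise SchemaError("cameras: duplicate camera id")
        labels = [lm.label for lm in self.landmarks]
        if len(set(labels)) != len(labels):
            raise SchemaError("landmarks: duplicate landmark label")
        known = set(ids)
        for lm in self.landmarks:
            for obs in lm.observations:
                if obs.camera_id not in known:
                    raise SchemaError(
                        f"landmarks[{lm.label!r}].observations: "
                        f"unknown camera id {obs.camera_id!r}"
                    )
        for name, cid in self.standard_views.views.items():
            if cid not in known:
                raise SchemaError(
                    f"standard_views[{name!r}]: unknown camera id {cid!r}"
                )

    def camera(self, camera_id: str) -> Optional[Camera]:
        for cam in self.cameras:
            if cam.id == camera_id:
                return cam
        return None

    def landmark(self, label: str) -> Optional[Landmark]:
        for lm in self.landmarks:
            if lm.label == label:
                return lm
        return None

    def replace_landmark(self, updated: Landmark) -> None:
        for i, lm in enumerate(self.landmarks):
            if lm.label == updated.label:
                self.landmarks[i] = updated
                return
        self.landmarks.append(updated)


# --- JSON serialization ---------------------------------------------------


def _camera_to_dict(cam: Camera) -> dict:
    return {
        "id": cam.id,
        "image_ref": cam.image_ref,
        "intrinsics": {k: getattr(cam.intrinsics, k) for k in _INTRINSICS_FIELDS},
        "pose": {"R": cam.pose.R.tolist(), "t": cam.pose.t.tolist()},
    }


def _camera_from_dict(d: dict, where: str) -> Camera:
    try:
        intr = Intrinsics(**d["intrinsics"])
        pose = Pose(R=np.array(d["pose"]["R"]), t=np.array(d["pose"]["t"]))
        return Camera(
            id=d["id"], image_ref=d.get("image_ref", ""), intrinsics=intr, pose=pose
        )
    except KeyError as e:
        raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e
    except (TypeError, ValueError) as e:
        raise SchemaError(f"{where}: {e}") from e


def _landmark_to_dict(lm: Landmark) -> dict:
    return {
        "label": lm.label,
        "color": lm.color,
        "observations": [
            {"camera_id": o.camera_id, "pixel": o.pixel.tolist()}
            for o in lm.observations
        ],
        "position": None if lm.position is None else lm.position.tolist(),
        "position_mm": None if lm.position_mm is None else lm.position_mm.tolist(),
    }


def _landmark_from_dict(d: dict, where: str) -> Landmark:
    try:
        return Landmark(
            label=d["label"],
            color=d.get("color", "#ff0000"),
            observations=tuple(
                Observation(camera_id=o["camera_id"], pixel=np.array(o["pixel"]))
                for o in d.get("observations", [])
            ),
            position=None if d.get("position") is None else np.array(d["position"]),
            position_mm=(
                None if d.get("position_mm") is None else np.array(d["position_mm"])
            ),
        )
    except KeyError as e:
        raise SchemaError(f"{where}: missing key {e.args[0]!r}") from e


def write_project(project: Project, path: PathLike) -> None:
    """Write a project as versioned JSON (full float precision, sorted keys)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "image_dir": project.image_dir,
        "cameras": [_camera_to_dict(c) for c in project.cameras],
        "landmarks": [_landmark_to_dict(lm) for lm in project.landmarks],
        "scale_calibration": (
            None
            if project.scale_calibration is None
            else {
                "landmark_a": project.scale_calibration.landmark_a,
                "landmark_b": project.scale_calibration.landmark_b,
                "known_distance_mm": project.scale_calibration.known_distance_mm,
                "scale": project.scale_calibration.scale,
            }
        ),
        "standard_views": dict(sorted(project.standard_views.views.items())),
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_project(path: PathLike) -> Project:
    """Read a project JSON document, validating schema and references.

    Raises
    ------
    SchemaError
        Malformed document; the message names the offending field.
    VersionUnsupported
        Unknown ``schema_version``.
    """
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise SchemaError(f"not valid JSON: {e}") from e
    if not isinstance(doc, dict):
        raise SchemaError("top level: expected a JSON object")
    version = doc.get("schema_version")
    if version is None:
        raise SchemaError("missing key 'schema_version'")
    if version != SCHEMA_VERSION:
        raise VersionUnsupported(
            f"schema_version {version!r} not supported (expected {SCHEMA_VERSION})"
        )
    if "cameras" not in doc:
        raise SchemaError("missing key 'cameras'")
    cameras = [
        _camera_from_dict(d, f"cameras[{i}]") for i, d in enumerate(doc["cameras"])
    ]
    landmarks = [
        _landmark_from_dict(d, f"landmarks[{i}]")
        for i, d in enumerate(doc.get("landmarks", []))
    ]
    sc = doc.get("scale_calibration")
    calibration = (
        None
        if sc is None
        else ScaleCalibration(
            landmark_a=sc["landmark_a"],
            landmark_b=sc["landmark_b"],
            known_distance_mm=sc["known_distance_mm"],
            scale=sc.get("scale"),
        )
    )
    views = StandardViews(views=dict(doc.get("standard_views", {})))
    return Project(
        cameras=cameras,
        landmarks=landmarks,
        scale_calibration=calibration,
        standard_views=views,
        image_dir=doc.get("image_dir", "."),
    )


# --- two-file calibration import ------------------------------------------


def import_calibration(
    intrinsics_file: PathLike,
    extrinsics_file: PathLike,
    *,
    dialect: str = "world_to_camera",
) -> list[Camera]:
    """Build cameras from a two-file photogrammetry calibration export.

    ``intrinsics_file`` is a JSON object mapping sensor ids to intrinsic
    parameter dicts (fx, fy, cx, cy, width, height and optional k1..k3,
    p1, p2).  ``extrinsics_file`` is a CSV with one row per image:

        camera_id,image_ref,sensor_id,r11,...,r33,tx,ty,tz

    With ``dialect="world_to_camera"`` the 3x3 block and translation are
    taken as-is (X_cam = R X + t).  With ``dialect="camera_to_world"`` the
    row carries the camera-to-world rotation and the camera center C, and
    is inverted on import (R = R_cw^T, t = -R C).

    Raises
    ------
    ParseError, MissingIntrinsics
    """
    if dialect not in ("world_to_camera", "camera_to_world"):
        raise ParseError(f"unknown extrinsics dialect {dialect!r}")
    try:
        sensors = json.loads(Path(intrinsics_file).read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ParseError(f"intrinsics file is not valid JSON: {e}") from e
    if not isinstance(sensors, dict):
        raise ParseError("intrinsics file must be a JSON object of sensors")
    intr_by_id = {}
    for sid, d in sensors.items():
        try:
            intr_by_id[sid] = Intrinsics(**d)
        except (TypeError, ValueError) as e:
            raise ParseError(f"intrinsics[{sid!r}]: {e}") from e

    try:
        table = pd.read_csv(extrinsics_file, float_precision="round_trip")
    except Exception as e:
        raise ParseError(f"extrinsics file unreadable: {e}") from e
    needed = (
        ["camera_id", "image_ref", "sensor_id"]
        + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
        + ["tx", "ty", "tz"]
    )
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ParseError(f"extrinsics file missing columns: {missing}")

    cameras = []
    for _, row in table.iterrows():
        sid = row["sensor_id"]
        if sid not in intr_by_id:
            raise MissingIntrinsics(
                f"extrinsic record {row['camera_id']!r} references "
                f"undefined sensor id {sid!r}"
            )
        M = np.array(
            [[row[f"r{i}{j}"] for j in (1, 2, 3)] for i in (1, 2, 3)], dtype=float
        )
        v = np.array([row["tx"], row["ty"], row["tz"]], dtype=float)
        if dialect == "camera_to_world":
            R, t = M.T, -M.T @ v
        else:
            R, t = M, v
        try:
            pose = Pose(R=R, t=t)
        except ValueError as e:
            raise ParseError(f"extrinsic record {row['camera_id']!r}: {e}") from e
        cameras.append(
            Camera(
                id=str(row["camera_id"]),
                image_ref=str(row["image_ref"]),
                intrinsics=intr_by_id[sid],
                pose=pose,
            )
        )
    return cameras


# --- landmark and observation CSVs ----------------------------------------


def export_landmarks_csv(project: Project, path: PathLike) -> None:
    """Export triangulated landmarks as a plain coordinate table.

    Columns: ``label,x,y,z,x_mm,y_mm,z_mm``.  Model-unit coordinates are
    written at full precision; millimeter coordinates are rounded to
    0.01 mm.  Without a computed scale calibration the mm columns default
    to the model-unit values (s = 1).

    Raises
    ------
    NothingToExport
        No landmark has a triangulated position.
    """
    s = 1.0
    if project.scale_calibration is not None and project.scale_calibration.scale:
        s = project.scale_calibration.scale
    rows = []
    for lm in project.landmarks:
        if lm.position is None:
            continue
        mm = lm.position_mm if lm.position_mm is not None else s * lm.position
        rows.append(
            {
                "label": lm.label,
                "x": repr(float(lm.position[0])),
                "y": repr(float(lm.position[1])),
                "z": repr(float(lm.position[2])),
                "x_mm": f"{round_mm(mm[0]):.2f}",
                "y_mm": f"{round_mm(mm[1]):.2f}",
                "z_mm": f"{round_mm(mm[2]):.2f}",
            }
        )
    if not rows:
        raise NothingToExport("no landmark has a triangulated 3D position")
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path: PathLike) -> list[Landmark]:
    """Re-import a landmark export CSV (positions only, no observations)."""
    table = pd.read_csv(path, float_precision="round_trip")
    return [
        Landmark(
            label=str(row["label"]),
            position=np.array([row["x"], row["y"], row["z"]], dtype=float),
            position_mm=np.array(
                [row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float
            ),
        )
        for _, row in table.iterrows()
    ]


def read_observations_csv(path: PathLike) -> dict[str, list[Observation]]:
    """Read pixel observations grouped by landmark label.

    Expected columns: ``landmark_label,camera_id,px,py``.
    """
    table = pd.read_csv(path, float_precision="round_trip")
    needed = ["landmark_label", "camera_id", "px", "py"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ParseError(f"observation CSV missing columns: {missing}")
    out: dict[str, list[Observation]] = {}
    for _, row in table.iterrows():
        out.setdefault(str(row["landmark_label"]), []).append(
            Observation(
                camera_id=str(row["camera_id"]),
                pixel=np.array([row["px"], row["py"]], dtype=float),
            )
        )
    return out


def write_observations_csv(
    observations: dict[str, Sequence[Observation]], path: PathLike
) -> None:
    rows = [
        {
            "landmark_label": label,
            "camera_id": o.camera_id,
            "px": repr(float(o.pixel[0])),
            "py": repr(float(o.pixel[1])),
        }
        for label, obs in observations.items()
        for o in obs
    ]
    pd.DataFrame(rows, columns=["landmark_label", "camera_id", "px", "py"]).to_csv(
        path, index=False
    )
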