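"""Scale calibration and metric inter-landmark distances.

Camera poses coming out of bundle adjustment fix geometry only up to a
global scale, so triangulated coordinates are in arbitrary "model units".
A calibration token of known physical size imaged alongside the specimen —
here, by default, a hexagonal bead whose reference points are 6.69 mm
apart — pins the scale: s = known_distance / model_distance, in mm per
model unit.  All distances are then s * ||a - b||.

Distances are reported rounded to 0.01 mm (the precision of a digital
caliper) using half-up decimal rounding; internal arithmetic keeps full
precision and rounding is applied only at the reporting/CSV layer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from .errors import NonPositiveDistance
from .triangulation import Observation

__all__ = [
    "DEFAULT_TOKEN_MM",
    "ScaleCalibration",
    "Landmark",
    "scale_factor",
    "distance",
    "apply_scale",
    "round_mm",
]

#: reference separation of the default calibration bead, in mm
DEFAULT_TOKEN_MM = 6.69


def round_mm(value: float, decimals: int = 2) -> float:
    """Half-up decimal rounding for reported millimeter values.

    Python's built-in round() rounds half to even; caliper-style reporting
    rounds half up, and the decimal module makes that bit-stable.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScaleCalibration:
    """The token pair and known length defining mm-per-model-unit."""

    landmark_a: str
    landmark_b: str
    known_distance_mm: float
    scale: Optional[float] = None  # mm per model unit, once computed

    def __post_init__(self) -> None:
        if not self.known_distance_mm > 0:
            raise NonPositiveDistance("known_distance_mm must be positive")
        if self.scale is not None and not self.scale > 0:
            raise NonPositiveDistance("scale factor must be positive")


@dataclass(frozen=True)
class Landmark:
    """A labeled anatomical point with its picks and triangulated position."""

    label: str
    color: str = "#ff0000"
    observations: tuple[Observation, ...] = ()
    position: Optional[np.ndarray] = None  # model units
    position_mm: Optional[np.ndarray] = None  # after scale calibration

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", tuple(self.observations))
        for attr in ("position", "position_mm"):
            v = getattr(self, attr)
            if v is not None:
                object.__setattr__(
                    self, attr, np.asarray(v, dtype=float).reshape(3)
                )


def scale_factor(model_distance: float, known_distance_mm: float) -> float:
    """mm-per-model-unit factor: s = known_distance / model_distance."""
    if not model_distance > 0:
        raise NonPositiveDistance(f"model_distance must be > 0, got {model_distance}")
    if not known_distance_mm > 0:
        raise NonPositiveDistance(
            f"known_distance_mm must be > 0, got {known_distance_mm}"
        )
    return known_distance_mm / model_distance


def distance(
    a: np.ndarray, b: np.ndarray, s: float = 1.0, *, rounded: bool = True
) -> float:
    """Scaled Euclidean distance s * ||a - b||, in mm.

    With the default s=1 the result is in model units.  ``rounded=True``
    (the default) reports to 0.01 mm; pass ``rounded=False`` for the raw
    value when feeding further computation.
    """
    d = s * float(
        np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    )
    return round_mm(d) if rounded else d


def apply_scale(landmarks: Sequence[Landmark], s: float) -> list[Landmark]:
    """Attach ``position_mm = s * position`` to every triangulated landmark.

    Idempotent for a fixed s: position_mm is always recomputed from the
    model-unit position, never rescaled in place.
    """
    out = []
    for lm in landmarks:
        if lm.position is None:
            out.append(lm)
        else:
            out.append(replace(lm, position_mm=s * lm.position))
    return out
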