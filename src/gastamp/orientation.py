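"""Postoperative body positions as gravity directions in the eye frame.

Each named resting position fixes the "up" unit vector (opposite to gravity)
in the eye frame of :mod:`gastamp.geometry`.  "Prone with closed eyes"
accounts for the residual supraduction of the globe measured in patients who
superficially hold a strict prone position: the gaze axis stays tipped a
default 16.1 degrees above straight-down, rotating about the nasal-temporal
axis only (no torsion or adduction is modelled).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .errors import OffSurfaceError, UnknownPositionError
from .geometry import EyeModel, Handedness

__all__ = [
    "Position",
    "GravityFrame",
    "DEFAULT_SUPRADUCTION_DEG",
    "up_vector",
    "wall_inclination",
    "inclination_at_height",
]

#: residual upward gaze in the prone-with-closed-eyes posture, degrees
DEFAULT_SUPRADUCTION_DEG = 16.1


class Position(str, enum.Enum):
    SUPINE = "supine"
    SITTING = "sitting"
    PRONE = "prone"
    PRONE_CLOSED_EYES = "prone_closed_eyes"
    LOWER_TEMPORAL = "lower_temporal"
    LOWER_NASAL = "lower_nasal"


@dataclass(frozen=True)
class GravityFrame:
    """A position name with its up unit vector in the eye frame."""

    position: Position
    up: np.ndarray
    supraduction_deg: float | None = None

    def __post_init__(self) -> None:
        n = float(np.linalg.norm(self.up))
        if abs(n - 1.0) > 1e-12:
            raise ValueError(f"up vector must be unit length, |up| = {n}")


def up_vector(
    position: Position | str,
    supraduction_deg: float = DEFAULT_SUPRADUCTION_DEG,
    handedness: Handedness | str = Handedness.RIGHT,
) -> GravityFrame:
    """The up direction for a named position.

    supine -> +z (gaze up); sitting -> +y; prone -> -z; prone with closed
    eyes -> prone tipped ``supraduction_deg`` about the nasal-temporal axis so
    the superior retina gains height; lower temporal / lower nasal -> the
    named retina lowest, i.e. up along the opposite horizontal meridian.
    """
    try:
        pos = Position(position)
    except ValueError as exc:
        raise UnknownPositionError(f"unknown position {position!r}") from exc
    if not 0.0 <= supraduction_deg < 90.0:
        raise ValueError("supraduction angle must lie in [0, 90) degrees")
    nasal = 1.0 if Handedness(handedness) is Handedness.RIGHT else -1.0

    if pos is Position.SUPINE:
        up = np.array([0.0, 0.0, 1.0])
    elif pos is Position.SITTING:
        up = np.array([0.0, 1.0, 0.0])
    elif pos is Position.PRONE:
        up = np.array([0.0, 0.0, -1.0])
    elif pos is Position.PRONE_CLOSED_EYES:
        a = math.radians(supraduction_deg)
        up = np.array([0.0, math.sin(a), -math.cos(a)])
    elif pos is Position.LOWER_TEMPORAL:
        up = np.array([nasal, 0.0, 0.0])
    elif pos is Position.LOWER_NASAL:
        up = np.array([-nasal, 0.0, 0.0])
    else:  # pragma: no cover
        raise UnknownPositionError(position)
    up.setflags(write=False)
    return GravityFrame(
        position=pos,
        up=up,
        supraduction_deg=supraduction_deg if pos is Position.PRONE_CLOSED_EYES else None,
    )


def inclination_at_height(radius: float, height: float) -> float:
    """Signed wall tilt from vertical (deg) on a sphere at a given height.

    ``height`` is the point's height above the sphere centre along up.
    0 on the horizontal great circle; +90 at the lowest point (horizontal
    floor, wall opens upward); -90 at the top (overhanging ceiling).
    """
    s = min(1.0, max(-1.0, -height / radius))
    return math.degrees(math.asin(s))


def wall_inclination(model: EyeModel, point, up) -> float:
    """Signed tilt of the spherical wall's tangent plane from vertical, deg.

    Positive where the wall opens upward (bowl-like, below the sphere's
    horizontal great circle); negative where it overhangs.
    """
    p = np.asarray(point, dtype=float)
    u = np.asarray(up, dtype=float)
    r = float(np.linalg.norm(p))
    if abs(r - model.radius) > 1e-6 * model.radius:
        raise OffSurfaceError(
            f"point at radius {r:.6f} mm is not on the spherical wall "
            f"(R = {model.radius} mm)"
        )
    return inclination_at_height(model.radius, float(p @ u))
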