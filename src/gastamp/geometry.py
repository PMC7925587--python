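"""Truncated-sphere pseudophakic eye model and its retinal quadrant bands.

The vitreous cavity of a pseudophakic eye is idealised as a sphere of the
stated axial diameter with the anterior 2.5 mm cap removed (the flat face
standing in for the IOL plane).  Anatomical landmarks are placed by arc
distance along the wall: the ora serrata of each quadrant a fixed distance
posterior to the limbus (the truncation rim), and the equator a further
6.5 mm posterior.  The retinal "quadrant" measured throughout the package is
the band between ora serrata and equator, split at the 1:30 / 4:30 / 7:30 /
10:30 clock meridians, i.e. +/-45 degrees about each cardinal meridian.

Coordinate frame: origin at the sphere centre, +z anterior (gaze axis),
+y superior, +x nasal for a right eye (mirrored for a left eye).  Azimuth is
measured in the x-y plane from the superior meridian with nasal at +90 deg;
polar angle is measured from the anterior pole.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .errors import InvalidGeometryError, OutOfSurfaceError, ResolutionTooLowError

__all__ = [
    "Quadrant",
    "Handedness",
    "EyeModel",
    "RetinalRegion",
    "SurfaceMesh",
    "DEFAULT_ORA_ARC_MM",
    "DEFAULT_TRUNCATION_MM",
    "DEFAULT_EQUATOR_OFFSET_MM",
    "build_eye_model",
    "limbus_polar_angle",
    "arc_to_polar",
    "region",
    "region_area",
    "cavity_volume",
    "surface_mesh",
    "quadrant_azimuth_interval",
    "direction",
    "height_extremes_over_region",
]


class Quadrant(str, enum.Enum):
    SUPERIOR = "superior"
    NASAL = "nasal"
    INFERIOR = "inferior"
    TEMPORAL = "temporal"


class Handedness(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"


#: anterior cap removed to mimic the pseudophakic (IOL) anterior segment, mm
DEFAULT_TRUNCATION_MM = 2.5
#: ora serrata arc distance posterior to the limbus per quadrant, mm
DEFAULT_ORA_ARC_MM = {
    Quadrant.SUPERIOR: 7.4,
    Quadrant.NASAL: 5.5,
    Quadrant.TEMPORAL: 6.9,
    Quadrant.INFERIOR: 6.7,
}
#: equator arc distance posterior to the ora serrata (vortex-vein ampullae), mm
DEFAULT_EQUATOR_OFFSET_MM = 6.5

# azimuth of each quadrant's central meridian, degrees from superior
_QUADRANT_CENTER_AZ = {
    Quadrant.SUPERIOR: 0.0,
    Quadrant.NASAL: 90.0,
    Quadrant.INFERIOR: 180.0,
    Quadrant.TEMPORAL: 270.0,
}


@dataclass(frozen=True)
class EyeModel:
    """One truncated-sphere cavity with its anatomical landmarks (mm)."""

    diameter: float
    truncation_depth: float = DEFAULT_TRUNCATION_MM
    ora_arc: dict[Quadrant, float] = field(
        default_factory=lambda: dict(DEFAULT_ORA_ARC_MM)
    )
    equator_offset: float = DEFAULT_EQUATOR_OFFSET_MM
    handedness: Handedness = Handedness.RIGHT

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidGeometryError(f"diameter must be positive, got {self.diameter}")
        if not 0 < self.truncation_depth < self.radius:
            raise InvalidGeometryError(
                f"truncation depth {self.truncation_depth} mm must lie in "
                f"(0, radius={self.radius} mm)"
            )
        if self.equator_offset <= 0:
            raise InvalidGeometryError("equator offset must be positive")
        missing = set(Quadrant) - set(self.ora_arc)
        if missing:
            raise InvalidGeometryError(f"ora_arc missing quadrants: {missing}")
        lim = limbus_polar_angle(self)
        for q, arc in self.ora_arc.items():
            if arc <= 0:
                raise InvalidGeometryError(f"ora arc for {q.value} must be positive")
            eq_deg = lim + math.degrees((arc + self.equator_offset) / self.radius)
            if eq_deg >= 180.0:
                raise InvalidGeometryError(
                    f"{q.value} equator boundary at {eq_deg:.1f} deg reaches past "
                    "the posterior pole"
                )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def truncation_plane_z(self) -> float:
        """z of the flat anterior face; cavity occupies z <= this."""
        return self.radius - self.truncation_depth

    @property
    def nasal_axis(self) -> np.ndarray:
        """Unit vector pointing nasally (+x right eye, -x left eye)."""
        s = 1.0 if self.handedness is Handedness.RIGHT else -1.0
        return np.array([s, 0.0, 0.0])

    def summary(self) -> dict:
        lim = limbus_polar_angle(self)
        return {
            "diameter_mm": self.diameter,
            "radius_mm": self.radius,
            "truncation_depth_mm": self.truncation_depth,
            "truncation_plane_z_mm": self.truncation_plane_z,
            "handedness": self.handedness.value,
            "limbus_polar_angle_deg": lim,
            "cavity_volume_mm3": cavity_volume(self),
            "quadrant_bands": {
                q.value: {
                    "ora_arc_mm": self.ora_arc[q],
                    "polar_interval_deg": list(region(self, q).polar_interval),
                    "azimuth_interval_deg": list(region(self, q).azimuth_interval),
                    "area_mm2": region_area(self, region(self, q)),
                }
                for q in Quadrant
            },
        }

    def summary_json(self, **kwargs) -> str:
        return json.dumps(self.summary(), indent=2, **kwargs)


@dataclass(frozen=True)
class RetinalRegion:
    """One quadrant's band between ora serrata and equator.

    ``azimuth_interval`` is the 90-degree span about the quadrant meridian
    (degrees from superior, nasal at +90); ``polar_interval`` runs from the
    ora serrata to the equator boundary (degrees from the anterior pole).
    """

    quadrant: Quadrant
    azimuth_interval: tuple[float, float]
    polar_interval: tuple[float, float]

    def __post_init__(self) -> None:
        a0, a1 = self.azimuth_interval
        if not math.isclose(a1 - a0, 90.0, abs_tol=1e-9):
            raise InvalidGeometryError("quadrant azimuth span must be 90 degrees")
        p0, p1 = self.polar_interval
        if not (0.0 < p0 < p1 < 180.0):
            raise InvalidGeometryError(
                f"polar interval ({p0}, {p1}) must be increasing within (0, 180)"
            )


def build_eye_model(diameter_mm: float, **overrides) -> EyeModel:
    """Construct a validated eye model of the given axial diameter.

    The truncation depth and landmark arc distances are anatomical constants
    held fixed in mm across diameters; only the sphere diameter scales.
    Overrides (``truncation_depth``, ``ora_arc``, ``equator_offset``,
    ``handedness``) are accepted for sensitivity studies.
    """
    ora = overrides.pop("ora_arc", None)
    model = EyeModel(diameter=float(diameter_mm), **overrides)
    if ora is not None:
        ora = {Quadrant(k): float(v) for k, v in ora.items()}
        model = replace(model, ora_arc={**model.ora_arc, **ora})
    return model


def limbus_polar_angle(model: EyeModel) -> float:
    """Polar angle (deg, from the anterior pole) of the truncation rim."""
    return math.degrees(math.acos(1.0 - model.truncation_depth / model.radius))


def arc_to_polar(model: EyeModel, arc_mm: float) -> float:
    """Polar angle (deg) of a landmark ``arc_mm`` posterior to the limbus.

    Arc distances are converted along great-circle meridians, s = R * dtheta.
    """
    if arc_mm < 0:
        raise OutOfSurfaceError("arc distance must be non-negative")
    theta = limbus_polar_angle(model) + math.degrees(arc_mm / model.radius)
    if theta > 180.0:
        raise OutOfSurfaceError(
            f"arc {arc_mm} mm runs {theta - 180.0:.2f} deg past the posterior pole"
        )
    return theta


def quadrant_azimuth_interval(quadrant: Quadrant) -> tuple[float, float]:
    """The quadrant's 90-deg azimuth span (clock boundaries at 1:30 etc.)."""
    c = _QUADRANT_CENTER_AZ[Quadrant(quadrant)]
    return (c - 45.0, c + 45.0)


def region(model: EyeModel, quadrant: Quadrant | str) -> RetinalRegion:
    """The quadrant's band between its ora serrata and equator boundary."""
    q = Quadrant(quadrant)
    ora = model.ora_arc[q]
    return RetinalRegion(
        quadrant=q,
        azimuth_interval=quadrant_azimuth_interval(q),
        polar_interval=(
            arc_to_polar(model, ora),
            arc_to_polar(model, ora + model.equator_offset),
        ),
    )


def region_area(model: EyeModel, reg: RetinalRegion) -> float:
    """Exact spherical zone-sector area of a band, mm^2.

    A zone between polar angles theta1 < theta2 has area
    2 pi R^2 (cos theta1 - cos theta2); the quadrant takes its 90/360 sector.
    """
    a0, a1 = reg.azimuth_interval
    p0, p1 = np.radians(reg.polar_interval)
    frac = (a1 - a0) / 360.0
    return frac * 2.0 * math.pi * model.radius**2 * (math.cos(p0) - math.cos(p1))


def cavity_volume(model: EyeModel) -> float:
    """Cavity volume, mm^3: sphere minus the removed anterior cap."""
    R, t = model.radius, model.truncation_depth
    return 4.0 / 3.0 * math.pi * R**3 - math.pi * t**2 * (3.0 * R - t) / 3.0


def direction(theta_deg, azimuth_deg, nasal_axis=None):
    """Unit direction(s) on the sphere for polar angle / azimuth in degrees.

    Broadcasts over array inputs.  ``nasal_axis`` defaults to +x (right eye).
    """
    if nasal_axis is None:
        nasal_axis = np.array([1.0, 0.0, 0.0])
    th = np.radians(np.asarray(theta_deg, dtype=float))
    az = np.radians(np.asarray(azimuth_deg, dtype=float))
    st = np.sin(th)
    out = (
        np.multiply.outer(st * np.sin(az), nasal_axis)
        + np.multiply.outer(st * np.cos(az), np.array([0.0, 1.0, 0.0]))
        + np.multiply.outer(np.cos(th), np.array([0.0, 0.0, 1.0]))
    )
    return out


def _extreme_over_interval(A: float, B: float, lo: float, hi: float) -> tuple[float, float]:
    """Min/max of f(t) = A sin t + B cos t over [lo, hi] (radians)."""
    cands = [lo, hi]
    tstar = math.atan2(A, B)
    for t in (tstar, tstar + math.pi, tstar - math.pi, tstar + 2 * math.pi):
        if lo <= t <= hi:
            cands.append(t)
    vals = [A * math.sin(t) + B * math.cos(t) for t in cands]
    return min(vals), max(vals)


def height_extremes_over_region(
    model: EyeModel, reg: RetinalRegion, up: np.ndarray
) -> tuple[float, float]:
    """Analytic min/max of wall height r.up over a band (mm, centre origin).

    Height of the wall point at (theta, phi) is
    R * (c sin(theta) cos(phi - phi0) + uz cos(theta)) with c, phi0 from the
    in-plane component of ``up``; extremes are taken over the band's box.
    """
    up = np.asarray(up, dtype=float)
    nx = model.nasal_axis
    ux = float(up @ nx)  # nasal component
    uy, uz = float(up[1]), float(up[2])
    c = math.hypot(ux, uy)
    phi0 = math.atan2(ux, uy)  # azimuth (from superior) of the in-plane up
    a0, a1 = np.radians(reg.azimuth_interval)
    p0, p1 = np.radians(reg.polar_interval)
    # cos(phi - phi0) extremes over azimuth interval
    cmin, cmax = _extreme_over_interval(math.sin(phi0), math.cos(phi0), a0, a1)
    lo = math.inf
    hi = -math.inf
    for cc in (cmin, cmax):
        mn, mx = _extreme_over_interval(c * cc, uz, p0, p1)
        lo = min(lo, mn)
        hi = max(hi, mx)
    return model.radius * lo, model.radius * hi


@dataclass
class SurfaceMesh:
    """Triangulated cavity boundary with per-face quadrant-band tags."""

    vertices: np.ndarray
    faces: np.ndarray
    region_tag: np.ndarray  # str per face: quadrant value or "other"

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def face_areas(self) -> np.ndarray:
        return self.as_trimesh().area_faces

    def tagged_area(self, quadrant: Quadrant | str) -> float:
        tag = Quadrant(quadrant).value
        return float(self.face_areas[self.region_tag == tag].sum())

    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def export(self, path: str) -> None:
        """Write OBJ/PLY/STL (format inferred from the extension)."""
        self.as_trimesh().export(path)


def surface_mesh(model: EyeModel, resolution: int = 256) -> SurfaceMesh:
    """Watertight triangulation of the cavity boundary, faces tagged by band.

    ``resolution`` is the azimuthal vertex count; polar rings use half that.
    Ring latitudes are snapped to every band boundary and ring meridians to
    the clock boundaries, so face tagging is exact and the tagged area error
    is pure chord-vs-arc discretisation.
    """
    if resolution < 16:
        raise ResolutionTooLowError("mesh resolution must be >= 16")
    R = model.radius
    lim = limbus_polar_angle(model)

    # polar rings: uniform + snapped band boundaries
    landmarks = sorted(
        {arc_to_polar(model, model.ora_arc[q]) for q in Quadrant}
        | {arc_to_polar(model, model.ora_arc[q] + model.equator_offset) for q in Quadrant}
    )
    thetas = np.unique(
        np.concatenate(
            [np.linspace(lim, 180.0, max(resolution // 2, 8)), np.array(landmarks)]
        )
    )
    # azimuth columns: uniform + snapped clock boundaries (45, 135, 225, 315)
    phis = np.unique(
        np.concatenate(
            [np.linspace(0.0, 360.0, resolution, endpoint=False), np.arange(45.0, 360.0, 90.0)]
        )
    )
    nphi = len(phis)

    nasal = model.nasal_axis
    verts = []
    ring_index = []
    for th in thetas[:-1]:
        base = len(verts)
        ring = R * direction(np.full(nphi, th), phis, nasal)
        verts.extend(ring)
        ring_index.append(np.arange(base, base + nphi))
    pole = np.array([0.0, 0.0, -R])
    pole_idx = len(verts)
    verts.append(pole)
    # rim-centre vertex closing the truncation disc
    disc_center = np.array([0.0, 0.0, model.truncation_plane_z])
    disc_idx = len(verts)
    verts.append(disc_center)
    verts = np.asarray(verts)

    faces = []
    tags = []

    def tag_for(th_c: float, phi_c: float) -> str:
        for q in Quadrant:
            a0, a1 = quadrant_azimuth_interval(q)
            p0 = arc_to_polar(model, model.ora_arc[q])
            p1 = arc_to_polar(model, model.ora_arc[q] + model.equator_offset)
            d = (phi_c - a0) % 360.0
            if d < 90.0 and p0 <= th_c <= p1:
                return q.value
        return "other"

    for i in range(len(thetas) - 2):
        th_c = 0.5 * (thetas[i] + thetas[i + 1])
        r0, r1 = ring_index[i], ring_index[i + 1]
        for j in range(nphi):
            k = (j + 1) % nphi
            phi_c = phis[j] + 0.5 * ((phis[k] - phis[j]) % 360.0)
            t = tag_for(th_c, phi_c % 360.0)
            faces.append((r0[j], r1[j], r1[k]))
            tags.append(t)
            faces.append((r0[j], r1[k], r0[k]))
            tags.append(t)
    # pole fan
    last = ring_index[-1]
    th_c = 0.5 * (thetas[-2] + 180.0)
    for j in range(nphi):
        k = (j + 1) % nphi
        phi_c = phis[j] + 0.5 * ((phis[k] - phis[j]) % 360.0)
        faces.append((last[j], pole_idx, last[k]))
        tags.append(tag_for(th_c, phi_c % 360.0))
    # truncation disc fan (rim ring is the first ring, at the limbus)
    rim = ring_index[0]
    for j in range(nphi):
        k = (j + 1) % nphi
        faces.append((rim[j], rim[k], disc_idx))
        tags.append("other")

    mesh = SurfaceMesh(
        vertices=verts, faces=np.asarray(faces, dtype=np.int64), region_tag=np.asarray(tags)
    )
    # area sanity: tagged areas must track the analytic band areas
    worst = 0.0
    for q in Quadrant:
        analytic = region_area(model, region(model, q))
        worst = max(worst, abs(mesh.tagged_area(q) - analytic) / analytic)
    if worst > 0.02:
        raise ResolutionTooLowError(
            f"tagged band area error {100 * worst:.2f}% exceeds 2%; increase resolution"
        )
    return mesh
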