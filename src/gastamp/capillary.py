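"""Static equilibrium gas-water interface in the oriented eye cavity.

At eye scale the Bond number Bo = (rho_w - rho_g) g R^2 / sigma is ~ 20, so
gravity dominates capillarity: the bulk interface is a horizontal plane whose
height is fixed by the gas volume, with a capillary boundary layer (the
meniscus) of width ~ the capillary length against the wall.  The interface is
therefore solved in two steps:

1. *flat mode* - bisect the fill level so the cavity volume below the plane
   equals the water volume (1-D slice quadrature of analytic circle/segment
   cross-sections of the truncated sphere);
2. *meniscus mode* - additionally lift the contact line along the wall by the
   planar-wall Young-Laplace climb
       rise = l_c * sqrt(2 (1 - sin(theta_c + alpha))),
   where l_c = sqrt(sigma / (delta rho g)) is the capillary length, theta_c
   the gas-water-retina contact angle, and alpha the local wall tilt from
   vertical.  Water wets the retina (theta_c = 38.8 deg), so the contact line
   sits above the flat level and gas coverage can only shrink.

The transient that settles into this state (and any CFD of it) is out of
scope; viscosities and thermal expansion rates are carried as metadata only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .errors import InvalidParamsError, NonConvergenceError
from .geometry import EyeModel, cavity_volume
from .orientation import inclination_at_height

__all__ = [
    "PhysicalParams",
    "SolverOptions",
    "InterfaceSolution",
    "CavityProfile",
    "capillary_length",
    "bond_number",
    "volume_below_plane",
    "fill_height",
    "meniscus_rise",
    "meniscus_profile_ode",
    "solve_interface",
    "up_basis",
    "azimuth_about_up",
]


@dataclass(frozen=True)
class PhysicalParams:
    """Gas/water properties at body temperature.

    Defaults are air against water at 37 C with the measured air-water-retina
    contact angle.  ``metadata`` records transport properties the static
    model does not use.
    """

    sigma: float = 0.072  # surface tension, N/m
    contact_angle_deg: float = 38.8
    rho_water: float = 998.23  # kg/m^3
    rho_gas: float = 1.1892  # kg/m^3
    g: float = 9.81  # m/s^2
    metadata: dict = field(
        default_factory=lambda: {
            "temperature_C": 37.0,
            "kinematic_viscosity_water_m2_s": 1.006e-6,
            "kinematic_viscosity_gas_m2_s": 1.544e-5,
            "volume_expansion_water_1_K": 1.18e-4,
            "volume_expansion_gas_1_K": 3.41e-3,
        }
    )

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise InvalidParamsError("surface tension must be positive")
        if not self.rho_water > self.rho_gas > 0:
            raise InvalidParamsError("need rho_water > rho_gas > 0")
        if not 0.0 < self.contact_angle_deg < 180.0:
            raise InvalidParamsError("contact angle must lie in (0, 180) deg")
        if self.g <= 0:
            raise InvalidParamsError("g must be positive")


@dataclass(frozen=True)
class SolverOptions:
    """Numerical knobs for the interface solve (all deterministic)."""

    mode: str = "meniscus"  # "meniscus" or "flat"
    n_slices: int = 2000  # 1-D volume quadrature slices
    n_azimuth: int = 720  # contact-line azimuth samples
    volume_tol: float = 1e-9  # |dV|/V tolerance of the fill level
    refine_contact: bool = False  # fixed-point refinement of the climb
    max_refine: int = 5
    refine_tol_mm: float = 1e-3
    include_meniscus_volume: bool = False  # re-balance flat level for the ring

    def __post_init__(self) -> None:
        if self.mode not in ("flat", "meniscus"):
            raise InvalidParamsError(f"unknown interface mode {self.mode!r}")
        if self.n_slices < 16 or self.n_azimuth < 8:
            raise InvalidParamsError("quadrature resolution too low")


def capillary_length(params: PhysicalParams) -> float:
    """Capillary length sqrt(sigma / (delta rho g)) in mm."""
    drho = params.rho_water - params.rho_gas
    return math.sqrt(params.sigma / (drho * params.g)) * 1000.0


def bond_number(params: PhysicalParams, length_mm: float) -> float:
    """Gravity/capillarity ratio at the given length scale."""
    return (length_mm / capillary_length(params)) ** 2


def _segment_area(rho: float, a: float) -> float:
    """Area of the part of a disc of radius rho with coordinate <= a."""
    if rho <= 0.0:
        return 0.0
    if a >= rho:
        return math.pi * rho * rho
    if a <= -rho:
        return 0.0
    return rho * rho * math.acos(-a / rho) + a * math.sqrt(rho * rho - a * a)


class CavityProfile:
    """Volume-vs-height profile of the oriented cavity.

    Cross-sections perpendicular to ``up`` are discs (from the sphere) cut by
    the half-space behind the truncation plane; their areas are analytic and
    the volume profile is their cumulative 1-D quadrature on ``n_slices``
    uniform slices.
    """

    def __init__(self, model: EyeModel, up, n_slices: int = 2000):
        self.model = model
        self.up = np.asarray(up, dtype=float)
        n = float(np.linalg.norm(self.up))
        if abs(n - 1.0) > 1e-9:
            raise InvalidParamsError("up must be a unit vector")
        R = model.radius
        zmax = model.truncation_plane_z
        uz = float(self.up[2])
        s = math.sqrt(max(0.0, 1.0 - uz * uz))  # in-plane |grad z|

        # cavity extent along up
        cands_hi, cands_lo = [], []
        if R * uz <= zmax + 1e-12:
            cands_hi.append(R)
        if -R * uz <= zmax + 1e-12:
            cands_lo.append(-R)
        r_rim = math.sqrt(max(0.0, R * R - zmax * zmax))
        cands_hi.append(zmax * uz + r_rim * s)
        cands_lo.append(zmax * uz - r_rim * s)
        self.u_min = min(cands_lo)
        self.u_max = max(cands_hi)

        self._ugrid = np.linspace(self.u_min, self.u_max, int(n_slices) + 1)
        rho = np.sqrt(np.clip(R * R - self._ugrid**2, 0.0, None))
        if s < 1e-12:
            sign = 1.0 if uz > 0 else -1.0
            areas = np.where(sign * self._ugrid <= zmax, np.pi * rho**2, 0.0)
        else:
            astar = (zmax - self._ugrid * uz) / s
            areas = np.array([_segment_area(r, a) for r, a in zip(rho, astar)])
        self._areas = areas
        self._cumvol = np.concatenate(
            [[0.0], cumulative_trapezoid(areas, self._ugrid)]
        )

    @property
    def total_volume(self) -> float:
        return float(self._cumvol[-1])

    def cross_section_area(self, h) -> np.ndarray:
        return np.interp(h, self._ugrid, self._areas)

    def volume_below(self, h) -> np.ndarray:
        return np.interp(h, self._ugrid, self._cumvol)

    def fill_height(self, water_fraction: float, tol: float = 1e-9) -> float:
        """Height of the flat level holding the given water fraction.

        Bisection on the (monotone) volume profile to |dV|/V <= tol.
        """
        if not 0.0 <= water_fraction <= 1.0:
            raise InvalidParamsError("water fraction must lie in [0, 1]")
        if water_fraction == 0.0:
            return self.u_min
        if water_fraction == 1.0:
            return self.u_max
        target = water_fraction * self.total_volume
        lo, hi = self.u_min, self.u_max
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            v = float(self.volume_below(mid))
            if abs(v - target) <= tol * self.total_volume:
                return mid
            if v < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def volume_below_plane(model: EyeModel, up, h: float, n_slices: int = 2000) -> float:
    """Cavity volume below height ``h`` (mm^3)."""
    return float(CavityProfile(model, up, n_slices).volume_below(h))


def fill_height(
    model: EyeModel, up, water_fraction: float, tol: float = 1e-9, n_slices: int = 2000
) -> float:
    """Flat fill level (height above centre, mm) for a water fraction."""
    return CavityProfile(model, up, n_slices).fill_height(water_fraction, tol)


def meniscus_rise(params: PhysicalParams, inclination_deg: float = 0.0) -> float:
    """Vertical contact-line climb on a planar wall tilted from vertical, mm.

    First integral of the 2-D Young-Laplace equation:
    rise = l_c sqrt(2 (1 - sin theta_eff)) with
    theta_eff = clamp(theta_c + inclination, 0, 90) deg; a wall opening
    upward (positive inclination) reduces the climb, an overhang increases it
    up to the clamp at sqrt(2) l_c.
    """
    lc = capillary_length(params)
    theta_eff = min(90.0, max(0.0, params.contact_angle_deg + inclination_deg))
    return lc * math.sqrt(2.0 * (1.0 - math.sin(math.radians(theta_eff))))


def meniscus_profile_ode(params: PhysicalParams, inclination_deg: float = 0.0) -> float:
    """Contact-line climb by numerical integration of the meniscus profile.

    Independent oracle for :func:`meniscus_rise`: the 2-D profile is
    integrated in the tangent-angle parametrisation dy/dpsi =
    l_c^2 sin(psi) / y from the flat far field (linearised seed) up to the
    wall, met at the prescribed contact angle on the tilted wall.
    """
    if not abs(inclination_deg) < 90.0:
        raise InvalidParamsError("inclination must satisfy |alpha| < 90 deg")
    lc = capillary_length(params)
    theta_eff = min(90.0, max(0.0, params.contact_angle_deg + inclination_deg))
    tau_c = math.radians(90.0 - theta_eff)  # interface tangent angle at the wall
    if tau_c <= 0.0:
        return 0.0
    psi0 = 1e-8
    sol = solve_ivp(
        lambda psi, y: lc * lc * math.sin(psi) / y[0],
        (psi0, tau_c),
        [lc * psi0],
        rtol=1e-10,
        atol=1e-14,
    )
    if not sol.success:
        raise NonConvergenceError(f"meniscus profile integration failed: {sol.message}")
    return float(sol.y[0, -1])


def up_basis(up) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal pair (e1, e2) perpendicular to ``up``."""
    u = np.asarray(up, dtype=float)
    a = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = a - (a @ u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def azimuth_about_up(points, up) -> np.ndarray:
    """Azimuth (deg in [0, 360)) of points about the up axis."""
    e1, e2 = up_basis(up)
    p = np.asarray(points, dtype=float)
    psi = np.degrees(np.arctan2(p @ e2, p @ e1))
    return np.mod(psi, 360.0)


@dataclass
class InterfaceSolution:
    """Solved equilibrium interface: flat level + contact line on the wall.

    ``contact_height`` samples the height of the gas/water boundary on the
    wall (the line of complete gas coverage) per azimuth about the up axis.
    """

    model: EyeModel
    up: np.ndarray
    mode: str
    gas_fraction_target: float
    flat_height: float
    contact_azimuth_deg: np.ndarray
    contact_height: np.ndarray
    gas_volume_achieved: float
    degenerate: str | None = None  # "gas", "water", or None
    params: PhysicalParams | None = None

    def contact_height_at(self, azimuth_deg) -> np.ndarray:
        return np.interp(
            np.mod(azimuth_deg, 360.0),
            self.contact_azimuth_deg,
            self.contact_height,
            period=360.0,
        )

    @property
    def contact_range(self) -> tuple[float, float]:
        return float(self.contact_height.min()), float(self.contact_height.max())

    def to_json(self, **kwargs) -> str:
        d = {
            "diameter_mm": self.model.diameter,
            "up": list(map(float, self.up)),
            "mode": self.mode,
            "gas_fraction_target": self.gas_fraction_target,
            "flat_height_mm": self.flat_height,
            "gas_volume_achieved_mm3": self.gas_volume_achieved,
            "degenerate": self.degenerate,
            "contact_azimuth_deg": [float(x) for x in self.contact_azimuth_deg],
            "contact_height_mm": [float(x) for x in self.contact_height],
        }
        if self.params is not None:
            d["params"] = asdict(self.params)
        return json.dumps(d, **kwargs)


def solve_interface(
    model: EyeModel,
    up,
    gas_fraction: float,
    params: PhysicalParams | None = None,
    options: SolverOptions | None = None,
) -> InterfaceSolution:
    """Solve the equilibrium interface at a gas fill fraction.

    The flat level satisfies the volume budget for 1 - gas_fraction; in
    meniscus mode the contact line is lifted above it by the planar-wall
    climb evaluated at the wall inclination of the flat-level wall
    intersection (optionally iterated to the self-consistent height).  Where
    the flat level meets the truncation plane instead of the spherical wall,
    the lift uses the plane's inclination and the stored threshold is
    equivalent to clipping at the plane's rim for any retinal query.
    """
    if not 0.0 <= gas_fraction <= 1.0:
        raise InvalidParamsError("gas fraction must lie in [0, 1]")
    params = params or PhysicalParams()
    opts = options or SolverOptions()
    up = np.asarray(up, dtype=float)

    profile = CavityProfile(model, up, opts.n_slices)
    vcav = cavity_volume(model)
    psi = np.linspace(0.0, 360.0, opts.n_azimuth, endpoint=False)

    if gas_fraction in (0.0, 1.0):
        h = profile.u_max if gas_fraction == 0.0 else profile.u_min
        return InterfaceSolution(
            model=model,
            up=up,
            mode=opts.mode,
            gas_fraction_target=gas_fraction,
            flat_height=h,
            contact_azimuth_deg=psi,
            contact_height=np.full_like(psi, h),
            gas_volume_achieved=gas_fraction * vcav,
            degenerate="water" if gas_fraction == 0.0 else "gas",
            params=params,
        )

    water_fraction = 1.0 - gas_fraction
    h = profile.fill_height(water_fraction, opts.volume_tol)

    if opts.mode == "meniscus" and opts.include_meniscus_volume:
        # re-balance the flat level for the water held in the meniscus ring
        lc = capillary_length(params)
        for _ in range(opts.max_refine):
            incl = inclination_at_height(model.radius, h)
            theta_eff = min(90.0, max(0.0, params.contact_angle_deg + incl))
            perim = 2.0 * math.pi * math.sqrt(
                max(0.0, model.radius**2 - min(h**2, model.radius**2))
            )
            v_ring = perim * lc * lc * math.cos(math.radians(theta_eff))
            wf = max(0.0, water_fraction - v_ring / profile.total_volume)
            h_new = profile.fill_height(wf, opts.volume_tol)
            if abs(h_new - h) < opts.refine_tol_mm:
                h = h_new
                break
            h = h_new

    contact = np.full_like(psi, h)
    if opts.mode == "meniscus":
        R = model.radius
        zmax = model.truncation_plane_z
        e1, e2 = up_basis(up)
        rho = math.sqrt(max(0.0, R * R - h * h)) if abs(h) < R else 0.0
        d = (
            np.outer(np.cos(np.radians(psi)), e1)
            + np.outer(np.sin(np.radians(psi)), e2)
        )
        pz = h * up[2] + rho * d[:, 2]
        on_sphere = pz <= zmax + 1e-12
        incl_sphere = inclination_at_height(R, h)
        incl_plane = math.degrees(math.asin(min(1.0, max(-1.0, -up[2]))))
        incl = np.where(on_sphere, incl_sphere, incl_plane)
        rise = np.array([meniscus_rise(params, i) for i in incl])
        uc = h + rise
        if opts.refine_contact:
            for _ in range(opts.max_refine):
                incl_ref = np.array(
                    [
                        inclination_at_height(R, min(R, max(-R, u)))
                        if on_sphere[k]
                        else incl_plane
                        for k, u in enumerate(uc)
                    ]
                )
                uc_new = h + np.array([meniscus_rise(params, i) for i in incl_ref])
                if np.max(np.abs(uc_new - uc)) < opts.refine_tol_mm:
                    uc = uc_new
                    break
                uc = uc_new
        contact = np.clip(uc, profile.u_min, profile.u_max)

    achieved = profile.total_volume - float(profile.volume_below(h))
    # report on the analytic cavity volume scale
    achieved *= vcav / profile.total_volume
    return InterfaceSolution(
        model=model,
        up=up,
        mode=opts.mode,
        gas_fraction_target=gas_fraction,
        flat_height=h,
        contact_azimuth_deg=psi,
        contact_height=contact,
        gas_volume_achieved=achieved,
        degenerate=None,
        params=params,
    )
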