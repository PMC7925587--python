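"""Per-quadrant gas cover rates from a solved interface.

The gas cover rate of a quadrant band is
(gas-covered band area) / (total band area) x 100%.  A wall point counts as
covered iff it lies strictly above the contact line at its azimuth (the
boundary set has measure zero; strictness is fixed for determinism).  In
flat mode the contact line is the fill level itself; in meniscus mode it is
the lifted contact line, so coverage can only shrink.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .capillary import (
    InterfaceSolution,
    PhysicalParams,
    SolverOptions,
    azimuth_about_up,
    solve_interface,
)
from .config import RunConfig
from .errors import EmptyBreakSetError, MismatchedModelError
from .geometry import (
    EyeModel,
    Quadrant,
    RetinalRegion,
    build_eye_model,
    direction,
    height_extremes_over_region,
    region,
    region_area,
)
from .orientation import Position, up_vector

__all__ = [
    "CoverageResult",
    "CoverageTable",
    "round_half_away",
    "covered_percent",
    "run_case",
    "run_grid",
    "recommend_position",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (table convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CoverageResult:
    quadrant: Quadrant
    covered_area: float  # mm^2
    total_area: float  # mm^2
    percent_raw: float
    diameter: float
    position: Position | None
    gas_fraction: float
    mode: str

    @property
    def percent(self) -> int:
        return round_half_away(self.percent_raw)


def _adaptive_polar_samples(span_deg: float) -> int:
    return int(np.clip(round(span_deg * 8), 64, 512))


def covered_percent(
    model: EyeModel,
    reg: RetinalRegion,
    interface: InterfaceSolution,
    n_azimuth: int = 1024,
    n_polar: int | None = None,
    position: Position | None = None,
) -> CoverageResult:
    """Gas cover rate of one quadrant band under a solved interface.

    Bands whose height range clears the whole contact line are resolved
    exactly (0 or 100%); otherwise the covered patch is integrated on an
    azimuth x polar quadrature grid with the per-azimuth contact threshold.
    """
    if interface.model != model:
        raise MismatchedModelError("interface was solved on a different eye model")
    expected = region(model, reg.quadrant)
    if (
        expected.polar_interval != reg.polar_interval
        or expected.azimuth_interval != reg.azimuth_interval
    ):
        raise MismatchedModelError("region does not belong to this eye model")

    total = region_area(model, reg)
    meta = dict(
        quadrant=reg.quadrant,
        total_area=total,
        diameter=model.diameter,
        position=position,
        gas_fraction=interface.gas_fraction_target,
        mode=interface.mode,
    )
    if interface.degenerate == "gas":
        return CoverageResult(covered_area=total, percent_raw=100.0, **meta)
    if interface.degenerate == "water":
        return CoverageResult(covered_area=0.0, percent_raw=0.0, **meta)

    c_min, c_max = interface.contact_range
    h_min, h_max = height_extremes_over_region(model, reg, interface.up)
    if h_min > c_max:
        return CoverageResult(covered_area=total, percent_raw=100.0, **meta)
    if h_max <= c_min:
        return CoverageResult(covered_area=0.0, percent_raw=0.0, **meta)

    p0, p1 = reg.polar_interval
    a0, a1 = reg.azimuth_interval
    if n_polar is None:
        n_polar = _adaptive_polar_samples(p1 - p0)
    th = np.linspace(p0, p1, n_polar + 1)
    ph = np.linspace(a0, a1, n_azimuth + 1)
    thc = 0.5 * (th[:-1] + th[1:])
    phc = 0.5 * (ph[:-1] + ph[1:])
    TH, PH = np.meshgrid(thc, phc, indexing="ij")
    pts = model.radius * direction(TH, PH, model.nasal_axis)
    u = pts @ interface.up
    psi = azimuth_about_up(pts.reshape(-1, 3), interface.up)
    thresh = interface.contact_height_at(psi).reshape(u.shape)
    w = np.sin(np.radians(TH))
    frac = float((w * (u > thresh)).sum() / w.sum())
    return CoverageResult(covered_area=frac * total, percent_raw=100.0 * frac, **meta)


def run_case(
    model: EyeModel,
    position: Position | str,
    gas_fraction: float,
    params: PhysicalParams | None = None,
    options: SolverOptions | None = None,
    supraduction_deg: float | None = None,
    n_azimuth: int = 1024,
) -> list[CoverageResult]:
    """Solve one interface and evaluate all four quadrant bands."""
    kwargs = {} if supraduction_deg is None else {"supraduction_deg": supraduction_deg}
    frame = up_vector(position, handedness=model.handedness, **kwargs)
    sol = solve_interface(model, frame.up, gas_fraction, params, options)
    return [
        covered_percent(
            model, region(model, q), sol, n_azimuth=n_azimuth, position=frame.position
        )
        for q in Quadrant
    ]


class CoverageTable:
    """Grid of coverage results (long-format DataFrame under the hood)."""

    COLUMNS = [
        "diameter",
        "position",
        "quadrant",
        "gas_percent",
        "coverage_percent",
        "coverage_raw",
        "covered_area_mm2",
        "total_area_mm2",
        "mode",
    ]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS[:5]) - set(df.columns)
        if missing:
            raise ValueError(f"coverage table missing columns: {missing}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def cell(self, diameter: float, position: str, quadrant: str, gas_percent: int) -> int:
        m = self.df[
            (self.df.diameter == diameter)
            & (self.df.position == position)
            & (self.df.quadrant == quadrant)
            & (self.df.gas_percent == gas_percent)
        ]
        if len(m) != 1:
            raise KeyError((diameter, position, quadrant, gas_percent))
        return int(m.coverage_percent.iloc[0])

    def check_monotone(self) -> bool:
        for _, g in self.df.groupby(["diameter", "position", "quadrant"]):
            s = g.sort_values("gas_percent").coverage_raw.to_numpy()
            if np.any(np.diff(s) < -1e-9):
                return False
        return True

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def to_wide(self) -> pd.DataFrame:
        """Reference-style layout: one row per series, gas 100 -> 0 columns."""
        wide = self.df.pivot_table(
            index=["diameter", "quadrant", "position"],
            columns="gas_percent",
            values="coverage_percent",
            aggfunc="first",
        )
        return wide[sorted(wide.columns, reverse=True)]

    @classmethod
    def from_csv(cls, path) -> "CoverageTable":
        return cls(pd.read_csv(path))


def run_grid(config: RunConfig | None = None) -> CoverageTable:
    """Run the full diameters x positions x gas-fractions grid.

    Deterministic for a fixed configuration; the default grid is
    4 diameters x 6 positions x 11 gas levels x 4 quadrants = 1056 cells.
    """
    config = config or RunConfig()
    rows = []
    for d in config.diameters:
        model = build_eye_model(d, handedness=config.handedness)
        for pos in config.positions:
            for gp in config.gas_percents:
                results = run_case(
                    model,
                    pos,
                    gp / 100.0,
                    params=config.params,
                    options=config.options,
                    supraduction_deg=config.supraduction_deg,
                    n_azimuth=config.n_coverage_azimuth,
                )
                for r in results:
                    rows.append(
                        {
                            "diameter": d,
                            "position": Position(pos).value,
                            "quadrant": r.quadrant.value,
                            "gas_percent": gp,
                            "coverage_percent": r.percent,
                            "coverage_raw": r.percent_raw,
                            "covered_area_mm2": r.covered_area,
                            "total_area_mm2": r.total_area,
                            "mode": r.mode,
                        }
                    )
    return CoverageTable(pd.DataFrame(rows, columns=CoverageTable.COLUMNS))


def recommend_position(
    table: CoverageTable,
    break_quadrants,
    diameter: float | None = None,
) -> pd.DataFrame:
    """Rank positions for a set of break quadrants.

    A position is better the smaller the gas fraction down to which every
    break quadrant still shows a 100% cover rate (gas resorbs over days, so
    a lower threshold means full tamponade for longer).  Ties break on the
    mean raw coverage of the break quadrants over the whole grid.
    """
    quads = [Quadrant(q).value for q in break_quadrants]
    if not quads:
        raise EmptyBreakSetError("at least one break quadrant is required")
    df = table.df
    if diameter is not None:
        df = df[df.diameter == diameter]
    if df.empty:
        raise KeyError(f"no rows for diameter {diameter}")
    df = df[df.quadrant.isin(quads)]
    rows = []
    for pos, g in df.groupby("position"):
        full = (
            g.groupby("gas_percent")
            .coverage_percent.agg(lambda s: bool((s == 100).all()))
            .sort_index()
        )
        ok = full[full].index
        min_full = int(ok.min()) if len(ok) else 101
        rows.append(
            {
                "position": pos,
                "min_gas_percent_full_cover": min_full,
                "mean_coverage": g.coverage_raw.mean(),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["min_gas_percent_full_cover", "mean_coverage"],
        ascending=[True, False],
        kind="mergesort",
    )
    return out.reset_index(drop=True)
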