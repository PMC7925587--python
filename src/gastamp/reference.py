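"""Published reference tables, the voxel brute-force oracle, and comparison.

The packaged CSV transcribes the four published tables of per-quadrant gas
cover rates (superior / nasal / temporal / inferior bands of 24-31 mm eye
models, six positions, gas 100% down to 0% in 10% steps).  The printed
"lateral" rows are evaluated as the lower-temporal decubitus.

The voxel oracle is an independent brute-force check of flat-mode geometry:
voxelise the cavity, fill it from the bottom by voxel count, and classify
wall voxels by quadrant band and wet/dry state.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageTable
from .errors import FixtureCorruptionError, MemoryGuardError, MisalignedGridError
from .geometry import EyeModel, Quadrant, arc_to_polar
from .orientation import Position

__all__ = [
    "ReferenceTable",
    "load_reference_tables",
    "reference_position_to_orientation",
    "voxel_oracle",
    "compare",
    "ComparisonReport",
]

#: printed position label -> simulator position
_POSITION_MAP = {
    "supine": Position.SUPINE,
    "sitting": Position.SITTING,
    "prone": Position.PRONE,
    "prone_closed_eyes": Position.PRONE_CLOSED_EYES,
    "lower_nasal": Position.LOWER_NASAL,
    "lower_temporal": Position.LOWER_TEMPORAL,
    "lateral": Position.LOWER_TEMPORAL,
}


def reference_position_to_orientation(label: str) -> Position:
    """Map a printed position label to the simulated orientation."""
    return _POSITION_MAP[label]


@dataclass
class ReferenceTable:
    """All cells of the published tables, long format."""

    df: pd.DataFrame

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

    def canonical(self) -> pd.DataFrame:
        """Rows with positions renamed to simulator orientations."""
        out = self.df.copy()
        out["position"] = out.position.map(lambda p: _POSITION_MAP[p].value)
        return out


def load_reference_tables() -> ReferenceTable:
    """Load and validate the packaged reference tables."""
    with importlib.resources.files("gastamp.data").joinpath(
        "reference_tables.csv"
    ).open() as fh:
        df = pd.read_csv(fh, comment="#")
    required = {"table", "diameter", "position", "quadrant", "gas_percent", "coverage_percent"}
    if set(df.columns) != required:
        raise FixtureCorruptionError(f"unexpected columns {list(df.columns)}")
    if not df.gas_percent.isin(range(0, 101, 10)).all():
        raise FixtureCorruptionError("gas percents must be multiples of 10 in [0, 100]")
    if not df.coverage_percent.between(0, 100).all():
        raise FixtureCorruptionError("coverage outside [0, 100]")
    if not (df.loc[df.gas_percent == 100, "coverage_percent"] == 100).all():
        raise FixtureCorruptionError("full fill must give 100% everywhere")
    for key, g in df.groupby(["diameter", "position", "quadrant"]):
        s = g.sort_values("gas_percent").coverage_percent.to_numpy()
        if np.any(np.diff(s) < 0):
            raise FixtureCorruptionError(f"non-monotone series {key}")
    if len(df) != 968:
        raise FixtureCorruptionError(f"expected 968 cells, got {len(df)}")
    return ReferenceTable(df)


def voxel_oracle(
    model: EyeModel,
    up,
    gas_fraction: float,
    resolution: int = 200,
    resolution_cap: int = 384,
) -> dict[Quadrant, float]:
    """Flat-interface coverage percents by brute-force voxelisation.

    The cavity is voxelised on a ``resolution``^3 grid, filled from the
    bottom by voxel count to the water volume, and wall voxels (cavity voxels
    with a 6-neighbour outside the cavity) are classified by band membership
    and wet/dry state.  Converges to the analytic flat-mode coverage as the
    resolution grows.
    """
    if resolution < 64:
        raise ValueError("voxel resolution must be >= 64")
    if resolution > resolution_cap:
        raise MemoryGuardError(
            f"resolution {resolution} exceeds the cap {resolution_cap}"
        )
    if not 0.0 <= gas_fraction <= 1.0:
        raise ValueError("gas fraction must lie in [0, 1]")
    R = model.radius
    up = np.asarray(up, dtype=float)
    n = int(resolution)
    # cell-centred grid of spacing 2R/n (centres clear the coordinate planes)
    c = ((np.arange(n, dtype=np.float32) + np.float32(0.5)) * np.float32(2 * R / n)
         - np.float32(R))
    X, Y, Z = np.meshgrid(c, c, c, indexing="ij", sparse=True)
    inside = (X * X + Y * Y + Z * Z < R * R) & (Z < model.truncation_plane_z)

    u = (X * up[0] + Y * up[1] + Z * up[2]).astype(np.float32)
    u = np.broadcast_to(u, inside.shape)
    heights = u[inside]
    k = int(round((1.0 - gas_fraction) * heights.size))
    eps = np.float32(1e-6 * R)
    if k <= 0:
        level, frac_gas_tie = -np.inf, 1.0
    elif k >= heights.size:
        level, frac_gas_tie = np.inf, 0.0
    else:
        # water takes the k lowest voxels; voxels tied with the k-th height
        # (whole layers when gravity is axis-aligned) are split fractionally
        level = np.partition(heights, k - 1)[k - 1]
        n_below = int((heights < level - eps).sum())
        n_tie = int((np.abs(heights - level) <= eps).sum())
        frac_gas_tie = 1.0 - (k - n_below) / n_tie if n_tie else 0.0

    # wall voxels: cavity voxels with 6-neighbours outside; counting exposed
    # faces and dividing by the L1 norm of the local (analytic, radial)
    # surface normal removes the staircase anisotropy of the area estimate
    faces = np.zeros(inside.shape, dtype=np.int8)
    for axis in (0, 1, 2):
        for shift in (1, -1):
            nb = np.roll(inside, shift, axis=axis)
            # rolled-in border counts as outside
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            nb[tuple(sl)] = False
            faces += inside & ~nb
    wall = faces > 0

    xs, ys, zs = np.nonzero(wall)
    p = np.stack([c[xs], c[ys], c[zs]], axis=1)
    nrm = p / np.linalg.norm(p, axis=1, keepdims=True)
    weight = faces[xs, ys, zs] / np.abs(nrm).sum(axis=1)
    uu = p @ up
    theta = np.degrees(np.arccos(np.clip(p[:, 2] / np.linalg.norm(p, axis=1), -1, 1)))
    nasal = p @ model.nasal_axis
    azim = np.mod(np.degrees(np.arctan2(nasal, p[:, 1])), 360.0)

    out: dict[Quadrant, float] = {}
    centers = {
        Quadrant.SUPERIOR: 0.0,
        Quadrant.NASAL: 90.0,
        Quadrant.INFERIOR: 180.0,
        Quadrant.TEMPORAL: 270.0,
    }
    for q in Quadrant:
        p0 = arc_to_polar(model, model.ora_arc[q])
        p1 = arc_to_polar(model, model.ora_arc[q] + model.equator_offset)
        in_band = (
            (theta >= p0)
            & (theta <= p1)
            & (np.mod(azim - (centers[q] - 45.0), 360.0) < 90.0)
        )
        tot = float(weight[in_band].sum())
        if tot == 0.0:
            raise MemoryGuardError("no band voxels; resolution too coarse")
        gas = float(weight[in_band & (uu > level + eps)].sum())
        gas += frac_gas_tie * float(weight[in_band & (np.abs(uu - level) <= eps)].sum())
        out[q] = 100.0 * gas / tot
    return out


@dataclass
class ComparisonReport:
    """Per-cell differences between a computed grid and the reference."""

    cells: pd.DataFrame  # merged rows with computed, reference, diff
    tolerance_points: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_within(self) -> int:
        return int((self.cells["diff"].abs() <= self.tolerance_points).sum())

    @property
    def max_abs_diff(self) -> float:
        return float(self.cells["diff"].abs().max())

    @property
    def mean_abs_diff(self) -> float:
        return float(self.cells["diff"].abs().mean())

    @property
    def all_within(self) -> bool:
        return self.n_within == self.n_cells

    def hundred_zero_sets(self) -> dict:
        c = self.cells
        return {
            "computed_100": int((c.computed == 100).sum()),
            "reference_100": int((c.reference == 100).sum()),
            "matching_100": int(((c.computed == 100) & (c.reference == 100)).sum()),
            "computed_0": int((c.computed == 0).sum()),
            "reference_0": int((c.reference == 0).sum()),
            "matching_0": int(((c.computed == 0) & (c.reference == 0)).sum()),
        }

    def summary(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "tolerance_points": self.tolerance_points,
            "n_within_tolerance": self.n_within,
            "fraction_within_tolerance": self.n_within / self.n_cells,
            "mean_abs_diff": self.mean_abs_diff,
            "max_abs_diff": self.max_abs_diff,
            **self.hundred_zero_sets(),
        }

    def text(self) -> str:
        s = self.summary()
        lines = [
            f"cells compared: {s['n_cells']}",
            f"within {s['tolerance_points']:g} points: {s['n_within_tolerance']} "
            f"({100 * s['fraction_within_tolerance']:.1f}%)",
            f"mean |diff| = {s['mean_abs_diff']:.2f}, max |diff| = {s['max_abs_diff']:.0f}",
            f"100% cells: computed {s['computed_100']} / reference {s['reference_100']} "
            f"(agree on {s['matching_100']})",
            f"0% cells: computed {s['computed_0']} / reference {s['reference_0']} "
            f"(agree on {s['matching_0']})",
        ]
        return "\n".join(lines)


def compare(
    computed: CoverageTable,
    reference: ReferenceTable | None = None,
    tolerance_points: float = 10.0,
) -> ComparisonReport:
    """Align a computed grid with the reference tables cell by cell."""
    reference = reference or load_reference_tables()
    ref = reference.canonical().rename(columns={"coverage_percent": "reference"})
    comp = computed.df[
        ["diameter", "position", "quadrant", "gas_percent", "coverage_percent"]
    ].rename(columns={"coverage_percent": "computed"})
    merged = ref.merge(
        comp, on=["diameter", "position", "quadrant", "gas_percent"], how="left"
    )
    if merged.computed.isna().any():
        missing = merged[merged.computed.isna()]
        raise MisalignedGridError(
            f"{len(missing)} reference cells missing from the computed grid "
            f"(first: {missing.iloc[0][['diameter', 'position', 'quadrant', 'gas_percent']].to_dict()})"
        )
    merged["computed"] = merged.computed.astype(int)
    merged["diff"] = merged.computed - merged.reference
    return ComparisonReport(cells=merged, tolerance_points=tolerance_points)
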