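"""Voxel grids, HU-to-density calibration, and synthetic phantom fixtures.

The CT calibration follows the two-stage scheme used when preparing patient
grids for transport: the full Hounsfield range (-1000 .. 3070) is divided
into 27 base intervals, each carrying a reference density read from the
scanner calibration curve at the interval's median HU; within an interval,
densities are obtained by linearly interpolating a correction factor so that
any voxel density stays within [2/3, 3/2] of the interval reference.  The
two lowest-HU intervals (-1000..-950 and -950..-120), where density varies
by orders of magnitude, are replaced by finer subdivisions, yielding a final
table of 39 intervals.

The phantom builders generate the test geometries: a 30 cm water tank,
layered slab phantoms with lung/bone inserts, and a toy thorax with
CTV/rib/lung masks emulating a tangential breast treatment.  The HU-density
anchor values used by the fixture calibration curve are declared surrogate
values, not measured scanner data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "HuDensityTable",
    "GRID_KINDS",
    "HU_RANGE",
    "MATERIAL_HU",
    "LETD_NODATA",
    "fixture_hu_density_curve",
    "build_hu_density_table",
    "hu_to_density",
    "densify",
    "make_water_tank",
    "make_slab_phantom",
    "make_thorax_phantom",
    "write_hu_density_table_csv",
    "read_hu_density_table_csv",
]

GRID_KINDS = {"HU", "density", "dose", "letd", "mask"}

#: Full Hounsfield range covered by the calibration table.
HU_RANGE = (-1000.0, 3070.0)

#: Declared fixture HU values for the slab/thorax materials.
MATERIAL_HU = {"air": -1000.0, "lung": -700.0, "water": 0.0, "soft tissue": 40.0, "bone": 700.0}

#: Sentinel stored in LETd grids where no dose was scored (recorded in meta).
LETD_NODATA = -1.0


@dataclass
class VoxelGrid:
    """A regular 3-D scalar grid with world geometry.

    values are indexed ``[ix, iy, iz]``; the world coordinate of a voxel
    center is ``origin + (index + 0.5) * spacing`` (mm).  ``kind`` declares
    the physical meaning of the values (HU, density g/cm3, dose Gy,
    letd keV/um, or a binary mask).
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.values = np.asarray(self.values)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on all axes")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-d array with dims >= 1")
        if self.kind not in GRID_KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}; expected one of {sorted(GRID_KINDS)}")
        if self.kind == "mask":
            u = np.unique(self.values)
            if not np.all(np.isin(u, (0, 1))):
                raise ValueError("mask grids may contain only 0 and 1")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return self.spacing * np.array(self.values.shape)

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + (np.asarray(index, dtype=float) + 0.5) * self.spacing

    def like(self, values: np.ndarray, kind: str, meta: dict | None = None) -> "VoxelGrid":
        """New grid sharing this grid's geometry."""
        return VoxelGrid(self.origin.copy(), self.spacing.copy(), values, kind, dict(meta or {}))

    def congruent(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )


# -- HU-density calibration ---------------------------------------------------

#: Base 27-interval boundaries over the full HU range (28 edges).  The list
#: follows the conventional segmentation protocols for MC material maps; it
#: includes -950 and -120 (the two steep low-HU intervals) and 0 (so the
#: water anchor maps exactly).  Declared fixture boundaries.
BASE_HU_EDGES = np.array(
    [-1000, -950, -120, -83, -53, -23, 0, 18, 80, 120, 200, 300, 400, 500,
     600, 700, 800, 900, 1000, 1100, 1200, 1300, 1400, 1500, 1600, 1800,
     2300, 3070],
    dtype=float,
)

#: Piecewise-linear fixture calibration curve (HU, g/cm3): air, lung, water,
#: soft tissue, cortical bone, and a dense upper anchor covering the top of
#: the HU scale.  Surrogate values for a scanner curve.
FIXTURE_CURVE_ANCHORS = np.array(
    [(-1000.0, 0.00121), (-700.0, 0.26), (0.0, 1.000), (40.0, 1.04),
     (700.0, 1.42), (3070.0, 2.50)]
)


def fixture_hu_density_curve(n: int = 408) -> pd.DataFrame:
    """Sample the fixture calibration curve as an (HU, density) table."""
    hu = np.linspace(HU_RANGE[0], HU_RANGE[1], n)
    hu = np.unique(np.concatenate([hu, FIXTURE_CURVE_ANCHORS[:, 0]]))
    dens = np.interp(hu, FIXTURE_CURVE_ANCHORS[:, 0], FIXTURE_CURVE_ANCHORS[:, 1])
    return pd.DataFrame({"hu": hu, "density": dens})


@dataclass
class HuDensityTable:
    """Piecewise-linear HU to mass-density map with per-interval corrections.

    Each interval [hu_lo, hu_hi) carries a reference density (curve value at
    the interval's median HU) and correction factors at both ends; a voxel's
    density is ``ref * lerp(corr_lo, corr_hi)``.  All corrections lie in
    [2/3, 3/2].
    """

    hu_lo: np.ndarray
    hu_hi: np.ndarray
    ref_density: np.ndarray
    corr_lo: np.ndarray
    corr_hi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hu_lo", "hu_hi", "ref_density", "corr_lo", "corr_hi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.hu_lo.size
        if not all(getattr(self, a).size == n for a in ("hu_hi", "ref_density", "corr_lo", "corr_hi")):
            raise ValueError("table columns must have equal length")
        if not np.allclose(self.hu_lo[1:], self.hu_hi[:-1]):
            raise ValueError("intervals must be contiguous")
        if not (self.hu_lo[0] == HU_RANGE[0] and self.hu_hi[-1] == HU_RANGE[1]):
            raise ValueError(f"intervals must cover the full HU range {HU_RANGE}")
        if np.any(self.ref_density <= 0):
            raise ValueError("reference densities must be positive")

    def __len__(self) -> int:
        return int(self.hu_lo.size)

    def ratio_violations(self, lo: float = 2.0 / 3.0, hi: float = 1.5) -> list[int]:
        """Indices of intervals whose correction leaves [lo, hi]."""
        c_min = np.minimum(self.corr_lo, self.corr_hi)
        c_max = np.maximum(self.corr_lo, self.corr_hi)
        bad = (c_min < lo - 1e-12) | (c_max > hi + 1e-12)
        return list(np.nonzero(bad)[0])


def _subdivide_geometric(hu_a, hu_b, curve_hu, curve_d, n_sub):
    """Edges inside [hu_a, hu_b] spaced geometrically in density."""
    d_a = np.interp(hu_a, curve_hu, curve_d)
    d_b = np.interp(hu_b, curve_hu, curve_d)
    targets = d_a * (d_b / d_a) ** (np.arange(1, n_sub) / n_sub)
    # invert the monotone curve restricted to [hu_a, hu_b]
    fine_hu = np.linspace(hu_a, hu_b, 4001)
    fine_d = np.interp(fine_hu, curve_hu, curve_d)
    edges = np.interp(targets, fine_d, fine_hu)
    return np.concatenate([[hu_a], edges, [hu_b]])


def build_hu_density_table(
    curve_samples: pd.DataFrame,
    base_intervals: int = 27,
    subdivide_low_hu: bool = True,
    n_subintervals: int = 14,
    allow_extra_subdivision: bool = False,
) -> HuDensityTable:
    """Build the HU-density interval table from a calibration curve.

    The curve (columns ``hu``, ``density``) must be monotone in HU and span
    the full range.  27 base intervals get a reference density at their
    median HU; with ``subdivide_low_hu`` the two steep low-HU intervals are
    replaced by ``n_subintervals`` subintervals whose edges are geometric in
    density (allocated between the two intervals in proportion to their log
    density ratio), giving the standard 39-interval table.  Every interval
    must satisfy the [2/3, 3/2] correction bound; violations raise unless
    ``allow_extra_subdivision`` permits bisecting offenders (the table then
    grows beyond 39).
    """
    hu = curve_samples["hu"].to_numpy(dtype=float)
    d = curve_samples["density"].to_numpy(dtype=float)
    order = np.argsort(hu)
    hu, d = hu[order], d[order]
    if hu[0] > HU_RANGE[0] or hu[-1] < HU_RANGE[1]:
        raise ValueError(f"curve samples must span the full HU range {HU_RANGE}")
    if np.any(np.diff(d) < 0):
        raise ValueError("calibration curve must be monotone nondecreasing in HU")
    if base_intervals != len(BASE_HU_EDGES) - 1:
        # equal-width fallback for nonstandard interval counts
        edges = np.linspace(HU_RANGE[0], HU_RANGE[1], base_intervals + 1)
    else:
        edges = BASE_HU_EDGES.copy()

    if subdivide_low_hu:
        # replace the two steep intervals [-1000,-950) and [-950,-120)
        r1 = np.interp(-950.0, hu, d) / np.interp(-1000.0, hu, d)
        r2 = np.interp(-120.0, hu, d) / np.interp(-950.0, hu, d)
        k1 = int(round(n_subintervals * np.log(r1) / (np.log(r1) + np.log(r2))))
        k1 = min(max(k1, 1), n_subintervals - 1)
        k2 = n_subintervals - k1
        sub1 = _subdivide_geometric(-1000.0, -950.0, hu, d, k1)
        sub2 = _subdivide_geometric(-950.0, -120.0, hu, d, k2)
        rest = edges[edges > -120.0]
        edges = np.concatenate([sub1[:-1], sub2[:-1], [-120.0], rest[rest > -120.0]])
        edges = np.unique(edges)

    lo, hi = edges[:-1], edges[1:]

    def interval_arrays(lo, hi):
        mid = 0.5 * (lo + hi)
        ref = np.interp(mid, hu, d)
        c_lo = np.interp(lo, hu, d) / ref
        c_hi = np.interp(hi, hu, d) / ref
        return ref, c_lo, c_hi

    ref, c_lo, c_hi = interval_arrays(lo, hi)
    table = HuDensityTable(lo, hi, ref, c_lo, c_hi)
    bad = table.ratio_violations()
    while bad:
        if not allow_extra_subdivision:
            offenders = [(float(lo[i]), float(hi[i])) for i in bad]
            raise ValueError(
                "density correction leaves [2/3, 3/2] in intervals "
                f"{offenders}; rerun with allow_extra_subdivision=True"
            )
        new_edges = sorted(set(edges) | {0.5 * (lo[i] + hi[i]) for i in bad})
        edges = np.array(new_edges)
        lo, hi = edges[:-1], edges[1:]
        ref, c_lo, c_hi = interval_arrays(lo, hi)
        table = HuDensityTable(lo, hi, ref, c_lo, c_hi)
        bad = table.ratio_violations()
    return table


def hu_to_density(hu, table: HuDensityTable):
    """Mass density (g/cm3) for HU via the interval table.

    HU outside [-1000, 3070] is clamped (with a warning); inside each
    interval the correction factor is linearly interpolated, making the map
    continuous and total.
    """
    h = np.asarray(hu, dtype=float)
    if np.any(h < HU_RANGE[0]) or np.any(h > HU_RANGE[1]):
        warnings.warn("HU values outside [-1000, 3070] were clamped", stacklevel=2)
        h = np.clip(h, HU_RANGE[0], HU_RANGE[1])
    idx = np.clip(np.searchsorted(table.hu_hi, h, side="right"), 0, len(table) - 1)
    lo, hi = table.hu_lo[idx], table.hu_hi[idx]
    t = np.where(hi > lo, (h - lo) / (hi - lo), 0.0)
    corr = table.corr_lo[idx] + t * (table.corr_hi[idx] - table.corr_lo[idx])
    out = table.ref_density[idx] * corr
    return float(out) if np.isscalar(hu) else out


def densify(hu_grid: VoxelGrid, table: HuDensityTable) -> VoxelGrid:
    """Voxelwise HU to density conversion; geometry preserved."""
    if hu_grid.kind != "HU":
        raise ValueError(f"densify expects an HU grid, got kind={hu_grid.kind!r}")
    dens = hu_to_density(hu_grid.values, table)
    return hu_grid.like(dens, "density", {"unit": "g/cm3"})


# -- phantom builders ---------------------------------------------------------

def make_water_tank(side_cm: float = 30.0, spacing_mm=2.0, depth_cm: float | None = None) -> VoxelGrid:
    """Uniform water (HU = 0) tank, centered on the origin laterally with the
    beam axis (z) starting at z = 0.

    ``depth_cm`` extends the z extent beyond the lateral side (default: a
    cube) so that beams whose range slightly exceeds the nominal tank depth
    still stop inside the scoring grid.
    """
    sp = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    size_mm = np.array([side_cm, side_cm, depth_cm if depth_cm else side_cm]) * 10.0
    dims = np.maximum(np.rint(size_mm / sp).astype(int), 1)
    origin = np.array([-0.5 * dims[0] * sp[0], -0.5 * dims[1] * sp[1], 0.0])
    return VoxelGrid(origin, sp, np.zeros(dims, dtype=float), "HU")


def make_slab_phantom(layers, lateral_cm: float = 10.0, spacing_mm=2.0) -> VoxelGrid:
    """Layered phantom along the beam (z) axis.

    ``layers`` is a sequence of (material, thickness_cm) with materials from
    MATERIAL_HU.  Layer boundaries land on voxel boundaries as closely as the
    spacing allows.
    """
    sp = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    layers = list(layers)
    for mat, _ in layers:
        if mat not in MATERIAL_HU:
            raise ValueError(f"unknown material {mat!r}; expected one of {sorted(MATERIAL_HU)}")
    total_mm = sum(t for _, t in layers) * 10.0
    nz = max(int(np.rint(total_mm / sp[2])), 1)
    nxy = max(int(np.rint(lateral_cm * 10.0 / sp[0])), 1)
    values = np.zeros((nxy, nxy, nz), dtype=float)
    zc = (np.arange(nz) + 0.5) * sp[2]
    z0 = 0.0
    for mat, thick in layers:
        z1 = z0 + thick * 10.0
        values[:, :, (zc >= z0) & (zc < z1)] = MATERIAL_HU[mat]
        z0 = z1
    origin = np.array([-0.5 * nxy * sp[0], -0.5 * nxy * sp[1], 0.0])
    return VoxelGrid(origin, sp, values, "HU")


def make_thorax_phantom(spacing_mm=2.0, seed: int = 0):
    """Toy thorax: soft-tissue breast bulk, CTV, rib band, lung.

    Returns ``(hu_grid, masks)`` where ``masks`` maps ``ctv``/``rib``/
    ``lung`` to binary VoxelGrids.  Geometry along the (unrotated) beam
    axis z: 6 cm of soft tissue containing an ellipsoidal CTV, an 8 mm bone
    band (rib) at the CTV's distal edge, then lung.  Soft tissue and lung
    carry small seeded HU texture, so a fixed seed gives bit-identical
    grids.  Masks are pairwise disjoint; the rib band is adjacent to the
    lung.  The rib volume well exceeds 0.5 cm3 so D_0.5cm3 is defined.
    """
    sp = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,)).copy()
    if np.any(sp <= 0):
        raise ValueError("spacing must be positive")
    size_mm = np.array([160.0, 160.0, 160.0])
    dims = np.maximum(np.rint(size_mm / sp).astype(int), 1)
    origin = np.array([-0.5 * size_mm[0], -0.5 * size_mm[1], 0.0])
    grid = VoxelGrid(origin, sp, np.zeros(dims, dtype=float), "HU")
    x = grid.axis_centers(0)[:, None, None]
    y = grid.axis_centers(1)[None, :, None]
    z = grid.axis_centers(2)[None, None, :]

    rng = np.random.default_rng(seed)
    hu = np.full(tuple(dims), MATERIAL_HU["air"], dtype=float)
    soft = z < 60.0
    rib = (z >= 60.0) & (z < 68.0) & (np.abs(x) < 60.0) & (np.abs(y) < 25.0)
    lung = (z >= 60.0) & ~rib
    hu[np.broadcast_to(soft, hu.shape)] = MATERIAL_HU["soft tissue"]
    hu += np.broadcast_to(soft, hu.shape) * rng.normal(0.0, 5.0, hu.shape)
    hu[rib] = MATERIAL_HU["bone"]
    lung_tex = MATERIAL_HU["lung"] + rng.normal(0.0, 20.0, hu.shape)
    hu = np.where(lung, lung_tex, hu)

    ctv = ((x / 40.0) ** 2 + (y / 40.0) ** 2 + ((z - 35.0) / 22.0) ** 2) <= 1.0
    ctv = ctv & np.broadcast_to(soft, hu.shape)

    masks = {
        "ctv": grid.like(ctv.astype(np.uint8), "mask"),
        "rib": grid.like(rib.astype(np.uint8), "mask"),
        "lung": grid.like(lung.astype(np.uint8), "mask"),
    }
    return grid.like(hu, "HU"), masks


# -- table CSV interface ------------------------------------------------------

def write_hu_density_table_csv(path, table: HuDensityTable) -> None:
    pd.DataFrame(
        {
            "hu_lo": table.hu_lo,
            "hu_hi": table.hu_hi,
            "ref_density": table.ref_density,
            "corr_lo": table.corr_lo,
            "corr_hi": table.corr_hi,
        }
    ).to_csv(path, index=False)


def read_hu_density_table_csv(path) -> HuDensityTable:
    df = pd.read_csv(path)
    return HuDensityTable(
        df["hu_lo"].to_numpy(),
        df["hu_hi"].to_numpy(),
        df["ref_density"].to_numpy(),
        df["corr_lo"].to_numpy(),
        df["corr_hi"].to_numpy(),
    )
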