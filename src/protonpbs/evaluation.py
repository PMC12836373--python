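"""Plan-quality metrics: DVH/LVH curves, D_v / V_x, and 3-D gamma analysis.

The cumulative histograms and dose metrics operate on any scalar grid with a
binary structure mask; LETd grids may carry a no-data sentinel (voxels never
reached by dose), which is excluded from histograms with the excluded
fraction reported.

Gamma analysis compares an evaluated dose grid against a reference using the
combined dose-difference / distance-to-agreement criterion

    gamma(r) = min over r' of sqrt( |r'-r|^2 / dta^2 + (De(r')-Dr(r))^2 / dD^2 )

with the dose criterion dD taken globally as a percentage of the reference
maximum, a low-dose cutoff applied to the reference grid, trilinear
interpolation of the evaluated grid at 0.5 mm sub-sampling, and the search
radius capped at 3 x dta.  A point passes when gamma <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .phantom import VoxelGrid

__all__ = [
    "HistogramCurve",
    "GammaResult",
    "cumulative_histogram",
    "dose_at_volume",
    "volume_at_dose",
    "gamma_analysis",
    "profile_difference",
    "write_histogram_csv",
    "read_histogram_csv",
]


@dataclass
class HistogramCurve:
    """Cumulative volume histogram: percent of volume with value >= edge."""

    edges: np.ndarray
    percent_volume: np.ndarray
    excluded_fraction: float = 0.0
    unit: str = "Gy"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.percent_volume = np.asarray(self.percent_volume, dtype=float)
        if self.edges.shape != self.percent_volume.shape:
            raise ValueError("edges and percent_volume must match")
        if self.percent_volume.size and abs(self.percent_volume[0] - 100.0) > 1e-9:
            raise ValueError("cumulative histogram must start at 100%")
        if np.any(np.diff(self.percent_volume) > 1e-12):
            raise ValueError("cumulative histogram must be nonincreasing")

    def value_at(self, edge: float) -> float:
        return float(np.interp(edge, self.edges, self.percent_volume))


@dataclass
class GammaResult:
    """Outcome of a gamma comparison."""

    pass_rate: float
    gamma_map: VoxelGrid
    criteria: tuple
    evaluated_points: int = 0
    shift_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_rate <= 100.0:
            raise ValueError("pass rate must lie in [0, 100]")


def _masked_values(values_grid: VoxelGrid, mask: VoxelGrid):
    if not values_grid.congruent(mask):
        raise ValueError("value grid and mask are not congruent")
    if mask.kind != "mask":
        raise ValueError("structure grid must be of kind 'mask'")
    sel = mask.values > 0
    if not np.any(sel):
        raise ValueError("structure mask is empty")
    return values_grid.values[sel]


def cumulative_histogram(
    values_grid: VoxelGrid, mask: VoxelGrid, bins=None, bin_width: float | None = None
) -> HistogramCurve:
    """DVH/LVH: percent of the structure with value >= each bin edge.

    ``bins`` may be an explicit edge array; otherwise edges run from 0 to
    just past the structure maximum in steps of ``bin_width`` (default
    0.1 Gy for dose, 0.1 keV/um for LETd).  Sentinel (no-data) voxels are
    excluded and reported via ``excluded_fraction``.
    """
    vals = _masked_values(values_grid, mask)
    excluded = 0.0
    if "nodata" in values_grid.meta:
        nodata = float(values_grid.meta["nodata"])
        bad = vals == nodata
        excluded = float(bad.mean())
        vals = vals[~bad]
        if vals.size == 0:
            raise ValueError("structure contains only no-data voxels")
    if bins is None:
        width = 0.1 if bin_width is None else float(bin_width)
        top = max(float(vals.max()), 0.0)
        bins = np.arange(0.0, top + 2 * width, width)
    edges = np.asarray(bins, dtype=float)
    sorted_vals = np.sort(vals)
    # fraction with value >= edge, via binary search on the sorted values
    n_below = np.searchsorted(sorted_vals, edges, side="left")
    pct = 100.0 * (1.0 - n_below / vals.size)
    unit = str(values_grid.meta.get("unit", "Gy" if values_grid.kind == "dose" else ""))
    return HistogramCurve(edges, pct, excluded_fraction=excluded, unit=unit)


def dose_at_volume(dose: VoxelGrid, mask: VoxelGrid, volume_cm3: float) -> float:
    """D_v: minimum dose (Gy) of the hottest ``volume_cm3`` of the structure.

    Voxel volumes are spacing products; the partial last voxel is resolved
    by linear interpolation on the sorted dose-volume curve.
    """
    vals = np.sort(_masked_values(dose, mask))[::-1]
    vv = dose.voxel_volume_cm3
    total = vals.size * vv
    if volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    if volume_cm3 > total + 1e-12:
        raise ValueError(f"requested volume {volume_cm3} cm3 exceeds structure volume {total:.3f} cm3")
    cumvol = vv * np.arange(1, vals.size + 1)
    return float(np.interp(volume_cm3, cumvol, vals))


def volume_at_dose(dose: VoxelGrid, mask: VoxelGrid, threshold_gy: float) -> float:
    """V_x: percent of the structure receiving at least ``threshold_gy``."""
    vals = _masked_values(dose, mask)
    return float(100.0 * np.mean(vals >= threshold_gy))


def _best_integer_shift(reference: VoxelGrid, evaluated: VoxelGrid, max_shift: int = 2):
    """Integer-voxel rigid shift of the evaluated grid minimising the mean
    squared dose difference on the overlap (the auto-alignment analog)."""
    ref = reference.values
    ev = evaluated.values
    best = (0, 0, 0)
    best_mse = np.inf
    rng = range(-max_shift, max_shift + 1)
    for sx in rng:
        for sy in rng:
            for sz in rng:
                sl_r = tuple(
                    slice(max(s, 0), n + min(s, 0))
                    for s, n in zip((sx, sy, sz), ref.shape)
                )
                sl_e = tuple(
                    slice(max(-s, 0), n + min(-s, 0))
                    for s, n in zip((sx, sy, sz), ev.shape)
                )
                a, b = ref[sl_r], ev[sl_e]
                if a.size == 0:
                    continue
                mse = float(np.mean((a - b) ** 2))
                if mse < best_mse:
                    best_mse = mse
                    best = (sx, sy, sz)
    return np.array(best, dtype=float) * evaluated.spacing


def gamma_analysis(
    reference: VoxelGrid,
    evaluated: VoxelGrid,
    dose_pct: float = 3.0,
    dta_mm: float = 3.0,
    low_threshold_pct: float = 5.0,
    shift_search: bool = False,
    search_step_mm: float = 0.5,
) -> GammaResult:
    """Global 3-D gamma comparison of two dose grids.

    Reference voxels below ``low_threshold_pct`` % of the reference maximum
    are excluded.  The evaluated grid is interpolated trilinearly at offsets
    on a ``search_step_mm`` lattice within 3 x dta of each reference point;
    offsets are visited in shells of increasing distance with early
    termination once the distance term alone exceeds the running gamma.
    With ``shift_search`` an integer-voxel rigid shift (+-2 voxels per axis)
    minimising the mean squared difference is applied first.
    """
    ref_lo = reference.origin
    ref_hi = reference.origin + reference.extent_mm
    ev_lo = evaluated.origin
    ev_hi = evaluated.origin + evaluated.extent_mm
    if np.any(ref_hi <= ev_lo) or np.any(ev_hi <= ref_lo):
        raise ValueError("reference and evaluated grids have disjoint extents")

    shift = np.zeros(3)
    if shift_search and reference.congruent(evaluated):
        shift = _best_integer_shift(reference, evaluated)
    ev_origin = evaluated.origin + shift

    dmax = float(reference.values.max())
    if dmax <= 0:
        raise ValueError("reference grid has no positive dose")
    dd_abs = dose_pct / 100.0 * dmax
    cutoff = low_threshold_pct / 100.0 * dmax

    axes = [ev_origin[i] + (np.arange(evaluated.dims[i]) + 0.5) * evaluated.spacing[i] for i in range(3)]
    interp = RegularGridInterpolator(
        axes, evaluated.values, method="linear", bounds_error=False, fill_value=np.nan
    )

    sel = reference.values >= cutoff
    idx = np.argwhere(sel)
    pts = reference.origin[None, :] + (idx + 0.5) * reference.spacing[None, :]
    dref = reference.values[sel]

    radius = 3.0 * dta_mm
    n_off = int(np.floor(radius / search_step_mm))
    g = search_step_mm * np.arange(-n_off, n_off + 1)
    ox, oy, oz = np.meshgrid(g, g, g, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    dist2 = np.sum(offsets**2, axis=1)
    keep = dist2 <= radius**2
    offsets, dist2 = offsets[keep], dist2[keep]
    order = np.argsort(dist2)
    offsets, dist2 = offsets[order], dist2[order]

    gamma2 = np.full(dref.shape, np.inf)
    pending = np.ones(dref.shape, dtype=bool)
    dta2 = dta_mm**2
    i = 0
    while i < len(offsets) and np.any(pending):
        d2 = dist2[i]
        # all offsets at the same distance shell are tried together
        j = i
        while j < len(offsets) and dist2[j] == d2:
            j += 1
        space_term = d2 / dta2
        pending &= gamma2 > space_term
        if not np.any(pending):
            break
        ids = np.nonzero(pending)[0]
        for k in range(i, j):
            dev = interp(pts[ids] + offsets[k])
            ok = ~np.isnan(dev)
            g2 = space_term + (dev[ok] - dref[ids[ok]]) ** 2 / dd_abs**2
            np.minimum.at(gamma2, ids[ok], g2)
        i = j

    gamma_vals = np.sqrt(gamma2)
    gmap = np.full(reference.dims, np.nan)
    gmap[sel] = gamma_vals
    passed = gamma_vals <= 1.0 + 1e-12
    rate = float(100.0 * passed.mean()) if gamma_vals.size else 0.0
    return GammaResult(
        pass_rate=rate,
        gamma_map=reference.like(gmap, "dose", {"unit": "gamma"}),
        criteria=(dose_pct, dta_mm, low_threshold_pct),
        evaluated_points=int(gamma_vals.size),
        shift_mm=shift,
    )


def profile_difference(curve_a, curve_b) -> tuple[float, float]:
    """(max abs, mean abs) pointwise difference of two sampled curves.

    Curves are (positions, values) pairs or DepthDoseCurve-like objects;
    curve_b is linearly interpolated onto curve_a's samples restricted to
    the overlapping abscissa range.
    """
    def unpack(c):
        if hasattr(c, "depths"):
            return np.asarray(c.depths, float), np.asarray(c.dose, float)
        x, y = c
        return np.asarray(x, float), np.asarray(y, float)

    xa, ya = unpack(curve_a)
    xb, yb = unpack(curve_b)
    lo = max(xa.min(), xb.min())
    hi = min(xa.max(), xb.max())
    sel = (xa >= lo) & (xa <= hi)
    if hi <= lo or not np.any(sel):
        raise ValueError("curves do not overlap")
    diff = np.abs(ya[sel] - np.interp(xa[sel], xb, yb))
    return float(diff.max()), float(diff.mean())


def write_histogram_csv(path, curve: HistogramCurve) -> None:
    pd.DataFrame({"edge": curve.edges, "percent_volume": curve.percent_volume}).to_csv(
        path, index=False
    )


def read_histogram_csv(path) -> HistogramCurve:
    df = pd.read_csv(path)
    return HistogramCurve(df["edge"].to_numpy(), df["percent_volume"].to_numpy())
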