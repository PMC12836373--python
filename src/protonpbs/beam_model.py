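"""Analytic proton energy-range physics and beam commissioning fits.

The depth-dose engine rests on the power-law range-energy relation

    R0 = a * E^p          (range in cm of water, energy in MeV)

with the Bortfeld-approximation constants ``a = 0.0022 cm/MeV^p`` and
``p = 1.77``.  Inverting it gives the residual energy at water-equivalent
depth ``z``::

    E(z) = ((R0 - z) / a)^(1/p)          for z < R0

and differentiating gives the electronic stopping power

    S(z) = -dE/dz = (R0 - z)^(1/p - 1) / (p * a^(1/p))   [MeV/cm].

A pristine Bragg curve is modelled as the expectation of ``S`` over a
Gaussian-distributed range ``R0' ~ N(R0, sigma_R)`` (range straggling),
optionally multiplied by a linear fluence-loss factor.  This analytic model
is a desk-scale stand-in for a full Monte Carlo transport code: it captures
the Bragg-peak shape, range scaling and distal falloff, not nuclear-halo or
spectrum effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial

__all__ = [
    "EnergyRangeModel",
    "DepthDoseCurve",
    "RangeMetrics",
    "CalibrationModel",
    "DEFAULT_ENERGY_INTERVAL",
    "MEV_PER_CM_TO_KEV_PER_UM",
    "range_from_energy",
    "residual_energy",
    "stopping_power",
    "default_range_straggling",
    "bragg_curve",
    "extract_range_metrics",
    "fit_calibration",
    "build_sobp",
    "profile_fwhm",
    "calibrate_absolute",
    "read_curve_csv",
    "write_curve_csv",
    "read_calibration_table",
]

#: Clinical energy interval of the modelled synchrotron, MeV.
DEFAULT_ENERGY_INTERVAL = (48.08, 221.07)

#: 1 MeV/cm of water = 0.1 keV/um.
MEV_PER_CM_TO_KEV_PER_UM = 0.1

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class EnergyRangeModel:
    """Power-law range-energy relation R0 = a * E^p.

    Parameters
    ----------
    a : float
        Range coefficient, cm * MeV^(-p).  Must be positive.
    p : float
        Dimensionless exponent, in (1, 2).
    """

    a: float = 0.0022
    p: float = 1.77

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"range coefficient a must be > 0, got {self.a}")
        if not 1.0 < self.p < 2.0:
            raise ValueError(f"exponent p must lie in (1, 2), got {self.p}")


@dataclass
class DepthDoseCurve:
    """A sampled depth-dose curve.

    depths are in cm (strictly increasing), dose values are nonnegative
    (unit recorded in ``unit``), ``energy`` is the nominal beam energy label
    in MeV (NaN for composite curves such as an SOBP).
    """

    depths: np.ndarray
    dose: np.ndarray
    energy: float = float("nan")
    unit: str = "MeV/cm"

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.depths.ndim != 1 or self.depths.size < 10:
            raise ValueError("depth-dose curve needs >= 10 one-dimensional samples")
        if self.dose.shape != self.depths.shape:
            raise ValueError("depths and dose must have identical shapes")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be nonnegative")

    def value_at(self, depth_cm: float) -> float:
        """Linear interpolation of the curve at ``depth_cm``."""
        return float(np.interp(depth_cm, self.depths, self.dose))


@dataclass(frozen=True)
class RangeMetrics:
    """Depth markers of a Bragg curve: the peak and distal falloff points.

    r100 is the depth of maximum dose; r90/r80/r20 are the first depths
    distal to the peak where the dose falls to 90/80/20 % of the maximum.
    All in cm.
    """

    r100: float
    r90: float
    r80: float
    r20: float

    def __post_init__(self) -> None:
        if not (self.r100 <= self.r90 <= self.r80 <= self.r20):
            raise ValueError("range metrics must satisfy r100 <= r90 <= r80 <= r20")


def range_from_energy(energy_mev, model: EnergyRangeModel = EnergyRangeModel()):
    """Range in water, cm, for initial kinetic energy in MeV (R0 = a E^p)."""
    e = np.asarray(energy_mev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be positive")
    r = model.a * e**model.p
    return float(r) if np.isscalar(energy_mev) else r


def residual_energy(energy_mev, z_cm, model: EnergyRangeModel = EnergyRangeModel()):
    """Residual energy (MeV) at water-equivalent depth z (cm).

    Returns 0 for z >= R0 (the proton has stopped) so that vectorised grid
    evaluation is total; negative depths are a domain error.
    """
    z = np.asarray(z_cm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be nonnegative")
    r0 = range_from_energy(energy_mev, model)
    rem = np.maximum(r0 - z, 0.0)
    e = (rem / model.a) ** (1.0 / model.p)
    return float(e) if np.isscalar(z_cm) and np.isscalar(energy_mev) else e


def stopping_power(z_cm, r0_cm, model: EnergyRangeModel = EnergyRangeModel()):
    """Electronic stopping power S(z) = (R0-z)^(1/p-1) / (p a^(1/p)), MeV/cm.

    Depends only on the residual range R0 - z; returns 0 beyond R0.
    Multiply by :data:`MEV_PER_CM_TO_KEV_PER_UM` for keV/um.
    """
    z = np.asarray(z_cm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be nonnegative")
    rem = np.asarray(r0_cm, dtype=float) - z
    safe = np.where(rem > 0, rem, 1.0)
    s = np.where(
        rem > 0,
        safe ** (1.0 / model.p - 1.0) / (model.p * model.a ** (1.0 / model.p)),
        0.0,
    )
    return float(s) if np.isscalar(z_cm) and np.isscalar(r0_cm) else s


def default_range_straggling(r0_cm):
    """Gaussian range-straggling sigma (cm) as a function of range (cm).

    Uses the published power-law approximation sigma_R = 0.012 * R0^0.935.
    """
    return 0.012 * np.asarray(r0_cm, dtype=float) ** 0.935


def bragg_curve(
    energy_mev: float,
    sigma_r_cm: float | None = None,
    grid_cm=None,
    model: EnergyRangeModel = EnergyRangeModel(),
    fluence_loss_k: float = 0.0,
    _nq: int = 257,
) -> DepthDoseCurve:
    """Pristine Bragg curve: E[ S(z; R0') ] over R0' ~ N(R0, sigma_R).

    Parameters
    ----------
    energy_mev : float
        Initial kinetic energy, MeV.
    sigma_r_cm : float, optional
        Range-straggling sigma in cm.  ``None`` selects the default
        straggling law; 0 degenerates to the bare stopping-power curve
        truncated at R0.
    grid_cm : array, optional
        Depth sample points in cm.  Default: 0 .. R0 + 6 sigma in steps of
        min(0.05 cm, sigma/4).
    fluence_loss_k : float
        Optional linear fluence-loss factor (1 - k z / R0), clipped at 0.
        Default 0 (off); a cheap hook standing in for nuclear attenuation.

    Notes
    -----
    The Gaussian expectation is computed with the substitution
    u = (r - z)^(1/p), which removes the integrable endpoint singularity of
    the stopping power, leaving a smooth integrand handled by a fixed
    trapezoidal rule.
    """
    r0 = range_from_energy(energy_mev, model)
    sigma = default_range_straggling(r0) if sigma_r_cm is None else float(sigma_r_cm)
    if sigma < 0:
        raise ValueError("sigma_R must be nonnegative")
    if grid_cm is None:
        step = min(0.05, sigma / 4.0) if sigma > 0 else 0.02
        grid_cm = np.arange(0.0, r0 + 6.0 * sigma + step, step)
    z = np.asarray(grid_cm, dtype=float)
    if z.size == 0:
        raise ValueError("depth grid must be nonempty")
    if sigma == 0.0:
        dose = stopping_power(np.minimum(z, r0), r0, model) * (z < r0)
    else:
        invp = 1.0 / model.p
        lo = np.maximum(r0 - z - 8.0 * sigma, 0.0) ** invp
        hi = np.maximum(r0 - z + 8.0 * sigma, 0.0) ** invp
        frac = np.linspace(0.0, 1.0, _nq)
        u = lo[:, None] + (hi - lo)[:, None] * frac[None, :]
        integrand = np.exp(-((z[:, None] + u**model.p - r0) ** 2) / (2.0 * sigma**2))
        dose = np.trapezoid(integrand, u, axis=1) / (
            model.a**invp * np.sqrt(2.0 * np.pi) * sigma
        )
    if fluence_loss_k != 0.0:
        dose = dose * np.clip(1.0 - fluence_loss_k * z / r0, 0.0, None)
    return DepthDoseCurve(z, np.maximum(dose, 0.0), energy=float(energy_mev))


def _first_distal_crossing(depths, dose, level, name):
    """First depth distal to the maximum where dose crosses ``level``."""
    imax = int(np.argmax(dose))  # argmax takes the smallest depth on ties
    below = np.nonzero(dose[imax:] < level)[0]
    if below.size == 0:
        raise ValueError(f"dose never falls below the {name} level distal to the peak")
    j = imax + below[0]
    z1, z2, d1, d2 = depths[j - 1], depths[j], dose[j - 1], dose[j]
    return float(z1 + (level - d1) * (z2 - z1) / (d2 - d1))


def extract_range_metrics(curve: DepthDoseCurve) -> RangeMetrics:
    """R100 (peak depth) and distal R90/R80/R20 by linear interpolation.

    The distal search scans from the peak toward larger depth and takes the
    first crossing of each relative level; the metrics are invariant under
    uniform scaling of the dose.
    """
    dmax = float(curve.dose.max())
    if dmax <= 0:
        raise ValueError("curve has no positive dose")
    r100 = float(curve.depths[int(np.argmax(curve.dose))])
    levels = {"r90": 0.9, "r80": 0.8, "r20": 0.2}
    vals = {
        k: _first_distal_crossing(curve.depths, curve.dose, f * dmax, k)
        for k, f in levels.items()
    }
    return RangeMetrics(r100=r100, **vals)


@dataclass
class CalibrationModel:
    """Commissioning fits of a scanning beamline vs nominal energy.

    A linear model maps nominal to simulated energy; a cubic models the
    energy spread (MeV); two quartics model the spot FWHM (mm) in X and Y.
    Polynomials are stored in numpy's scaled-domain basis for conditioning;
    ``coefficients()`` exports the unscaled power-basis coefficients.
    """

    energy_map: Polynomial
    spread_poly: Polynomial
    fwhm_x_poly: Polynomial
    fwhm_y_poly: Polynomial
    validity_mev: tuple[float, float] = DEFAULT_ENERGY_INTERVAL
    residuals: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        e = np.linspace(*self.validity_mev, 501)
        if np.any(self.spread_poly(e) <= 0):
            raise ValueError("fitted energy spread is nonpositive inside validity interval")
        if np.any(self.fwhm_x_poly(e) <= 0) or np.any(self.fwhm_y_poly(e) <= 0):
            raise ValueError("fitted FWHM is nonpositive inside validity interval")

    def simulated_energy(self, nominal_mev):
        return self.energy_map(np.asarray(nominal_mev, dtype=float))

    def energy_spread(self, nominal_mev):
        return self.spread_poly(np.asarray(nominal_mev, dtype=float))

    def fwhm_x(self, nominal_mev):
        return self.fwhm_x_poly(np.asarray(nominal_mev, dtype=float))

    def fwhm_y(self, nominal_mev):
        return self.fwhm_y_poly(np.asarray(nominal_mev, dtype=float))

    def contains(self, energy_mev) -> bool:
        e = np.asarray(energy_mev, dtype=float)
        lo, hi = self.validity_mev
        return bool(np.all((e >= lo - 1e-9) & (e <= hi + 1e-9)))

    def coefficients(self) -> dict:
        """Unscaled power-basis coefficients, low order first."""
        return {
            "energy_map": self.energy_map.convert().coef.tolist(),
            "spread": self.spread_poly.convert().coef.tolist(),
            "fwhm_x": self.fwhm_x_poly.convert().coef.tolist(),
            "fwhm_y": self.fwhm_y_poly.convert().coef.tolist(),
        }


_CAL_COLUMNS = ["nominal_MeV", "simulated_MeV", "spread_MeV", "fwhm_x_mm", "fwhm_y_mm"]


def fit_calibration(samples: pd.DataFrame) -> CalibrationModel:
    """Least-squares commissioning fits from a measured/simulated table.

    ``samples`` must contain columns nominal_MeV, simulated_MeV, spread_MeV,
    fwhm_x_mm, fwhm_y_mm with at least 5 distinct energies (the quartic FWHM
    fits are otherwise unidentifiable).
    """
    missing = [c for c in _CAL_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"calibration table missing columns: {missing}")
    e = samples["nominal_MeV"].to_numpy(dtype=float)
    if np.unique(e).size < 5:
        raise ValueError("need at least 5 distinct energies to fit a quartic")
    fits = {}
    resid = {}
    for col, deg, key in [
        ("simulated_MeV", 1, "energy_map"),
        ("spread_MeV", 3, "spread"),
        ("fwhm_x_mm", 4, "fwhm_x"),
        ("fwhm_y_mm", 4, "fwhm_y"),
    ]:
        y = samples[col].to_numpy(dtype=float)
        poly = Polynomial.fit(e, y, deg)
        fits[key] = poly
        resid[key] = y - poly(e)
    return CalibrationModel(
        energy_map=fits["energy_map"],
        spread_poly=fits["spread"],
        fwhm_x_poly=fits["fwhm_x"],
        fwhm_y_poly=fits["fwhm_y"],
        validity_mev=(float(e.min()), float(e.max())),
        residuals=resid,
    )


def build_sobp(
    components,
    grid_cm,
    model: EnergyRangeModel = EnergyRangeModel(),
    sigma_r_cm=None,
    fluence_loss_k: float = 0.0,
) -> DepthDoseCurve:
    """Spread-out Bragg peak: weighted sum of pristine curves on one grid.

    ``components`` is a sequence of (energy_MeV, weight) pairs; weights must
    be nonnegative with at least one positive.  The result is linear in the
    weights.
    """
    comps = list(components)
    if not comps:
        raise ValueError("SOBP needs at least one component")
    weights = np.array([w for _, w in comps], dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(weights > 0):
        raise ValueError("at least one SOBP weight must be positive")
    grid = np.asarray(grid_cm, dtype=float)
    total = np.zeros_like(grid)
    for (energy, w) in comps:
        if w == 0:
            continue
        c = bragg_curve(energy, sigma_r_cm, grid, model, fluence_loss_k)
        total += w * c.dose
    return DepthDoseCurve(grid, total, energy=float("nan"))


def profile_fwhm(positions_mm, values) -> float:
    """Full width at half maximum of a unimodal profile, mm.

    Half-maximum crossings are located by linear interpolation on each side
    of the peak; invariant under translation of positions and scaling of
    values.
    """
    x = np.asarray(positions_mm, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3 or y.shape != x.shape:
        raise ValueError("profile needs matching 1-d position/value arrays (>= 3 samples)")
    imax = int(np.argmax(y))
    half = 0.5 * y[imax]
    left = np.nonzero(y[: imax + 1] < half)[0]
    right = np.nonzero(y[imax:] < half)[0]
    if left.size == 0 or right.size == 0:
        raise ValueError("profile does not cross half maximum on both sides of the peak")
    i = left[-1]  # last sample below half on the rising edge
    x_lo = x[i] + (half - y[i]) * (x[i + 1] - x[i]) / (y[i + 1] - y[i])
    j = imax + right[0]
    x_hi = x[j - 1] + (half - y[j - 1]) * (x[j] - x[j - 1]) / (y[j] - y[j - 1])
    return float(x_hi - x_lo)


def calibrate_absolute(
    curve: DepthDoseCurve, depth_cm: float, measured_dose_gy: float, primaries: float = 1.0
) -> float:
    """Scalar Gy-per-primary factor matching the curve to a reference point.

    Returns the factor f such that f * curve(depth) equals the measured dose
    per primary at the reference depth.
    """
    if not curve.depths[0] <= depth_cm <= curve.depths[-1]:
        raise ValueError("reference depth outside curve support")
    if primaries <= 0:
        raise ValueError("primaries must be positive")
    v = curve.value_at(depth_cm)
    if v == 0:
        raise ValueError("simulated dose is zero at the reference depth")
    return measured_dose_gy / primaries / v


# -- CSV interfaces ---------------------------------------------------------

def write_curve_csv(path, curve: DepthDoseCurve, position_unit: str = "cm") -> None:
    """Write a curve as `position_cm,value` (or `position_mm`) CSV."""
    pd.DataFrame(
        {f"position_{position_unit}": curve.depths, "value": curve.dose}
    ).to_csv(path, index=False)


def read_curve_csv(path) -> DepthDoseCurve:
    df = pd.read_csv(path)
    pos_cols = [c for c in df.columns if c.startswith("position_")]
    if not pos_cols:
        raise ValueError("curve CSV needs a position_cm or position_mm column")
    pos = df[pos_cols[0]].to_numpy(dtype=float)
    if pos_cols[0].endswith("_mm"):
        pos = pos / 10.0
    return DepthDoseCurve(pos, df["value"].to_numpy(dtype=float))


def read_calibration_table(path) -> pd.DataFrame:
    """Read a commissioning CSV (nominal_MeV,simulated_MeV,spread_MeV,fwhm_x_mm,fwhm_y_mm)."""
    df = pd.read_csv(path)
    missing = [c for c in _CAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"calibration table missing columns: {missing}")
    return df
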