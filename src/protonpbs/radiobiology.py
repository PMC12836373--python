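"""Variable proton RBE models and RBE-weighted dose maps.

Protons are conventionally assigned a constant RBE of 1.1, but the
biological effectiveness rises with dose-averaged LET, especially near the
distal edge of a field and in late-responding tissues (low alpha/beta).
Three published phenomenological models are implemented:

* McMahon (linear in LETd):      RBE = 1 + 0.055 * LETd
* McNamara (linear-quadratic):   RBE(Dp, a/b, LETd) interpolating between
    RBEmax = 0.99064 + 0.35605 * LETd / (a/b)      (low-dose limit)
    RBEmin = 1.1012 - 0.0038703 * sqrt(a/b) * LETd (high-dose limit)
* Wedenberg (linear-quadratic with LET-dependent alpha only):
    RBE = -(a/b)/(2D) + (1/D) sqrt( (a/b)^2/4 + (q LETd + a/b) D + D^2 ),
    q = 0.434 Gy um/keV.

Doses entering the LQ-based models are per-fraction physical doses; the
RBE-weighted total course dose is n_fractions * RBE(d, LETd) * d with
d = D_total / n_fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import LETD_NODATA, VoxelGrid

__all__ = [
    "RBE_MODELS",
    "RadiobiologyParams",
    "rbe_constant",
    "rbe_mcm",
    "rbe_mcn",
    "rbe_wed",
    "rbe_weighted_dose",
]

RBE_MODELS = ("constant", "mcm", "mcn", "wed")

#: Wedenberg LET-response slope, Gy um/keV.
DEFAULT_Q = 0.434

# McNamara fit constants
_MCN_MAX_0 = 0.99064
_MCN_MAX_SLOPE = 0.35605  # Gy (keV/um)^-1
_MCN_MIN_0 = 1.1012
_MCN_MIN_SLOPE = 0.0038703  # Gy^-1/2 (keV/um)^-1


@dataclass(frozen=True)
class RadiobiologyParams:
    """Tissue and fractionation parameters for the RBE models.

    alpha_beta_gy: LQ alpha/beta ratio of the tissue (Gy); ~3 Gy for
    late-responding tissue such as rib.  q: Wedenberg slope (Gy um/keV).
    n_fractions converts a total-course dose grid to the per-fraction dose
    the LQ models are evaluated at; it has no default because the choice
    changes the result.
    """

    model: str
    n_fractions: int
    alpha_beta_gy: float = 3.0
    q: float = DEFAULT_Q

    def __post_init__(self) -> None:
        if self.model not in RBE_MODELS:
            raise ValueError(f"unknown RBE model {self.model!r}; expected one of {RBE_MODELS}")
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha/beta must be positive")
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


def _check_letd(letd):
    l = np.asarray(letd, dtype=float)
    if np.any(l < 0):
        raise ValueError("LETd must be nonnegative")
    return l


def rbe_constant(letd=None):
    """The clinical constant RBE of 1.1 (ignores LETd)."""
    return 1.1 if letd is None or np.isscalar(letd) else np.full(np.shape(letd), 1.1)


def rbe_mcm(letd):
    """McMahon model: RBE = 1 + 0.055 LETd (keV/um); exactly 1 at LETd = 0."""
    l = _check_letd(letd)
    out = 1.0 + 0.055 * l
    return float(out) if np.isscalar(letd) else out


def rbe_mcn(dose_per_fraction_gy, alpha_beta_gy, letd):
    """McNamara model at per-fraction dose Dp (Gy).

    RBE = [ sqrt((a/b)^2 + 4 Dp (a/b) RBEmax + 4 Dp^2 RBEmin^2) - (a/b) ]
          / (2 Dp);
    tends to RBEmax as Dp -> 0 and to RBEmin as Dp -> inf.  Raises if the
    parameters push RBEmin negative (outside the model's fitted domain).
    """
    dp = np.asarray(dose_per_fraction_gy, dtype=float)
    ab = float(alpha_beta_gy)
    l = _check_letd(letd)
    if np.any(dp <= 0):
        raise ValueError("per-fraction dose must be positive")
    if ab <= 0:
        raise ValueError("alpha/beta must be positive")
    rbe_max = _MCN_MAX_0 + _MCN_MAX_SLOPE * l / ab
    rbe_min = _MCN_MIN_0 - _MCN_MIN_SLOPE * np.sqrt(ab) * l
    if np.any(rbe_min < 0):
        raise ValueError("RBEmin < 0: LETd * sqrt(alpha/beta) outside the fitted domain")
    out = (np.sqrt(ab**2 + 4.0 * dp * ab * rbe_max + 4.0 * dp**2 * rbe_min**2) - ab) / (2.0 * dp)
    return float(out) if out.ndim == 0 else out


def rbe_wed(dose_gy, alpha_beta_gy, letd, q: float = DEFAULT_Q):
    """Wedenberg model at dose D (Gy); exactly 1 at LETd = 0 for any D, a/b."""
    d = np.asarray(dose_gy, dtype=float)
    ab = float(alpha_beta_gy)
    l = _check_letd(letd)
    if np.any(d <= 0):
        raise ValueError("dose must be positive")
    if ab <= 0 or q <= 0:
        raise ValueError("alpha/beta and q must be positive")
    out = -ab / (2.0 * d) + np.sqrt(0.25 * ab**2 + (q * l + ab) * d + d**2) / d
    return float(out) if out.ndim == 0 else out


def rbe_weighted_dose(
    physical_dose: VoxelGrid, letd: VoxelGrid | None, params: RadiobiologyParams
) -> VoxelGrid:
    """RBE-weighted total-course dose grid, Gy(RBE).

    ``physical_dose`` is the total course physical dose.  The RBE is
    evaluated voxelwise at the per-fraction dose D/n_fractions and the local
    LETd; voxels with zero dose get zero regardless of the LETd sentinel.
    The constant model needs no LETd grid.
    """
    if params.model == "constant":
        return physical_dose.like(1.1 * physical_dose.values, "dose", {"unit": "Gy(RBE)", "rbe_model": "constant"})
    if letd is None:
        raise ValueError(f"model {params.model!r} requires a LETd grid")
    if not physical_dose.congruent(letd):
        raise ValueError("dose and LETd grids are not congruent")
    nodata = float(letd.meta.get("nodata", LETD_NODATA))
    dose = physical_dose.values
    pos = dose > 0
    l = np.where(letd.values == nodata, 0.0, letd.values)
    l = np.where(pos, l, 0.0)
    dp = np.where(pos, dose / params.n_fractions, 1.0)  # dummy where dose is 0
    if params.model == "mcm":
        rbe = rbe_mcm(l)
    elif params.model == "mcn":
        rbe = rbe_mcn(dp, params.alpha_beta_gy, l)
    else:
        rbe = rbe_wed(dp, params.alpha_beta_gy, l, params.q)
    out = np.where(pos, rbe * dose, 0.0)
    return physical_dose.like(out, "dose", {"unit": "Gy(RBE)", "rbe_model": params.model})
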