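"""Dose–response scoring of lipid-peroxidation inhibition.

The ω score of each spectrum is mapped to the inhibition ordinate

    y = −ln[(ω − ω_∞) / (ω₀ − ω_∞)],

where ω₀ is the uninhibited score and ω_∞ the fully-inhibited one, so y = 0
with no inhibitor and y = ln 2 = 0.693 at 50 % inhibition.  The ordinate is
regressed linearly on inhibitor concentration; the concentration producing
ln 2 on that line defines IC₅₀, and pI₅₀ = −log₁₀(IC₅₀ / 1 mol L⁻¹).

Because the published treatment converts pI₅₀ "from the obtained slopes",
the default IC₅₀ is ln 2 / slope (``ic50_from="slope"``); this ignores any
intercept contributed by a co-inhibitor, which is exactly what the
cross-competition design needs.  ``ic50_from="crossing"`` instead solves for
the concentration where the fitted line (with intercept) crosses ln 2.

Cross-competition is summarised as the least-squares slope of pI₅₀ against
the concentration of the competing scavenger (dpI₅₀ᴰʳᵘᵍ/d[TRO] and its
mirror image).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .svd import OmegaScores

__all__ = [
    "LN2",
    "UNIT_TO_MOLAR",
    "OrdinateResult",
    "DoseResponseFit",
    "CompetitionResult",
    "inhibition_ordinate",
    "fit_inhibition",
    "estimate_asymptotes",
    "calibrate_to_molarity",
    "competition_slopes",
]

LN2 = math.log(2.0)

#: conversion factor from a concentration unit to mol L⁻¹
UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9}


@dataclass
class OrdinateResult:
    """Inhibition ordinate with censoring flags.

    Scores at or below ω_∞ (over-complete inhibition, possible under noise)
    have no defined −ln value; they are returned as NaN with ``censored``
    True so downstream fits can drop them explicitly instead of silently
    propagating NaN.
    """

    values: np.ndarray
    censored: np.ndarray

    def usable(self) -> np.ndarray:
        return ~self.censored


@dataclass
class DoseResponseFit:
    """A linear inhibition fit and the derived IC₅₀ / pI₅₀.

    ``unit`` names the concentration unit of ``concentrations`` and
    ``ic50``; pI₅₀ is always on the mol L⁻¹ scale and therefore invariant to
    the unit choice.  ``defined`` is False when the slope is non-positive:
    IC₅₀/pI₅₀ are then NaN, never fabricated.
    """

    concentrations: np.ndarray
    ordinate: np.ndarray
    unit: str
    slope: float
    intercept: float
    r2: float
    ic50: float
    pI50: float
    through_origin: bool = False
    defined: bool = True
    n_censored: int = 0
    curvature_warning: bool = False


@dataclass
class CompetitionResult:
    """pI₅₀ of one agent as a linear function of a competing modifier."""

    modifier_concs: np.ndarray
    pI50_values: np.ndarray
    slope: float
    intercept: float
    r2: float
    modifier_unit: str = "uM"


def inhibition_ordinate(
    omega: np.ndarray | Sequence[float], omega0: float, omega_inf: float
) -> OrdinateResult:
    """Map ω scores to y = −ln[(ω − ω_∞)/(ω₀ − ω_∞)] with censoring flags."""
    if omega0 == omega_inf:
        raise ValueError("omega0 must differ from omega_inf")
    omega = np.asarray(omega, dtype=float)
    frac = (omega - omega_inf) / (omega0 - omega_inf)
    censored = frac <= 0
    values = np.full_like(frac, np.nan)
    values[~censored] = -np.log(frac[~censored])
    return OrdinateResult(values=values, censored=censored)


def _curvature_check(x: np.ndarray, y: np.ndarray) -> bool:
    """True when a quadratic term (upward-convex) clearly improves the fit."""
    if x.size < 4 or np.ptp(x) == 0:
        return False
    lin = np.polyfit(x, y, 1)
    quad = np.polyfit(x, y, 2)
    ss_lin = float(np.sum((y - np.polyval(lin, x)) ** 2))
    ss_quad = float(np.sum((y - np.polyval(quad, x)) ** 2))
    return quad[0] < 0 and ss_lin > 0 and (ss_lin - ss_quad) / ss_lin > 0.2


def fit_inhibition(
    concs: np.ndarray | Sequence[float],
    ordinate: OrdinateResult | np.ndarray | Sequence[float],
    through_origin: bool = False,
    unit: str = "mM",
    ic50_from: str = "slope",
) -> DoseResponseFit:
    """Least-squares line through (concentration, ordinate) points.

    Censored ordinate points are dropped (not clipped); at least three usable
    points are required.  With ``ic50_from="slope"``, IC₅₀ = ln 2 / slope;
    with ``"crossing"``, IC₅₀ = (ln 2 − intercept) / slope.  A non-positive
    slope leaves IC₅₀/pI₅₀ undefined (NaN, ``defined=False``).  Upward-convex
    curvature is detected and warned about; the linear gradient is still
    reported as the summary.
    """
    if unit not in UNIT_TO_MOLAR:
        raise ValueError(f"unknown concentration unit {unit!r}")
    if ic50_from not in ("slope", "crossing"):
        raise ValueError("ic50_from must be 'slope' or 'crossing'")
    concs = np.asarray(concs, dtype=float)
    if isinstance(ordinate, OrdinateResult):
        keep = ordinate.usable()
        y = ordinate.values[keep]
        x = concs[keep]
        n_censored = int(np.count_nonzero(~keep))
    else:
        y = np.asarray(ordinate, dtype=float)
        keep = np.isfinite(y)
        n_censored = int(np.count_nonzero(~keep))
        x, y = concs[keep], y[keep]
    if x.size < 3:
        raise ValueError(f"need >= 3 usable points, have {x.size}")

    if through_origin:
        denom = float(x @ x)
        if denom == 0:
            raise ValueError("all concentrations are zero")
        slope = float(x @ y) / denom
        intercept = 0.0
        yhat = slope * x
    else:
        slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
        yhat = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    curvature = _curvature_check(x, y)
    if curvature:
        warnings.warn(
            "inhibition curve is upward-convex; the linear gradient is only "
            "a convenience summary",
            stacklevel=2,
        )

    if slope > 0:
        ic50 = (LN2 - intercept) / slope if ic50_from == "crossing" else LN2 / slope
        defined = ic50 > 0
    else:
        ic50, defined = float("nan"), False
    pI50 = -math.log10(ic50 * UNIT_TO_MOLAR[unit]) if defined else float("nan")

    return DoseResponseFit(
        concentrations=x,
        ordinate=y,
        unit=unit,
        slope=slope,
        intercept=intercept,
        r2=r2,
        ic50=ic50 if defined else float("nan"),
        pI50=pI50,
        through_origin=through_origin,
        defined=defined,
        n_censored=n_censored,
        curvature_warning=curvature,
    )


def _is_zero_inhibitor(cond: Mapping[str, Any]) -> bool:
    if cond.get("role") == "zero":
        return True
    conc_keys = [
        k
        for k in cond
        if any(k.endswith("_" + u) for u in ("uM", "mM", "nM", "M"))
    ]
    return bool(conc_keys) and all(cond[k] == 0 for k in conc_keys)


def estimate_asymptotes(
    scores: OmegaScores, omega_inf_role: str = "full"
) -> tuple[float, float]:
    """Estimate (ω₀, ω_∞) from designated columns of a scored titration.

    ω₀ is the mean score over zero-inhibitor columns (``role=zero`` or all
    concentration entries zero); ω_∞ the mean over columns tagged with
    ``role=full`` (conditions where the signal overlaps the lowest-intensity,
    100 %-inhibition spectra).  Raises if either set is empty — supply
    explicit values in that case.
    """
    zero_idx = [j for j, c in enumerate(scores.conditions) if _is_zero_inhibitor(c)]
    full_idx = [
        j for j, c in enumerate(scores.conditions) if c.get("role") == omega_inf_role
    ]
    if not zero_idx or not full_idx:
        raise ValueError(
            "no designated zero-inhibitor and/or full-inhibition columns; "
            "pass omega0/omega_inf explicitly"
        )
    omega0 = float(np.mean(scores.omega[zero_idx]))
    omega_inf = float(np.mean(scores.omega[full_idx]))
    return omega0, omega_inf


def calibrate_to_molarity(
    calib_scores: np.ndarray | Sequence[float],
    calib_concs: np.ndarray | Sequence[float],
    sample_scores: np.ndarray | Sequence[float],
    through_origin: bool = True,
) -> np.ndarray:
    """Convert sample ω scores to concentration via a linear standard series.

    Requires >= 2 calibration points with non-degenerate scores; samples
    outside the calibrated score range trigger an extrapolation warning.
    """
    cs = np.asarray(calib_scores, dtype=float)
    cc = np.asarray(calib_concs, dtype=float)
    ss = np.asarray(sample_scores, dtype=float)
    if cs.size != cc.size or cs.size < 2:
        raise ValueError("need >= 2 matched calibration points")
    if np.ptp(cs) == 0:
        raise ValueError("degenerate calibration: zero score variance")
    if through_origin:
        slope = float(cs @ cc) / float(cs @ cs)
        intercept = 0.0
    else:
        slope, intercept = (float(v) for v in np.polyfit(cs, cc, 1))
    if np.any(ss < cs.min() - 1e-12) or np.any(ss > cs.max() + 1e-12):
        warnings.warn(
            "sample scores fall outside the calibration range; extrapolating",
            stacklevel=2,
        )
    return slope * ss + intercept


def competition_slopes(
    groups: Mapping[float, DoseResponseFit],
    modifier_unit: str = "uM",
) -> CompetitionResult:
    """Slope of pI₅₀ against the concentration of a competing modifier.

    *groups* maps modifier concentration -> single-agent fit at that level.
    At least three levels with a defined pI₅₀ are required.  The intercept
    estimates the single-agent pI₅₀ at zero modifier.
    """
    concs, pI50s = [], []
    for conc in sorted(groups):
        fit = groups[conc]
        if fit.defined and np.isfinite(fit.pI50):
            concs.append(float(conc))
            pI50s.append(fit.pI50)
    if len(concs) < 3:
        raise ValueError(f"need >= 3 defined pI50 values, have {len(concs)}")
    x = np.asarray(concs)
    y = np.asarray(pI50s)
    slope, intercept = (float(v) for v in np.polyfit(x, y, 1))
    yhat = slope * x + intercept
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return CompetitionResult(
        modifier_concs=x,
        pI50_values=y,
        slope=slope,
        intercept=intercept,
        r2=r2,
        modifier_unit=modifier_unit,
    )
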