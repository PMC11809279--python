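"""DSC thermogram analysis: onset melting temperature, fusion enthalpy/entropy.

The melting temperature is the extrapolated onset: the tangent at the
left-side inflection point of the endotherm intersected with the pre-peak
baseline.  The fusion enthalpy is the baseline-subtracted numerical integral
of the peak converted to a molar quantity, and the fusion entropy follows
from Clausius, Δ_fus S⁰ = Δ_fus H⁰ / T_m.  Walden's empirical rule puts
Δ_fus S⁰ near 56.5 J K⁻¹ mol⁻¹ for organic compounds that do not associate
in the melt; the excess over that constant is reported as a molecular
flexibility / association descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Thermogram

__all__ = [
    "WALDEN_CONSTANT",
    "FusionResult",
    "melting_temperature",
    "fusion_enthalpy",
    "fusion_entropy",
    "analyze_thermogram",
]

#: Walden's constant, J K⁻¹ mol⁻¹
WALDEN_CONSTANT = 56.5


@dataclass
class FusionResult:
    """Fusion thermodynamics of one melt; dS = dH / Tm exactly."""

    Tm: float             # K, extrapolated onset
    dH: float             # J mol⁻¹
    dS: float             # J K⁻¹ mol⁻¹
    walden_excess: float  # dS − 56.5 J K⁻¹ mol⁻¹


def _baseline_and_window(
    tg: Thermogram, departure_sd: float = 3.0
) -> tuple[np.ndarray, int, int, int]:
    """Fit the flank baseline and locate the peak window.

    The baseline is a line fit to the outer flanks, refit after excluding the
    region where the signal departs from it by more than ``departure_sd``
    times the flank residual SD.  Returns (baseline values, window start,
    peak index, window end).  Raises when no peak rises above the departure
    threshold (pure baseline).
    """
    T = tg.temperature
    y = tg.endo_up_signal
    n = T.size
    flank = max(n // 10, 5)
    idx = np.r_[0:flank, n - flank : n]
    for _ in range(3):
        coef = np.polyfit(T[idx], y[idx], 1)
        resid = y[idx] - np.polyval(coef, T[idx])
        sd = float(np.std(resid))
        corrected = y - np.polyval(coef, T)
        above = corrected > departure_sd * max(sd, 1e-12)
        if not np.any(above):
            raise ValueError("no peak above the baseline departure threshold")
        keep = ~above
        if keep.sum() < 4:
            break
        idx = np.flatnonzero(keep)
    baseline = np.polyval(coef, T)
    corrected = y - baseline
    peak = int(np.argmax(corrected))
    thresh = departure_sd * max(sd, 1e-12)
    start = peak
    while start > 0 and corrected[start - 1] > thresh:
        start -= 1
    end = peak
    while end < n - 1 and corrected[end + 1] > thresh:
        end += 1
    return baseline, start, peak, end


def melting_temperature(tg: Thermogram) -> float:
    """Extrapolated onset temperature of the dominant endotherm (K).

    The tangent with the gradient at the left-side inflection point of the
    baseline-corrected peak is intersected with the (refit) baseline; the
    result is invariant to the baseline's slope and offset.
    """
    baseline, start, peak, _ = _baseline_and_window(tg)
    T = tg.temperature
    corrected = tg.endo_up_signal - baseline
    if peak - start < 2:
        raise ValueError("left flank too short to locate an inflection point")
    grad = np.gradient(corrected, T)
    seg = slice(start, peak + 1)
    i = start + int(np.argmax(grad[seg]))
    slope = grad[i]
    if slope <= 0:
        raise ValueError("no rising inflection found on the left flank")
    # tangent y = corrected[i] + slope·(T − T[i]) crosses the baseline at 0
    return float(T[i] - corrected[i] / slope)


def fusion_enthalpy(
    tg: Thermogram,
    molar_mass: float | None = None,
    sample_mass: float | None = None,
) -> float:
    """Molar fusion enthalpy (J mol⁻¹) from the baseline-subtracted peak area.

    Heat flow is interpreted in mW; the peak window runs from baseline
    departure to return.  ``molar_mass`` (g mol⁻¹) and ``sample_mass`` (mg)
    default to the thermogram metadata.  A negative area after baseline
    subtraction is an error.
    """
    molar_mass = molar_mass if molar_mass is not None else tg.meta.get("molar_mass_g_mol")
    sample_mass = sample_mass if sample_mass is not None else tg.meta.get("sample_mass_mg")
    if not molar_mass or molar_mass <= 0 or not sample_mass or sample_mass <= 0:
        raise ValueError("positive molar_mass (g/mol) and sample_mass (mg) required")
    try:
        baseline, start, _, end = _baseline_and_window(tg)
    except ValueError:
        # no peak above the departure threshold: zero-area endotherm
        return 0.0
    T = tg.temperature
    corrected = tg.endo_up_signal - baseline
    area_mWK = float(np.trapezoid(corrected[start : end + 1], T[start : end + 1]))
    if area_mWK < 0:
        raise ValueError("negative peak area after baseline subtraction")
    rate_K_per_s = tg.scan_rate / 60.0
    area_J = area_mWK * 1e-3 / rate_K_per_s
    moles = sample_mass * 1e-3 / molar_mass
    return area_J / moles


def fusion_entropy(dH: float, Tm: float) -> FusionResult:
    """Clausius fusion entropy dS = dH / Tm and its excess over Walden's constant."""
    if Tm <= 0:
        raise ValueError("Tm must be positive (kelvin)")
    dS = dH / Tm
    return FusionResult(Tm=Tm, dH=dH, dS=dS, walden_excess=dS - WALDEN_CONSTANT)


def analyze_thermogram(
    tg: Thermogram,
    molar_mass: float | None = None,
    sample_mass: float | None = None,
) -> FusionResult:
    """Full chain: onset Tm, molar ΔH, Clausius ΔS, Walden excess."""
    Tm = melting_temperature(tg)
    dH = fusion_enthalpy(tg, molar_mass=molar_mass, sample_mass=sample_mass)
    return fusion_entropy(dH, Tm)
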