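"""Synthetic assay data with known ground truth.

Every downstream stage of the pipeline (unmixing, dose–response, EPR,
anisotropy, DSC) is exercised against data generated here, where the truth
is known exactly.  The generators emulate:

* **TBARS optical spectra** — a quantitative 530 nm chromogen peak, a 495 nm
  shoulder in the standard-MDA shape, and (for lipid-peroxidation samples) a
  455 nm by-product peak whose amplitude co-occurs with the 530 nm peak only
  noisily: ``A₄₅₅ = coupling · A₅₃₀ · (1 + ε)``, ε ~ N(0, coupling_jitter²).
  This non-quantitative co-occurrence is what the ω score is built to cancel.
* **Inhibition titrations** — additive inhibition ordinates for drug and
  scavenger, with the drug's pI₅₀ attenuated linearly in the scavenger
  concentration (the cross-competition model the analysis assumes).
* **EPR derivative multiplets** — equidistant derivative-of-Gaussian lines
  (quintet for DPPH-like radicals, a_N = 8.86 G; doublet for galvinoxyl-like,
  4.75 G) scaled by the remaining radical fraction, exactly antisymmetric
  about the multiplet centre when noise is off.
* **Polarized fluorescence pairs** — Gaussian emission bands whose areas
  satisfy the anisotropy relation R = (VV − G·VH)/(VV + 2G·VH) exactly.
* **DSC endotherms** — an affine baseline plus a Gaussian melting peak of
  prescribed molar fusion enthalpy.

All generators are deterministic given their parameters and seed.  Line
shapes are Gaussian (optical, DSC) or Gaussian-derivative (EPR): analytically
controllable areas, inflection points and antisymmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np

from .dose import LN2
from .io import AxisKind, SpectralMatrix, Spectrum, Thermogram

__all__ = [
    "TbarsModel",
    "EprKind",
    "EprModel",
    "InhibitionTruth",
    "gen_tbars_spectrum",
    "gen_tbars_titration",
    "gen_epr_spectrum",
    "gen_epr_decay_series",
    "gen_polarized_pair",
    "gen_thermogram",
]


def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


# ---------------------------------------------------------------------------
# TBARS
# ---------------------------------------------------------------------------


@dataclass
class TbarsModel:
    """Shape and noise parameters of synthetic TBARS spectra.

    ``response`` is the 530 nm peak absorbance per μM of MDA equivalent
    (0.05 AU/μM puts the 20 μM top standard near 1 AU).  Peaks are
    (center nm, sigma nm) Gaussians; the 495 nm shoulder belongs to the
    standard-MDA shape only, the 455 nm by-product to lipid samples only.
    """

    peak530: tuple[float, float] = (530.0, 22.0)
    peak455: tuple[float, float] = (455.0, 20.0)
    shoulder495: tuple[float, float] = (495.0, 15.0)
    shoulder_frac: float = 0.35       # 495 nm amplitude relative to 530 nm
    coupling: float = 0.35            # mean A455/A530 ratio in lipid samples
    coupling_jitter: float = 0.2      # sd of the relative 455 nm jitter ε
    response: float = 0.05            # AU per μM MDA equivalent at 530 nm
    noise_sd: float = 0.003           # additive absorbance noise, AU
    grid: tuple[float, float, float] = (400.0, 700.0, 1.0)  # nm start/stop/step
    seed: int = 0

    def __post_init__(self) -> None:
        for _, width in (self.peak530, self.peak455, self.shoulder495):
            if width <= 0:
                raise ValueError("peak widths must be positive")
        if self.coupling < 0 or self.coupling_jitter < 0 or self.noise_sd < 0:
            raise ValueError("coupling and noise parameters must be >= 0")

    def wavelengths(self) -> np.ndarray:
        start, stop, step = self.grid
        return np.arange(start, stop + step / 2, step)


def _tbars_intensity(
    model: TbarsModel,
    wl: np.ndarray,
    mda_equiv: float,
    is_lipid: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    a530 = model.response * mda_equiv
    y = a530 * _gauss(wl, *model.peak530)
    if is_lipid:
        eps = rng.normal(0.0, model.coupling_jitter) if model.coupling_jitter else 0.0
        a455 = max(model.coupling * a530 * (1.0 + eps), 0.0)
        y += a455 * _gauss(wl, *model.peak455)
    else:
        y += model.shoulder_frac * a530 * _gauss(wl, *model.shoulder495)
    if model.noise_sd:
        y = y + rng.normal(0.0, model.noise_sd, wl.size)
    return y


def gen_tbars_spectrum(
    model: TbarsModel, mda_equiv: float, is_lipid: bool = True
) -> Spectrum:
    """One TBARS spectrum at a given MDA-equivalent concentration (μM).

    The 530 nm amplitude is strictly proportional to ``mda_equiv``.  Lipid
    samples get the noisily-coupled 455 nm by-product peak; the standard-MDA
    shape gets the 495 nm shoulder instead.
    """
    if mda_equiv < 0:
        raise ValueError("mda_equiv must be >= 0")
    rng = np.random.default_rng(model.seed)
    wl = model.wavelengths()
    y = _tbars_intensity(model, wl, mda_equiv, is_lipid, rng)
    return Spectrum(
        wl,
        y,
        AxisKind.wavelength,
        {"MDA_uM": mda_equiv, "role": "sample" if is_lipid else "calib"},
    )


@dataclass
class InhibitionTruth:
    """Ground truth of a two-agent inhibition titration.

    ``pI50_drug``/``pI50_tro`` are the single-agent potencies on the molar
    scale; ``cross_slope_drug_per_tro`` attenuates the drug's pI₅₀ linearly
    in the scavenger concentration (pI₅₀ units per μM of Trolox, typically a
    few times −10⁻³ here).  ``omega0``/``omega_inf`` are the MDA-equivalent
    amplitudes (μM) of the uninhibited and fully-inhibited endpoints — the ω
    score itself is only defined up to the SVD scaling, so truth lives on
    the amplitude scale.
    """

    pI50_drug: float = 3.7
    pI50_tro: float = 4.9
    cross_slope_drug_per_tro: float = -48e-3
    omega0: float = 20.0
    omega_inf: float = 0.0

    def __post_init__(self) -> None:
        if not self.omega0 > self.omega_inf:
            raise ValueError("omega0 must exceed omega_inf")

    def drug_pI50_at(self, tro_uM: float) -> float:
        return self.pI50_drug + self.cross_slope_drug_per_tro * tro_uM

    def ordinate(self, drug_mM: float, tro_uM: float) -> float:
        """Additive inhibition ordinate y = y_drug + y_TRO."""
        y = 0.0
        if drug_mM > 0:
            ic50_mM = 10.0 ** (-self.drug_pI50_at(tro_uM)) * 1e3
            y += LN2 * drug_mM / ic50_mM
        if tro_uM > 0:
            ic50_uM = 10.0 ** (-self.pI50_tro) * 1e6
            y += LN2 * tro_uM / ic50_uM
        return y


#: MDA-equivalent concentrations (μM) of the packaged standard series.
DEFAULT_CALIB_UM = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)


def gen_tbars_titration(
    truth: InhibitionTruth,
    drug_concs: Sequence[float],
    tro_concs: Sequence[float],
    model: TbarsModel | None = None,
    drug_name: str = "IMP",
    drug_unit: str = "mM",
    calib_concs: Sequence[float] | None = DEFAULT_CALIB_UM,
) -> SpectralMatrix:
    """Full factorial (drug x TRO) TBARS titration with ground truth recorded.

    One lipid-sample column per (drug, TRO) pair, the underlying 530 nm
    amplitude following the additive two-agent inhibition model mapped back
    through the (ω₀, ω_∞) amplitude range.  Appends a full-inhibition
    reference column (``role=full``) and, unless disabled, a standard-MDA
    calibration series (``role=calib``) — the decomposition matrix is meant
    to contain the calibration spectra.  The (0, 0) column is tagged
    ``role=zero``.  Truth parameters are stored in the matrix-level ``meta``.
    """
    if len(drug_concs) == 0 or len(tro_concs) == 0:
        raise ValueError("concentration grids must be non-empty")
    if model is None:
        model = TbarsModel()
    rng = np.random.default_rng(model.seed)
    wl = model.wavelengths()

    columns, conditions = [], []
    for tro in tro_concs:
        for drug in drug_concs:
            frac = math.exp(-truth.ordinate(drug, tro))
            mda = truth.omega_inf + (truth.omega0 - truth.omega_inf) * frac
            cond = {
                f"{drug_name}_{drug_unit}": float(drug),
                "TRO_uM": float(tro),
                "role": "zero" if (drug == 0 and tro == 0) else "sample",
                "true_mda_uM": mda,
            }
            columns.append(_tbars_intensity(model, wl, mda, True, rng))
            conditions.append(cond)

    # fully-inhibited reference: signal collapsed to the omega_inf amplitude
    columns.append(_tbars_intensity(model, wl, truth.omega_inf, True, rng))
    conditions.append({"role": "full", "true_mda_uM": truth.omega_inf})

    if calib_concs is not None:
        for c in calib_concs:
            columns.append(_tbars_intensity(model, wl, c, False, rng))
            conditions.append({"role": "calib", "MDA_uM": float(c)})

    return SpectralMatrix(
        wl,
        np.column_stack(columns),
        conditions,
        AxisKind.wavelength,
        meta={
            "truth_pI50_drug": truth.pI50_drug,
            "truth_pI50_tro": truth.pI50_tro,
            "truth_cross_slope": truth.cross_slope_drug_per_tro,
            "truth_omega0": truth.omega0,
            "truth_omega_inf": truth.omega_inf,
            "drug_name": drug_name,
            "drug_unit": drug_unit,
        },
    )


# ---------------------------------------------------------------------------
# EPR
# ---------------------------------------------------------------------------


class EprKind(str, Enum):
    DPPH = "DPPH"  # quintet from two equivalent nitrogens, a_N = 8.86 G
    GLV = "GLV"    # resolved doublet, 4.75 G


@dataclass
class EprModel:
    """Stick-pattern parameters of a synthetic EPR derivative spectrum."""

    kind: EprKind = EprKind.DPPH
    splitting: float = 8.86      # gauss between adjacent lines
    n_lines: int = 5             # equidistant, equal amplitude
    linewidth: float = 1.0       # Gaussian sigma per line, gauss
    center_offset: float = 0.0   # simulated phase misalignment, gauss
    amplitude: float = 1.0       # per-line derivative amplitude scale
    noise_sd: float = 0.0
    step: float = 0.02           # field grid step, gauss
    span: float | None = None    # half-width of the field window, gauss
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = EprKind(self.kind)
        if self.splitting <= 0 or self.linewidth <= 0:
            raise ValueError("splitting and linewidth must be positive")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")

    @classmethod
    def dpph(cls, **kw) -> "EprModel":
        return cls(kind=EprKind.DPPH, splitting=8.86, n_lines=5, **kw)

    @classmethod
    def glv(cls, **kw) -> "EprModel":
        return cls(kind=EprKind.GLV, splitting=4.75, n_lines=2, **kw)

    def field_grid(self) -> np.ndarray:
        span = self.span
        if span is None:
            span = (
                self.splitting * (self.n_lines - 1) / 2
                + 6 * self.linewidth
                + abs(self.center_offset)
                + 2.0
            )
        return np.arange(-span, span + self.step / 2, self.step)

    def line_centers(self) -> np.ndarray:
        k = np.arange(self.n_lines) - (self.n_lines - 1) / 2
        return self.center_offset + k * self.splitting


def gen_epr_spectrum(model: EprModel, radical_frac: float = 1.0) -> Spectrum:
    """Derivative-of-Gaussian multiplet scaled by the remaining radical fraction.

    The noiseless spectrum is exactly antisymmetric about ``center_offset``:
    s(c + x) = −s(c − x).
    """
    if not 0.0 <= radical_frac <= 1.0:
        raise ValueError("radical_frac must be in [0, 1]")
    rng = np.random.default_rng(model.seed)
    x = model.field_grid()
    y = np.zeros_like(x)
    s2 = model.linewidth**2
    for mu in model.line_centers():
        # derivative of a Gaussian absorption line: positive lobe upfield
        y += -(x - mu) / s2 * _gauss(x, mu, model.linewidth)
    y *= model.amplitude * radical_frac
    if model.noise_sd:
        y = y + rng.normal(0.0, model.noise_sd, x.size)
    return Spectrum(
        x,
        y,
        AxisKind.field_offset,
        {
            "kind": model.kind.value,
            "radical_frac": radical_frac,
            "true_center_G": model.center_offset,
            "true_splitting_G": model.splitting,
        },
    )


def gen_epr_decay_series(
    model: EprModel,
    radical_fracs: Sequence[float],
    seed: int | None = None,
) -> SpectralMatrix:
    """Aligned-grid EPR decay series, one column per radical fraction."""
    base = replace(model, seed=model.seed if seed is None else seed)
    spectra = []
    for i, f in enumerate(radical_fracs):
        spectra.append(gen_epr_spectrum(replace(base, seed=base.seed + i), f))
    mat = SpectralMatrix.from_spectra(spectra)
    mat.meta["true_splitting_G"] = model.splitting
    return mat


# ---------------------------------------------------------------------------
# polarized fluorescence
# ---------------------------------------------------------------------------


def gen_polarized_pair(
    R_true: float,
    total: float = 10000.0,
    G: float = 7.31,
    band: tuple[float, float] = (430.0, 25.0),
    grid: tuple[float, float, float] = (370.0, 560.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Spectrum, Spectrum]:
    """VV/VH Gaussian emission bands whose areas realise an exact anisotropy.

    Given R = (VV − G·VH)/(VV + 2G·VH) and a total area VV + VH, the pair of
    band areas is solved in closed form; the bands share the (center, sigma)
    in nm given by ``band``.  R must lie in the physically meaningful DPH
    range [−0.2, 0.4]; G must be positive.
    """
    if not -0.2 <= R_true <= 0.4:
        raise ValueError("R_true outside the physical DPH range [-0.2, 0.4]")
    if G <= 0 or total <= 0:
        raise ValueError("G and total must be positive")
    ratio = G * (1.0 + 2.0 * R_true) / (1.0 - R_true)  # AUC_VV / AUC_VH
    auc_vh = total / (1.0 + ratio)
    auc_vv = total - auc_vh
    center, sigma = band
    wl = np.arange(grid[0], grid[1] + grid[2] / 2, grid[2])
    rng = np.random.default_rng(seed)
    out = []
    for name, auc in (("VV", auc_vv), ("VH", auc_vh)):
        amp = auc / (sigma * math.sqrt(2.0 * math.pi))
        y = amp * _gauss(wl, center, sigma)
        if noise_sd:
            y = y + rng.normal(0.0, noise_sd, wl.size)
        out.append(
            Spectrum(
                wl,
                y,
                AxisKind.wavelength,
                {"polarization": name, "true_auc": auc, "true_R": R_true, "G": G},
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# DSC
# ---------------------------------------------------------------------------


def gen_thermogram(
    Tm: float,
    dH: float,
    baseline: tuple[float, float] = (0.1, 0.0005),
    width: float = 2.0,
    molar_mass: float = 280.0,
    sample_mass: float = 10.0,
    scan_rate: float = 10.0,
    window: float = 40.0,
    step: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Thermogram:
    """Affine baseline plus a Gaussian endotherm of molar fusion enthalpy dH.

    ``Tm`` (K) is the Gaussian peak *center*; the extrapolated onset — what
    the tangent construction estimates — lies at Tm − 2·width for a Gaussian
    peak and is recorded as ``meta['true_onset_K']``.  ``dH`` is in J mol⁻¹;
    heat flow is emitted in mW for a ``sample_mass`` mg sample of molar mass
    ``molar_mass`` g mol⁻¹ scanned at ``scan_rate`` K min⁻¹, so numerical
    integration of the baseline-subtracted peak recovers dH exactly.
    """
    if dH < 0:
        raise ValueError("dH must be >= 0")
    if width <= 0:
        raise ValueError("width must be positive")
    T = np.arange(Tm - window, Tm + window + step / 2, step)
    if not T[0] < Tm < T[-1]:
        raise ValueError("Tm must lie inside the temperature window")
    moles = sample_mass * 1e-3 / molar_mass
    area_J = dH * moles                       # heat absorbed by the sample
    rate_K_per_s = scan_rate / 60.0
    # peak area in mW·K = (J) * 1000 * (K/s)
    area_mWK = area_J * 1e3 * rate_K_per_s
    amp = area_mWK / (width * math.sqrt(2.0 * math.pi))
    y = baseline[0] + baseline[1] * (T - T[0]) + amp * _gauss(T, Tm, width)
    if noise_sd:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, T.size)
    return Thermogram(
        T,
        y,
        scan_rate=scan_rate,
        meta={
            "endo_up": True,
            "molar_mass_g_mol": molar_mass,
            "sample_mass_mg": sample_mass,
            "true_Tm_center_K": Tm,
            "true_onset_K": Tm - 2.0 * width,
            "true_dH_J_mol": dH,
        },
    )
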