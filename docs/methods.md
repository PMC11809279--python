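# Methods

This note records the models, numerical choices and limitations behind
`membrox`, in the spirit of a package-level methods appendix. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The unmixing model and the ω score

TBARS quantification is confounded by a 455 nm chromogen that co-occurs
with the quantitative 530 nm malondialdehyde adduct only loosely: its
amplitude tracks the 530 nm amplitude on average but fluctuates between
conditions. A titration is therefore decomposed as a matrix
`M = Ψ Σ Λᵀ` (spectra as columns, m sampling points ≥ n conditions, no
centering — the average spectral shape emerges as the first component).
The per-spectrum score

    ω_j = −σ₁ λ₁ⱼ + σ₂ λ₂ⱼ        (optical)
    ω_j = −σ₁ λ₁ⱼ                 (EPR)

is a linear functional of the spectrum: the first term measures overall
amplitude, the second adds the 530-increment/455-decrement differential
shape, cancelling the by-product's wander. Calibration standards are
decomposed as columns of the same matrix so their scores share the basis.

**Sign convention.** An SVD leaves each (ψᵢ, λᵢ) pair defined only up to a
joint sign, and the ω formula presumes an orientation. `decompose` fixes:
ψ₁ non-positive at its largest-magnitude element (so −σ₁λ₁ is a positive
amount for non-negative spectra); ψ₂ non-negative at 530 nm on wavelength
axes (so +σ₂λ₂ adds the 530 nm increment); higher components non-negative
at their peak. This shape-only rule keeps ω odd under sign flips of the
data. For antisymmetric EPR derivative shapes the rule is intrinsically
ill-conditioned (the positive and negative lobes tie in magnitude, and
noise decides the argmax), so `epr.decay_score` additionally orients its
returned scores to a positive-amount scale (all scores flipped if the
largest-magnitude one is negative). Cumulative variance is defined on σ²
(energy), the standard convention.

**Dimensionality.** `choose_dimensionality` takes the smallest d whose
cumulative σ² reaches a threshold (default 0.85); the complementary
`sigma_cutoff_dimensionality` drops components whose singular value falls
several hundred times (default 300×) below σ₁. Note that when the 455 nm
amplitude is tightly coupled to the 530 nm one — as the synthetic generator
produces by design — the second component carries very little energy and
the variance criterion selects d = 1; a second component is demanded only
by genuinely independent 455/530 variation. ω in optical mode always uses
two components regardless, which is harmless when σ₂ ≈ 0.

## Dose–response and competition

The inhibition ordinate `y = −ln[(ω − ω_∞)/(ω₀ − ω_∞)]` is 0 with no
inhibitor and ln 2 at half-maximal inhibition. ω₀ and ω_∞ are the mean
scores of the designated zero-inhibitor and full-inhibition columns.
Scores at or below ω_∞ (possible under noise) are *censored* from the
regression rather than clipped: −ln of a non-positive number is undefined,
and clipping would bias the slope.

The ordinate is fit by ordinary least squares with an intercept (the
two-agent design produces a nonzero intercept from the co-inhibitor's
additive contribution); a through-origin flag covers single-agent designs.
`IC₅₀ = ln 2 / slope` by default — the potency is converted from the
obtained slope, which is exactly what isolates the drug's own contribution
when a second agent shifts the intercept; the alternative reading
`IC₅₀ = (ln 2 − intercept)/slope` (where the fitted line crosses ln 2) is
available as `ic50_from="crossing"`. `pI₅₀ = −log₁₀(IC₅₀/1 mol L⁻¹)` is
unit-invariant; concentration units travel explicitly (`mM`, `uM`, ...)
and are never guessed. Upward-convex curves are still summarised by the
linear gradient, with a curvature warning (quadratic term improving the
residual sum of squares by >20 % with a negative coefficient).

Competition is the OLS slope of pI₅₀ against the modifier concentration
over ≥3 modifier levels; its intercept estimates the single-agent pI₅₀.

## Synthetic data: what it emulates, and what "noiseless" means

All generators are deterministic given (parameters, seed) and use Gaussian
(optical, DSC) or Gaussian-derivative (EPR) line shapes — the instruments'
true shapes are not on record, and Gaussians make areas, inflection points
and antisymmetry analytically controllable.

* **TBARS** (400–700 nm, 1 nm): 530 nm peak strictly proportional to the
  MDA-equivalent concentration at 0.05 AU/μM (≈1 AU at the 20 μM top
  standard); standard-MDA shape adds a 495 nm shoulder; lipid samples add
  the 455 nm by-product with `A₄₅₅ = coupling·A₅₃₀·(1+ε)`,
  ε ~ N(0, 0.2²), the knob that exercises the unmixing; additive
  absorbance noise 0.003 AU (a realistic UV–vis baseline; the study
  conditions do not state one).
* **Titrations**: inhibition ordinates add across agents,
  `y = y_drug + y_TRO`, with the drug's pI₅₀ attenuated linearly in the
  scavenger concentration — the same model the analysis assumes, so
  recovery tests are well-posed. The truth parameters `omega0`/`omega_inf`
  live on the MDA-equivalent amplitude scale (defaults 20/0 μM), because ω
  itself is only defined up to the SVD scaling. Default grids follow the
  assay design: six drug levels (0–0.40 mM for the imipramine-like
  default) × six Trolox levels (0–25 μM), plus a full-inhibition reference
  column and a six-point standard series.
* **EPR**: equidistant equal-amplitude derivative-of-Gaussian lines
  (quintet at 8.86 G; doublet at 4.75 G — the galvinoxyl "doublet of
  quintets" fine structure is deliberately modelled as the resolved
  doublet actually observed at low resolution), linewidth σ = 1.0 G, grid
  step 0.02 G, scaled by the remaining radical fraction; exactly
  antisymmetric about the configurable phase offset when noise is off.
* **Fluorescence**: VV/VH Gaussian bands at 430/25 nm (any fixed band
  works — R depends only on area ratios) whose areas satisfy the
  anisotropy relation exactly for the prescribed (R, G).
* **DSC**: affine baseline plus a Gaussian endotherm whose molar area is
  the prescribed ΔH (mW heat flow, 10 mg sample, 10 K/min); the `Tm`
  parameter is the peak *center*, and the extrapolated onset that the
  tangent construction estimates lies at `Tm − 2·width` for a Gaussian
  (recorded as `true_onset_K`).

"Noiseless" in the recovery tests means `noise_sd = 0` **and**
`coupling_jitter = 0`: the 455-coupling jitter is itself a noise source,
and with it on the ω purification is only approximate by construction.
Recovery under those conditions is exact up to numerics (pI₅₀ within
±0.05 across 2.5–5.3; DSC onset within 0.5 K and ΔH within 2 %); at
realistic noise the package is validated on weaker, sign/frequency-level
claims (competition-slope sign in ≥95 % of 20 seeds). What passing these
tests shows is that the *analysis chain* is faithful to its own model;
real instrument data add shape mismatch, drift and correlated noise that
the generators do not emulate.

## EPR numerical choices

The symmetry centre minimises the mean of `[s(c+u) + s(c−u)]²` over the
two-sided overlap (201-point resampling), after mean removal so constant
baseline offsets do not bias the search; candidates are grid points within
±25 % of the sweep width around the midpoint, refined by a parabola
through the discrete minimum. The absorption curve is the cumulative
trapezoid with the endpoint chord subtracted (both ends anchored ≈0).
Peaks are selected by prominence ≥5 % of the global maximum (suppressing
noise peaks without masking the known multiplets) and refined by a
three-point parabola; couplings are successive peak intervals.
Single-point intensity readings (e.g. at −2.5 G on the DPPH quintet) are
exposed as a parameterised query (`intensity_at_offset`) rather than a
hard-coded offset.

## DSC numerical choices

The baseline is a flank line refit iteratively after excluding the region
departing by >3× the flank residual SD; the peak window runs from
departure to return. The onset is the intersection of the baseline with
the tangent at the left-flank inflection (maximum gradient of the
corrected signal), which makes it invariant to baseline slope and offset.
Endothermic peaks are positive-up internally; the input convention is
declared in `meta['endo_up']`. A pure baseline is an error for the onset
(no melting event) but yields 0 for the enthalpy (zero-area peak). The
wording "fusion enthalpy divided by T_m" describes the *entropy*; the
package implements Clausius' `ΔS = ΔH/T_m` and reports the excess over
Walden's constant without asserting its biological interpretation.

## Anisotropy and LFER choices

Band areas use k = 2 Gaussian components by default (DPH vibronic
structure; "multicomponent" is otherwise unspecified), initialised at the
most prominent local maxima, after subtracting a linear baseline fit over
the lowest-intensity 10 % of points; a failed fit falls back to the
trapezoidal area with a warning. R values above the physical DPH limit of
0.4 are warned about, not rejected. The cholesterol control row of the
packaged anisotropy table is flagged: its printed R (0.024) is not
reproducible from its printed areas (≈0.029), and it is excluded from
correlation work by default. Correlations use the *printed* anisotropy
values rather than recomputed ones by default, toggleable by passing a
different column.

With n = 6 drugs, multi-predictor QSAR is fragile: `multiple_regression`
always reports n, refuses p ≥ n − 1, and rejects collinear designs
(condition number > 10⁸ on standardised predictors) naming the most
correlated pair. No stepwise selection or regularisation is provided.

## Known limitations

* The unit basis of published competition-slope columns ("×10⁻³" per μM)
  is not fully self-consistent across sources of the same quantities; the
  package stores slopes on the natural scale with explicit units and does
  not resolve the discrepancy.
* Vendor instrument formats (JCAMP-DX, Bruker binary) are not parsed;
  I/O is plain CSV with `key=value` condition headers.
* No spin-Hamiltonian simulation, g-factor work, MCR-ALS/varimax
  unmixing, 4PL/Hill fitting, multi-peak DSC deconvolution or
  time-resolved anisotropy: the scope is the assay chain above.
* At realistic noise the competition-slope *magnitude* is recovered with
  a visible bias (the worked example prints −42×10⁻³ against a −48×10⁻³
  truth): slope-based pI₅₀ estimates at high scavenger levels divide by
  small, jitter-affected gradients. Sign and ordering are robust; treat
  magnitudes at high modifier levels with care.
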