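"""SVD spectral unmixing and the purified ω score.

An m x n matrix M of observed spectra (columns are conditions, rows are
sampling points, m >= n) is factored as M = Ψ Σ Λᵀ.  The first left singular
vector ψ₁ captures the shared (average) spectral shape and the second the
dominant differential shape — for TBARS titrations, the incremental 530 nm
signal against the decremental 455 nm by-product signal.  A per-spectrum
score

    optical:  ω_j = −σ₁λ₁ⱼ + σ₂λ₂ⱼ
    epr:      ω_j = −σ₁λ₁ⱼ

then serves as a purified signal amount: the first term is the (positive)
overall amplitude, and for optical spectra the second term cancels the
non-quantitative co-occurrence of the 455 nm by-product.

The raw SVD leaves each (ψᵢ, λᵢ) pair determined only up to a joint sign.
The score formula presumes a fixed orientation, applied here as:

* ψ₁ is non-positive at its largest-magnitude element, making −σ₁λ₁ⱼ a
  positive amount for non-negative spectra;
* ψ₂ is non-negative at 530 nm for wavelength axes (at its largest-magnitude
  element otherwise), so +σ₂λ₂ⱼ adds the 530 nm increment;
* every further component is oriented non-negative at its largest-magnitude
  element (an arbitrary but deterministic convention).

Spectra are decomposed raw (no centering): the average behaviour emerges
naturally as the first component.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Any

import numpy as np

from .io import AxisKind, SpectralMatrix

__all__ = [
    "SVDResult",
    "OmegaScores",
    "ScoreMode",
    "decompose",
    "choose_dimensionality",
    "sigma_cutoff_dimensionality",
    "omega_scores",
    "reconstruct",
]

_REFERENCE_WAVELENGTH_NM = 530.0


class ScoreMode(str, Enum):
    optical = "optical"
    epr = "epr"


@dataclass
class SVDResult:
    """Truncated SVD of a spectral matrix, with the analysis sign convention.

    ``basis`` holds the retained basis functions ψᵢ as columns (m x d);
    ``coefficients`` the singular vectors λᵢ per spectrum (n x d);
    ``cumulative_variance`` is on σ² (energy) over *all* n components, so its
    last entry is 1 at full rank.  ``rank`` is the numerical matrix rank,
    recorded for reference but not used for truncation.
    """

    basis: np.ndarray
    singular_values: np.ndarray
    coefficients: np.ndarray
    cumulative_variance: np.ndarray
    d: int
    rank: int
    wavelengths: np.ndarray
    conditions: list[dict[str, Any]]
    axis_kind: AxisKind = AxisKind.wavelength

    @property
    def n(self) -> int:
        return self.coefficients.shape[0]


@dataclass
class OmegaScores:
    """Purified per-spectrum amount scores, ordered as the input columns."""

    omega: np.ndarray
    mode: ScoreMode
    conditions: list[dict[str, Any]] = field(default_factory=list)

    def __len__(self) -> int:
        return self.omega.size


def decompose(matrix: SpectralMatrix, d: int | None = None) -> SVDResult:
    """Singular-value decomposition of a spectral matrix.

    Parameters
    ----------
    matrix
        m x n spectra-as-columns matrix with m >= n and no missing values.
    d
        Retained dimensionality.  ``None`` keeps all n components (σ = 0
        components included, so full-rank reconstruction is exact).

    Raises
    ------
    ValueError
        If m < n (transpose or regrid the input so spectra are columns and
        sampling points rows) or the matrix is all zero / non-finite.
    """
    M = matrix.intensities
    m, n = M.shape
    if m < n:
        raise ValueError(
            f"matrix is {m} x {n} but SVD unmixing requires m >= n; "
            "transpose or regrid so spectra are columns over a finer abscissa"
        )
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains missing or non-finite values")
    if not np.any(M):
        raise ValueError("matrix is identically zero")

    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    V = Vt.T  # n x n, columns are singular vectors λᵢ

    # orientation convention (see module docstring)
    for i in range(n):
        col = U[:, i]
        peak = int(np.argmax(np.abs(col)))
        if i == 0:
            flip = col[peak] > 0
        elif i == 1:
            if matrix.axis_kind == AxisKind.wavelength and (
                matrix.wavelengths.min()
                <= _REFERENCE_WAVELENGTH_NM
                <= matrix.wavelengths.max()
            ):
                ref = int(
                    np.argmin(np.abs(matrix.wavelengths - _REFERENCE_WAVELENGTH_NM))
                )
                flip = col[ref] < 0
            else:
                flip = col[peak] < 0
        else:
            flip = col[peak] < 0
        if flip:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]

    total = float(np.sum(s**2))
    cumvar = np.cumsum(s**2) / total
    rank = int(np.linalg.matrix_rank(M))

    if d is None:
        d = n
    if not 1 <= d <= n:
        raise ValueError(f"d must be in [1, {n}], got {d}")

    return SVDResult(
        basis=U[:, :d],
        singular_values=s[:d],
        coefficients=V[:, :d],
        cumulative_variance=cumvar,
        d=d,
        rank=rank,
        wavelengths=matrix.wavelengths,
        conditions=[dict(c) for c in matrix.conditions],
        axis_kind=matrix.axis_kind,
    )


def choose_dimensionality(result: SVDResult, threshold: float = 0.9) -> int:
    """Smallest d whose cumulative σ² variance reaches *threshold*.

    ``threshold`` must lie in (0, 1]; 1.0 returns the numerical rank.  This is
    the variance criterion; see :func:`sigma_cutoff_dimensionality` for the
    complementary rule that drops components whose singular value falls
    several hundred times below σ₁.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if threshold == 1.0:
        return result.rank
    return int(np.searchsorted(result.cumulative_variance, threshold) + 1)


def sigma_cutoff_dimensionality(result: SVDResult, ratio: float = 300.0) -> int:
    """Number of components with σᵢ >= σ₁ / *ratio*.

    Components whose singular value is several hundred times smaller than the
    leading one carry no reproducible spectral information and are dropped.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    s = result.singular_values
    return int(np.count_nonzero(s >= s[0] / ratio)) or 1


def omega_scores(result: SVDResult, mode: ScoreMode | str = ScoreMode.optical) -> OmegaScores:
    """Per-spectrum purified amount score ω.

    ``optical`` mode needs d >= 2 (ω = −σ₁λ₁ + σ₂λ₂); ``epr`` mode needs
    d >= 1 (ω = −σ₁λ₁ — one component suffices for derivative multiplets
    that only scale with radical amount).
    """
    mode = ScoreMode(mode)
    need = 2 if mode == ScoreMode.optical else 1
    if result.d < need:
        raise ValueError(f"{mode.value} mode needs d >= {need}, result has d={result.d}")
    s, V = result.singular_values, result.coefficients
    omega = -s[0] * V[:, 0]
    if mode == ScoreMode.optical:
        omega = omega + s[1] * V[:, 1]
    return OmegaScores(omega=omega, mode=mode, conditions=[dict(c) for c in result.conditions])


def reconstruct(result: SVDResult, d: int) -> SpectralMatrix:
    """Rank-d reconstruction x⃗ⱼ = Σ_{i<=d} ψᵢ σᵢ λᵢⱼ of the input matrix."""
    if not 1 <= d <= result.d:
        raise ValueError(f"d must be in [1, {result.d}], got {d}")
    X = result.basis[:, :d] @ np.diag(result.singular_values[:d]) @ result.coefficients[:, :d].T
    return SpectralMatrix(
        result.wavelengths,
        X,
        [dict(c) for c in result.conditions],
        result.axis_kind,
        {"reconstruction_rank": d},
    )
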