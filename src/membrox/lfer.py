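"""Linear free-energy relationship (LFER / QSAR) regressions over drug descriptors.

Simple determination coefficients (squared Pearson correlations) and ordinary
least-squares multiple regressions relate physicochemical descriptors of the
study drugs — partition coefficient log P, fusion entropy Δ_fus S⁰,
Yalkowski's flexibility log f, relative polar surface area, refractivity and
polarizability κ — to measured responses such as the cross-competition slope
dpI₅₀ᴰʳᵘᵍ/d[TRO] or the DPH fluorescence anisotropy R.

With only six drugs, multi-predictor fits are fragile: reports always carry
n, and a fit with p >= n − 1 predictors is refused rather than over-fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["RegressionReport", "pearson_r2", "multiple_regression", "build_descriptor_join"]

_COLLINEARITY_COND_MAX = 1e8


@dataclass
class RegressionReport:
    """An OLS fit: named coefficients, standard errors, r² and sample size."""

    response: str
    predictors: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    r2: float
    n: int

    def summary(self) -> str:
        lines = [f"OLS: {self.response} ~ {' + '.join(self.predictors)}  (n={self.n})"]
        for name in self.coefficients.index:
            lines.append(
                f"  {name:>12s} = {self.coefficients[name]: .4g}"
                f"  (se {self.std_errors[name]:.3g})"
            )
        lines.append(f"  r2 = {self.r2:.3f}")
        return "\n".join(lines)


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation (determination coefficient) of two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(stats.pearsonr(x, y).statistic ** 2)


def multiple_regression(y: pd.Series, X: pd.DataFrame) -> RegressionReport:
    """OLS with intercept over named predictors; refuses under-determined fits.

    Requires n > p + 1.  Collinear predictor sets (design condition number
    above 1e8 on standardized columns) are rejected with the most correlated
    pair named.
    """
    y = pd.Series(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    n, p = X.shape
    if y.size != n:
        raise ValueError("response and predictors disagree in length")
    if n <= p + 1:
        raise ValueError(f"under-determined: n={n} <= p+1={p + 1}; drop predictors")
    Z = (X - X.mean()) / X.std(ddof=0).replace(0, np.nan)
    if Z.isna().any().any() or (p > 1 and np.linalg.cond(Z.to_numpy()) > _COLLINEARITY_COND_MAX):
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            f"collinear predictors: {corr.index[i]!r} and {corr.columns[j]!r}"
        )
    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    return RegressionReport(
        response=str(y.name or "response"),
        predictors=list(X.columns),
        coefficients=fit.params,
        std_errors=fit.bse,
        r2=float(fit.rsquared),
        n=n,
    )


def build_descriptor_join(left: pd.DataFrame, *others: pd.DataFrame) -> pd.DataFrame:
    """Outer-join per-drug tables on their drug index, tracking provenance.

    Each input frame may carry ``attrs['provenance']`` (column -> source
    label); the joined frame merges them, labelling unattributed columns by
    the frame's ``attrs.get('name')``.  Duplicate drug keys or column names
    colliding across frames are errors.  Missing cells stay NaN (flagged,
    not imputed).
    """
    frames = (left, *others)
    provenance: dict[str, str] = {}
    for k, frame in enumerate(frames):
        if frame.index.duplicated().any():
            raise ValueError("duplicate drug keys in a descriptor table")
        src = frame.attrs.get("name", f"table{k}")
        for col in frame.columns:
            provenance[col] = frame.attrs.get("provenance", {}).get(col, src)
    out = frames[0]
    for frame in frames[1:]:
        overlap = out.columns.intersection(frame.columns)
        if len(overlap):
            raise ValueError(f"column collision on join: {list(overlap)}")
        out = out.join(frame, how="outer")
    out.attrs["provenance"] = provenance
    return out
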