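"""High-level analysis chains combining unmixing and dose-response scoring.

`analyze_titration` runs the standard TBARS chain on a spectra-as-columns
titration matrix: SVD decomposition, optical ω scores, asymptote estimation
from the designated zero/full columns, a per-scavenger-level linear
inhibition fit, and (when three or more scavenger levels carry a defined
pI₅₀) the cross-competition slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dose, svd
from .io import SpectralMatrix

__all__ = ["TitrationAnalysis", "analyze_titration"]


@dataclass
class TitrationAnalysis:
    """Results of the standard TBARS titration chain."""

    omega0: float
    omega_inf: float
    fits: dict[float, dose.DoseResponseFit] = field(default_factory=dict)
    competition: dose.CompetitionResult | None = None
    svd_result: svd.SVDResult | None = None

    @property
    def pI50_at_zero_modifier(self) -> float:
        return self.fits[0.0].pI50 if 0.0 in self.fits else float("nan")


def analyze_titration(
    matrix: SpectralMatrix,
    drug_key: str | None = None,
    modifier_key: str = "TRO_uM",
    unit: str | None = None,
    through_origin: bool = False,
) -> TitrationAnalysis:
    """Full ω-score dose–response analysis of a titration matrix.

    ``drug_key`` (e.g. ``"IMP_mM"``) and ``unit`` default to the matrix
    metadata written by the synthetic generator.  Columns are grouped by the
    modifier concentration; each group must contain >= 3 usable points.
    """
    if drug_key is None:
        name, unit_ = matrix.meta.get("drug_name"), matrix.meta.get("drug_unit")
        if not name or not unit_:
            raise ValueError("drug_key not given and matrix carries no drug metadata")
        drug_key = f"{name}_{unit_}"
    if unit is None:
        unit = drug_key.rsplit("_", 1)[-1]

    result = svd.decompose(matrix)
    scores = svd.omega_scores(result, svd.ScoreMode.optical)
    omega0, omega_inf = dose.estimate_asymptotes(scores)

    levels = sorted(
        {
            c[modifier_key]
            for c in scores.conditions
            if modifier_key in c and c.get("role") in ("sample", "zero")
        }
    )
    fits: dict[float, dose.DoseResponseFit] = {}
    for level in levels:
        idx = [
            j
            for j, c in enumerate(scores.conditions)
            if c.get(modifier_key) == level and c.get("role") in ("sample", "zero")
        ]
        concs = np.array([scores.conditions[j][drug_key] for j in idx])
        ordinate = dose.inhibition_ordinate(scores.omega[idx], omega0, omega_inf)
        fits[float(level)] = dose.fit_inhibition(
            concs, ordinate, unit=unit, through_origin=through_origin
        )

    competition = None
    if sum(1 for f in fits.values() if f.defined) >= 3:
        competition = dose.competition_slopes(fits)

    return TitrationAnalysis(
        omega0=omega0,
        omega_inf=omega_inf,
        fits=fits,
        competition=competition,
        svd_result=result,
    )
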