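"""Published reference measurements for the six study drugs.

Three small tables accompany the package so the LFER/QSAR stage and the
anisotropy worked examples run without external files:

* :func:`inhibition_summary` — TBARS pI₅₀ values of each drug and of Trolox,
  and the cross-competition slopes dpI₅₀ᴰʳᵘᵍ/d[TRO] and dpI₅₀ᵀᴿᴼ/d[Drug]
  (slope columns are in units of 10⁻³ pI₅₀ per μM as published; stored here
  on the natural scale, pI₅₀ per μM).
* :func:`anisotropy_summary` — DPH emission band areas AUC_VV / AUC_VH and
  the derived anisotropy R for drug-doped DPPC liposomes, measured with
  instrumental factor G = 7.31.
* :func:`drug_descriptors` — physicochemical descriptors: log P, fusion
  entropy Δ_fus S⁰ (J K⁻¹ mol⁻¹), Yalkowski's log f, PSA/MW (Å²),
  refractivity (m³ mol⁻¹) and polarizability κ (Å³).

Drugs: lidocaine (LDC), dibucaine (DBC), imipramine (IMP), amitriptyline
(AMT), desipramine (DSP), olanzapine (OLZ).  The cholesterol (CHO) control
row of the anisotropy table is retained but flagged: its printed R is not
reproducible from its printed AUCs (the recomputed value is ≈ 0.029, the
printed one 0.024) and it is excluded from correlation work by default.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "G_FACTOR",
    "DRUGS",
    "inhibition_summary",
    "anisotropy_summary",
    "drug_descriptors",
    "reference_join",
]

#: instrumental polarization factor of the fluorimeter, AUC_HV / AUC_HH
G_FACTOR = 7.31

DRUGS = ["LDC", "DBC", "IMP", "AMT", "DSP", "OLZ"]


def inhibition_summary() -> pd.DataFrame:
    """TBARS pI₅₀ values and cross-competition slopes per drug."""
    df = pd.DataFrame(
        {
            "tbars_pI50_drug": [2.5, 2.8, 3.7, 3.3, 2.7, 5.3],
            "slope_dpI50drug_dTRO": [-19e-3, -21e-3, -48e-3, -72e-3, -150e-3, -48e-3],
            "tbars_pI50_tro": [4.1, 4.2, 3.7, 4.2, 4.0, 3.4],
            "slope_dpI50tro_dDrug": [-0.21e-3, -0.42e-3, -2.8e-3, -0.90e-3, -1.9e-3, -160e-3],
            "dpph_pI50_tro": [4.0, 4.0, 4.0, 4.0, 3.9, 4.0],
            "glv_pI50_tro": [4.2, 4.2, 4.2, 4.3, 4.3, 4.3],
        },
        index=pd.Index(DRUGS, name="drug"),
    )
    df.attrs["name"] = "inhibition_summary"
    df.attrs["provenance"] = {c: "inhibition_summary" for c in df.columns}
    return df


def anisotropy_summary(include_controls: bool = False) -> pd.DataFrame:
    """DPH band areas and anisotropy per drug (G = 7.31).

    ``include_controls`` adds the drug-free liposome (SUV) and cholesterol
    (CHO) rows; the CHO row's printed R is inconsistent with its printed
    AUCs and is marked ``flagged``.
    """
    rows = {
        "SUV": (6333, 357, 0.32, False),
        "CHO": (14710, 1848, 0.024, True),
        "LDC": (1054, 69, 0.26, False),
        "DBC": (5004, 507, 0.10, False),
        "IMP": (5361, 496, 0.13, False),
        "AMT": (6189, 452, 0.22, False),
        "DSP": (6310, 432, 0.24, False),
        "OLZ": (14180, 1403, 0.11, False),
    }
    keys = list(rows) if include_controls else DRUGS
    df = pd.DataFrame(
        [rows[k] for k in keys],
        index=pd.Index(keys, name="drug"),
        columns=["auc_vv", "auc_vh", "R", "flagged"],
    )
    df.attrs["name"] = "anisotropy_summary"
    df.attrs["provenance"] = {c: "anisotropy_summary" for c in df.columns}
    return df


def drug_descriptors() -> pd.DataFrame:
    """Physicochemical descriptors of the six drugs."""
    df = pd.DataFrame(
        {
            "logP": [2.26, 4.40, 4.80, 4.92, 4.90, 4.094],
            "dfusS": [44.2, 59.1, 46.7, 31.7, 17.6, 48.5],
            "logf": [2.047, 3.866, 1.592, 1.137, 1.592, 0.0],
            "psa_mw": [0.1382, 0.1586, 0.02311, 0.01168, 0.05732, 0.09880],
            "refractivity": [73.93, 102.12, 90.61, 101.51, 85.31, 93.87],
            "polarizability": [27.77, 40.78, 33.39, 33.34, 31.74, 35.35],
        },
        index=pd.Index(DRUGS, name="drug"),
    )
    df.attrs["name"] = "drug_descriptors"
    df.attrs["provenance"] = {c: "drug_descriptors" for c in df.columns}
    return df


def reference_join() -> pd.DataFrame:
    """All three reference tables joined per drug (CHO/SUV controls excluded)."""
    from .lfer import build_descriptor_join

    return build_descriptor_join(
        drug_descriptors(), inhibition_summary(), anisotropy_summary()
    )
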