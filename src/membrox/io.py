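"""Containers and delimited-text I/O for spectra, thermograms and descriptor tables.

The analysis chain operates on three kinds of traces: optical spectra
(absorbance or fluorescence vs. wavelength in nm), EPR derivative spectra
(signal vs. magnetic-field offset in gauss), and DSC thermograms (heat flow
vs. temperature in kelvin).  All of them travel as plain CSV: first column is
the abscissa, remaining columns are intensities, and the header row carries
per-column experimental conditions serialized as ``key=value`` pairs joined
with ``;`` (e.g. ``TRO_uM=50;IMP_mM=0.08;role=sample``).

Units are carried in the metadata *keys* (``TRO_uM``, ``IMP_mM``) and are
never guessed from magnitudes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AxisKind",
    "Spectrum",
    "SpectralMatrix",
    "Thermogram",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_descriptor_table",
    "write_descriptor_table",
]


class AxisKind(str, Enum):
    """What the abscissa of a spectrum physically is."""

    wavelength = "wavelength"      # nm, optical
    field_offset = "field_offset"  # gauss, EPR
    temperature = "temperature"    # kelvin, DSC

    @property
    def column_name(self) -> str:
        return {
            AxisKind.wavelength: "wavelength_nm",
            AxisKind.field_offset: "field_G",
            AxisKind.temperature: "temperature_K",
        }[self]


# Recognised unit suffixes for compact condition labels like "TRO=50uM".
_UNIT_SUFFIXES = ("uM", "mM", "nM", "M", "G", "K", "nm", "mg")
_COMPACT_RE = re.compile(
    r"^([+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)(%s)$" % "|".join(_UNIT_SUFFIXES)
)


def parse_condition_label(label: str) -> dict[str, Any]:
    """Parse a column-header condition label into a metadata dict.

    Two equivalent spellings are accepted for numeric entries with units:
    ``TRO_uM=50`` (unit in the key) and ``TRO=50uM`` (unit suffixed to the
    value); both yield ``{"TRO_uM": 50.0}``.  Non-numeric values are kept as
    strings (``role=zero``).  A token that is not ``key=value`` at all is
    preserved under the key ``"label"`` with a warning.
    """
    meta: dict[str, Any] = {}
    for token in str(label).split(";"):
        token = token.strip()
        if not token:
            continue
        if "=" not in token:
            warnings.warn(
                f"condition label {token!r} is not key=value; kept opaque",
                stacklevel=2,
            )
            meta["label"] = token
            continue
        key, value = token.split("=", 1)
        key, value = key.strip(), value.strip()
        m = _COMPACT_RE.match(value)
        if m:
            meta[f"{key}_{m.group(2)}"] = float(m.group(1))
            continue
        try:
            meta[key] = float(value)
        except ValueError:
            meta[key] = value
    return meta


def format_condition_label(meta: Mapping[str, Any]) -> str:
    """Inverse of :func:`parse_condition_label` (canonical ``key=value`` form)."""
    parts = []
    for key, value in meta.items():
        if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
            value = int(value)
        parts.append(f"{key}={value}")
    return ";".join(parts)


def _check_axis(abscissa: np.ndarray, what: str = "abscissa") -> np.ndarray:
    abscissa = np.asarray(abscissa, dtype=float)
    if abscissa.ndim != 1 or abscissa.size < 1:
        raise ValueError(f"{what} must be a 1-D vector")
    d = np.diff(abscissa)
    if abscissa.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{what} must be strictly monotonic")
    return abscissa


@dataclass
class Spectrum:
    """A single trace: ordered abscissa plus one intensity vector.

    ``meta`` carries the experimental condition (drug name and concentration,
    scavenger concentration, radical fraction, role in the design...).
    """

    abscissa: np.ndarray
    intensity: np.ndarray
    axis_kind: AxisKind = AxisKind.wavelength
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = _check_axis(self.abscissa)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.abscissa.shape:
            raise ValueError("abscissa and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        self.axis_kind = AxisKind(self.axis_kind)

    def __len__(self) -> int:
        return self.abscissa.size


@dataclass
class SpectralMatrix:
    """n spectra sharing one abscissa, stored as the columns of an m x n matrix.

    This is the object singular-value decomposition operates on; SVD requires
    m >= n (more sampling points than conditions), which is validated by the
    decomposition, not here, so that partially-built matrices remain usable.
    """

    wavelengths: np.ndarray            # shared abscissa, length m
    intensities: np.ndarray            # m x n, one condition per column
    conditions: list[dict[str, Any]]   # length n
    axis_kind: AxisKind = AxisKind.wavelength
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = _check_axis(self.wavelengths)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (m x n)")
        if self.intensities.shape[0] != self.wavelengths.size:
            raise ValueError("row count must match abscissa length")
        if len(self.conditions) != self.intensities.shape[1]:
            raise ValueError("need one condition record per column")
        self.axis_kind = AxisKind(self.axis_kind)

    @property
    def m(self) -> int:
        return self.intensities.shape[0]

    @property
    def n(self) -> int:
        return self.intensities.shape[1]

    def column(self, j: int) -> Spectrum:
        return Spectrum(
            self.wavelengths,
            self.intensities[:, j],
            self.axis_kind,
            dict(self.conditions[j]),
        )

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum]) -> "SpectralMatrix":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("need at least one spectrum")
        ref = spectra[0]
        for s in spectra[1:]:
            if s.axis_kind != ref.axis_kind or not np.array_equal(
                s.abscissa, ref.abscissa
            ):
                raise ValueError("all spectra must share the abscissa exactly")
        return cls(
            ref.abscissa,
            np.column_stack([s.intensity for s in spectra]),
            [dict(s.meta) for s in spectra],
            ref.axis_kind,
        )

    def select(self, predicate) -> "SpectralMatrix":
        """Sub-matrix of the columns whose condition dict satisfies *predicate*."""
        idx = [j for j, c in enumerate(self.conditions) if predicate(c)]
        if not idx:
            raise ValueError("no column matches the predicate")
        return SpectralMatrix(
            self.wavelengths,
            self.intensities[:, idx],
            [dict(self.conditions[j]) for j in idx],
            self.axis_kind,
            dict(self.meta),
        )


@dataclass
class Thermogram:
    """A DSC trace: temperature (K, strictly increasing) vs heat flow (mW).

    ``meta['endo_up']`` declares the sign convention (endothermic peaks point
    up when True, the internal convention); analysis flips the trace when it
    is False.  ``scan_rate`` is in K/min.
    """

    temperature: np.ndarray
    heat_flow: np.ndarray
    scan_rate: float = 10.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        self.heat_flow = np.asarray(self.heat_flow, dtype=float)
        if self.heat_flow.shape != self.temperature.shape:
            raise ValueError("temperature and heat_flow must have equal length")
        if self.scan_rate <= 0:
            raise ValueError("scan_rate must be positive")
        self.meta.setdefault("endo_up", True)

    @property
    def endo_up_signal(self) -> np.ndarray:
        return self.heat_flow if self.meta.get("endo_up", True) else -self.heat_flow


# ---------------------------------------------------------------------------
# delimited-text round trip
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.10g"


def read_spectrum_table(
    path: str | Path, axis_kind: AxisKind | str = AxisKind.wavelength
) -> SpectralMatrix:
    """Read a CSV spectral table (abscissa column + one column per condition).

    Header labels are parsed as ``key=value`` condition records; malformed
    labels are preserved as opaque strings with a warning.  A non-monotonic
    abscissa or ragged row is a hard error.
    """
    path = Path(path)
    axis_kind = AxisKind(axis_kind)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        labels = header.split(",")[1:]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(",")
            if len(cells) != len(labels) + 1:
                raise ValueError(
                    f"{path}: line {lineno} has {len(cells)} cells, "
                    f"expected {len(labels) + 1}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    data = np.asarray(rows, dtype=float)
    if data.size == 0:
        raise ValueError(f"{path}: no data rows")
    abscissa = _check_axis(data[:, 0], f"{path}: abscissa")
    conditions = [parse_condition_label(lbl) for lbl in labels]
    return SpectralMatrix(abscissa, data[:, 1:], conditions, axis_kind)


def write_spectrum_table(matrix: SpectralMatrix, path: str | Path) -> None:
    """Write a :class:`SpectralMatrix` as CSV, losslessly re-readable."""
    path = Path(path)
    labels = [format_condition_label(c) or f"col{j}" for j, c in enumerate(matrix.conditions)]
    with open(path, "w") as fh:
        fh.write(",".join([matrix.axis_kind.column_name] + labels) + "\n")
        for i in range(matrix.m):
            cells = [_FLOAT_FMT % matrix.wavelengths[i]] + [
                _FLOAT_FMT % v for v in matrix.intensities[i]
            ]
            fh.write(",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# descriptor tables
# ---------------------------------------------------------------------------


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    """Read a per-drug descriptor CSV (``drug`` key column -> index).

    A leading ``# provenance:`` comment line, if present, is restored into
    ``df.attrs['provenance']``.
    """
    path = Path(path)
    provenance: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# provenance:"):
            for tok in first[len("# provenance:"):].strip().split(";"):
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    provenance[k.strip()] = v.strip()
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if "drug" not in df.columns:
        raise ValueError(f"{path}: descriptor table needs a 'drug' column")
    if df["drug"].duplicated().any():
        dupes = df["drug"][df["drug"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate drug keys {dupes}")
    df = df.set_index("drug")
    df.attrs["provenance"] = provenance
    return df


def write_descriptor_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a descriptor table; column provenance survives the round trip."""
    path = Path(path)
    provenance = df.attrs.get("provenance", {})
    with open(path, "w") as fh:
        if provenance:
            line = ";".join(f"{k}={v}" for k, v in provenance.items())
            fh.write(f"# provenance: {line}\n")
        df.reset_index().rename(columns={df.index.name or "index": "drug"}).to_csv(
            fh, index=False
        )
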