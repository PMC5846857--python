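"""Reading, validating and describing binary and quantitative metabolite tables.

Tables are rectangular with a header row of metabolite labels and a first
column of sample labels.  The canonical in-memory orientation is samples in
rows, metabolites in columns; files stored the other way round are accepted
via ``orientation="samples_in_columns"`` and transposed on read.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryFingerprintMatrix",
    "QuantitativeMatrix",
    "DatasetDescriptor",
    "read_binary_matrix",
    "read_quantitative_matrix",
    "write_matrix",
    "binarize",
    "dataset_registry",
]

_DIALECTS = {"csv": ",", "tsv": "\t", "sheet": None}
_ORIENTATIONS = ("samples_in_rows", "samples_in_columns")


def _check_labels(labels: Sequence[str], kind: str) -> list[str]:
    labels = [str(x).strip() for x in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {kind} labels: {dupes}")
    return labels


@dataclass
class BinaryFingerprintMatrix:
    """Presence/absence table: samples in rows, metabolites in columns."""

    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray  # (m, k) of 0/1 ints

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.sample_ids = _check_labels(self.sample_ids, "sample")
        self.metabolite_ids = _check_labels(self.metabolite_ids, "metabolite")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D table")
        m, k = self.values.shape
        if m < 2:
            raise ValueError(f"need at least 2 samples, got {m}")
        if k < 1:
            raise ValueError("need at least 1 metabolite")
        if (m, k) != (len(self.sample_ids), len(self.metabolite_ids)):
            raise ValueError(
                f"table shape {self.values.shape} does not match labels "
                f"({len(self.sample_ids)} samples, {len(self.metabolite_ids)} metabolites)"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at sample {self.sample_ids[i]!r}, "
                f"metabolite {self.metabolite_ids[j]!r}: {self.values[i, j]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.metabolite_ids)


@dataclass
class QuantitativeMatrix:
    """Non-negative concentration table: samples in rows, metabolites in columns."""

    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray  # (m, k) of floats

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = _check_labels(self.sample_ids, "sample")
        self.metabolite_ids = _check_labels(self.metabolite_ids, "metabolite")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D table")
        if self.values.shape != (len(self.sample_ids), len(self.metabolite_ids)):
            raise ValueError("table shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite concentration values")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative concentration at sample {self.sample_ids[i]!r}, "
                f"metabolite {self.metabolite_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.metabolite_ids)


@dataclass(frozen=True)
class DatasetDescriptor:
    """Summary of one case-study dataset."""

    id: int
    material: str
    metabolites: str
    n_metabolites: int
    n_samples: int
    method: str

    def __post_init__(self) -> None:
        if self.n_metabolites <= 0 or self.n_samples <= 0:
            raise ValueError("dataset sizes must be positive")


def _read_frame(path, dialect: str, sheet=0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    if dialect == "sheet":
        raw_header = pd.read_excel(path, sheet_name=sheet, header=None, nrows=1)
        df = pd.read_excel(path, sheet_name=sheet, index_col=0)
    else:
        raw_header = pd.read_csv(path, sep=_DIALECTS[dialect], header=None, nrows=1)
        df = pd.read_csv(path, sep=_DIALECTS[dialect], index_col=0)
    # pandas silently mangles duplicate header labels; check the raw header
    header = [str(x).strip() for x in raw_header.iloc[0, 1:]]
    if len(set(header)) != len(header):
        dupes = sorted({x for x in header if header.count(x) > 1})
        raise ValueError(f"duplicate column labels in {path}: {dupes}")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table in {path}")
    return df


def _oriented(df: pd.DataFrame, orientation: str) -> pd.DataFrame:
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    return df.T if orientation == "samples_in_columns" else df


def _parse_bit(cell, row, col):
    if isinstance(cell, str):
        cell = cell.strip()
    try:
        value = float(cell)
    except (TypeError, ValueError):
        value = np.nan
    if np.isnan(value):
        raise ValueError(f"missing or non-numeric cell at row {row!r}, column {col!r}: {cell!r}")
    if value not in (0.0, 1.0):
        raise ValueError(f"non-binary cell at row {row!r}, column {col!r}: {cell!r}")
    return int(value)


def read_binary_matrix(path, dialect: str = "csv", orientation: str = "samples_in_rows",
                       sheet=0) -> BinaryFingerprintMatrix:
    """Read a presence/absence table.

    ``dialect`` is ``csv``, ``tsv`` or ``sheet`` (one rectangular labelled
    block per spreadsheet sheet).  Cells may be numeric or text "0"/"1"
    (surrounding whitespace is stripped); anything else — including missing
    cells — raises :class:`ValueError` naming the offending coordinates.
    """
    df = _oriented(_read_frame(path, dialect, sheet), orientation)
    values = np.array(
        [[_parse_bit(df.iat[i, j], df.index[i], df.columns[j])
          for j in range(df.shape[1])]
         for i in range(df.shape[0])]
    )
    return BinaryFingerprintMatrix(list(df.index), list(df.columns), values)


def read_quantitative_matrix(path, dialect: str = "csv",
                             orientation: str = "samples_in_rows",
                             sheet=0) -> QuantitativeMatrix:
    """Read a non-negative concentration table (same layout rules as binary)."""
    df = _oriented(_read_frame(path, dialect, sheet), orientation)
    try:
        values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing cell at row {df.index[i]!r}, column {df.columns[j]!r}")
    return QuantitativeMatrix(list(df.index), list(df.columns), values)


def write_matrix(matrix, path, dialect: str = "csv") -> None:
    """Write a binary or quantitative matrix back to delimited text."""
    if dialect not in ("csv", "tsv"):
        raise ValueError("write supports csv and tsv")
    matrix.to_frame().to_csv(path, sep=_DIALECTS[dialect])


def binarize(quantitative: QuantitativeMatrix, threshold: float = 0.0) -> BinaryFingerprintMatrix:
    """Presence/absence view of a concentration table (value > threshold -> 1)."""
    return BinaryFingerprintMatrix(
        list(quantitative.sample_ids),
        list(quantitative.metabolite_ids),
        (quantitative.values > threshold).astype(np.int8),
    )


_REGISTRY = (
    DatasetDescriptor(1, "Hungarian thyme", "Polyphenolic compounds", 12, 8, "HPLC-DAD"),
    DatasetDescriptor(2, "Aloe species", "", 16, 18, "UHPLC-QTOF"),
    DatasetDescriptor(3, "Plant resins and propolis",
                      "Carboxylic acids, phenolic acids and esters", 26, 17,
                      "UHPLC-MS/MS Orbitrap"),
    DatasetDescriptor(4, "Plant resins and propolis", "Flavonoids", 26, 17,
                      "UHPLC-MS/MS Orbitrap"),
    DatasetDescriptor(5, "Plant resins and propolis", "Glycerides and glycosides", 11, 17,
                      "UHPLC-MS/MS Orbitrap"),
    DatasetDescriptor(6, "Cotoneaster species", "Polyphenols", 34, 12,
                      "UHPLC-PDA-ESI-QTOF-MS"),
    DatasetDescriptor(7, "Nepeta species", "Phenolic acids and their derivatives", 37, 12,
                      "UHPLC-LTQ/Orbitrap-MS"),
    DatasetDescriptor(8, "Coprinoid mushrooms (Coprinellus)", "Fatty acids", 5, 17,
                      "GC (FID)"),
    DatasetDescriptor(9, "Grapes, grape-derived products", "Polyphenols", 53, 29,
                      "HPLC-MS (DAD, MSD trap, ESI)"),
)


def dataset_registry() -> list[DatasetDescriptor]:
    """The nine case-study datasets (sizes of the published binary tables)."""
    return list(_REGISTRY)
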