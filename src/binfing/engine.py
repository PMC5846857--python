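"""Pairwise similarity matrices and their unfolding into the SRD input matrix.

For every similarity coefficient a full sample-by-sample matrix is computed
from the binary fingerprints; its strict lower triangle is then unfolded into
a vector indexed by sample pairs.  Stacking the unfolded vectors of all
coefficients column-wise yields the input matrix for sum-of-ranking-
differences analysis: one column per coefficient, one row per sample pair.

Directional coefficients (Di1/Di2, Pe1/Pe2) are evaluated in a canonical
pair orientation — entry (i, j) with i > j uses (fingerprint_i,
fingerprint_j) — and mirrored, so every similarity matrix is symmetric.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import MeasureSpec, catalog, evaluate_raw, rescale
from .io import BinaryFingerprintMatrix

__all__ = [
    "SimilarityMatrix",
    "SRDInputMatrix",
    "pairwise_counts",
    "pairwise_similarity",
    "unfold",
    "assemble_srd_input",
]


@dataclass
class SimilarityMatrix:
    """Symmetric m x m matrix of rescaled similarities for one coefficient."""

    sample_ids: list[str]
    measure_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.sample_ids)
        if self.values.shape != (m, m):
            raise ValueError("similarity matrix shape does not match sample labels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class SRDInputMatrix:
    """Unfolded similarities: one row per sample pair, one column per measure."""

    row_ids: list[tuple[str, str]]
    measure_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.measure_ids)):
            raise ValueError("SRD input shape does not match labels")

    @property
    def n_pairs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index([f"{i}|{j}" for i, j in self.row_ids], name="pair")
        return pd.DataFrame(self.values, index=idx, columns=self.measure_ids)


def pairwise_counts(values: np.ndarray):
    """Contingency count matrices (a, b, c, d) between all sample rows."""
    X = np.asarray(values, dtype=float)
    a = X @ X.T
    ones = X.sum(axis=1)
    b = ones[:, None] - a
    c = ones[None, :] - a
    d = X.shape[1] - a - b - c
    return a, b, c, d


def pairwise_similarity(matrix: BinaryFingerprintMatrix, measure: MeasureSpec) -> SimilarityMatrix:
    """Full similarity matrix of *measure* over all sample pairs."""
    a, b, c, d = pairwise_counts(matrix.values)
    raw = evaluate_raw(measure, (a, b, c, d))
    sim = rescale(raw, measure, float(matrix.n_metabolites))
    if measure.order_dependent:
        # canonical orientation: take the lower-triangle evaluation and mirror
        low = np.tril(sim, -1)
        sim = low + low.T + np.diag(np.diag(sim))
    return SimilarityMatrix(list(matrix.sample_ids), measure.id, sim)


def unfold(sim: SimilarityMatrix, include_diagonal: bool = False):
    """Strict lower triangle of a symmetric similarity matrix, row-major.

    Returns ``(vector, row_ids)`` where ``row_ids`` are the (sample_i,
    sample_j) pairs, i > j, in the order (2,1), (3,1), (3,2), ...
    ``include_diagonal`` appends the self-similarities for replication
    experiments that unfolded the full matrix.
    """
    v = sim.values
    if not np.allclose(v, v.T, atol=1e-12):
        raise ValueError("cannot unfold an asymmetric similarity matrix")
    ids = sim.sample_ids
    i_idx, j_idx = np.tril_indices(len(ids), k=-1)
    vec = v[i_idx, j_idx]
    row_ids = [(ids[i], ids[j]) for i, j in zip(i_idx, j_idx)]
    if include_diagonal:
        vec = np.concatenate([vec, np.diag(v)])
        row_ids = row_ids + [(s, s) for s in ids]
    return vec, row_ids


def assemble_srd_input(
    matrix: BinaryFingerprintMatrix,
    measures: Sequence[MeasureSpec] | None = None,
    include_diagonal: bool = False,
) -> SRDInputMatrix:
    """Unfold one similarity matrix per measure into the SRD input matrix."""
    if matrix.n_samples < 3:
        raise ValueError(
            f"need at least 3 samples (>= 3 pairs) for a meaningful ranking, "
            f"got {matrix.n_samples}"
        )
    if measures is None:
        measures = catalog()
    columns = []
    row_ids = None
    for m in measures:
        vec, ids = unfold(pairwise_similarity(matrix, m), include_diagonal)
        if row_ids is None:
            row_ids = ids
        columns.append(vec)
    return SRDInputMatrix(row_ids, [m.id for m in measures], np.column_stack(columns))
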