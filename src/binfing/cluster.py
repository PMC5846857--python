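"""Cluster-agreement analysis: Ward trees from binary vs quantitative data.

A binary similarity matrix is turned into distances d = 1 - s'; the
quantitative reference uses column-standardized profiles and the distance
1 - |Pearson correlation| between samples.  Both are clustered
agglomeratively with Ward's linkage applied directly to the supplied
dissimilarities via the Lance-Williams update (the classic "ward.D"
dialect; a squared-distance "d2" variant is available for sensitivity
analysis).  Cutting both trees at k clusters gives two partitions whose
agreement is scored as the correct classification rate (CCR%): the fraction
of samples whose labels match under the best cluster-label permutation.  A
pairwise Rand-type agreement is reported alongside.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import linear_sum_assignment

from .engine import SimilarityMatrix
from .io import QuantitativeMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterComparison",
    "binary_distance",
    "quantitative_distance",
    "ward_linkage",
    "cut_tree",
    "ccr",
    "to_newick",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        m = len(self.sample_ids)
        if v.shape != (m, m):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("negative dissimilarities")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class Dendrogram:
    """Merge sequence in scipy linkage form plus leaf order."""

    sample_ids: list[str]
    merges: np.ndarray  # (m-1, 4): cluster_i, cluster_j, height, new_size
    leaf_order: list[int]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class ClusterComparison:
    sample_ids: list[str]
    assignment_a: np.ndarray
    assignment_b: np.ndarray
    k: int
    ccr_percent: float
    misclassification_count: int
    rand_percent: float


def binary_distance(sim: SimilarityMatrix) -> DistanceMatrix:
    """Distances d = 1 - s' from a rescaled similarity matrix (diagonal -> 0)."""
    v = 1.0 - np.asarray(sim.values, dtype=float)
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(list(sim.sample_ids), v)


def quantitative_distance(matrix: QuantitativeMatrix) -> DistanceMatrix:
    """1 - |Pearson r| between samples on column-standardized concentrations.

    Metabolite columns are standardized to zero mean and unit variance;
    constant columns carry no information and are dropped with a warning.
    """
    X = np.asarray(matrix.values, dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [matrix.metabolite_ids[j] for j in np.flatnonzero(~keep)]
        warnings.warn(f"dropping constant metabolite columns: {dropped}", stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("need at least 2 non-constant metabolites for a correlation distance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # a sample with a constant standardized profile has undefined r; treat it
    # as uncorrelated with everything (distance 1)
    flat = Z.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(Z)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    d = 1.0 - np.abs(np.clip(r, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.sample_ids), d)


def ward_linkage(d: DistanceMatrix, dialect: str = "d") -> Dendrogram:
    """Agglomerative Ward clustering on a precomputed dissimilarity matrix.

    ``dialect="d"`` applies the Lance-Williams Ward update to the supplied
    dissimilarities as they are (legacy "ward.D" behaviour);
    ``dialect="d2"`` applies it to their squares and reports square-rooted
    heights ("ward.D2").  Ties are broken towards the lexicographically
    smallest cluster-index pair, so the merge sequence is deterministic.
    """
    if dialect not in ("d", "d2"):
        raise ValueError("dialect must be 'd' or 'd2'")
    m = d.n_samples
    if m < 2:
        raise ValueError("need at least 2 samples to cluster")
    # Lance-Williams on working distances; for ward.D2 work on squares.
    work = d.values.astype(float) ** (2 if dialect == "d2" else 1)
    active = {i: (i, 1) for i in range(m)}  # pos -> (cluster id, size)
    dist = work.copy()
    np.fill_diagonal(dist, np.inf)
    merges = np.zeros((m - 1, 4))
    next_id = m
    positions = list(range(m))
    for step in range(m - 1):
        # nearest pair; ties -> smallest (i, j) among active positions
        best = (np.inf, None, None)
        for ii in range(len(positions)):
            for jj in range(ii + 1, len(positions)):
                pi, pj = positions[ii], positions[jj]
                val = dist[pi, pj]
                if val < best[0] - 1e-15:
                    best = (val, pi, pj)
        height, pi, pj = best
        ci, ni = active[pi]
        cj, nj = active[pj]
        lo, hi = min(ci, cj), max(ci, cj)
        merges[step] = (lo, hi, np.sqrt(height) if dialect == "d2" else height, ni + nj)
        # Lance-Williams Ward update against every other active position
        for pk in positions:
            if pk in (pi, pj):
                continue
            nk = active[pk][1]
            new = ((ni + nk) * dist[pi, pk] + (nj + nk) * dist[pj, pk]
                   - nk * height) / (ni + nj + nk)
            dist[pi, pk] = dist[pk, pi] = new
        active[pi] = (next_id, ni + nj)
        next_id += 1
        del active[pj]
        positions.remove(pj)
        dist[pj, :] = np.inf
        dist[:, pj] = np.inf
    leaf_order = [int(x) for x in hierarchy.leaves_list(
        np.ascontiguousarray(merges, dtype=float))]
    return Dendrogram(list(d.sample_ids), merges, leaf_order)


def cut_tree(t: Dendrogram, k: int) -> np.ndarray:
    """Per-sample cluster labels (0..k-1) after undoing the last k-1 merges."""
    m = t.n_samples
    if not 1 <= k <= m:
        raise ValueError(f"k must be between 1 and {m}")
    labels = hierarchy.cut_tree(np.ascontiguousarray(t.merges, dtype=float),
                                n_clusters=k).ravel()
    return labels.astype(int)


def ccr(assignment_a, assignment_b, k: int = 2,
        sample_ids: list[str] | None = None) -> ClusterComparison:
    """Correct classification rate between two partitions.

    The fraction of samples with matching labels, maximized over all
    cluster-label permutations (solved as an assignment problem, so any k
    works); 100% means the partitions are identical up to relabeling.  The
    Rand-type pairwise agreement (fraction of sample pairs on which the two
    partitions agree) is reported alongside as ``rand_percent``.
    """
    a = np.asarray(assignment_a)
    b = np.asarray(assignment_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("assignments must be equal-length 1-D label vectors")
    m = a.size
    ula, ulb = np.unique(a), np.unique(b)
    if len(ula) > k or len(ulb) > k:
        raise ValueError(f"assignments use more than k={k} labels")
    # contingency of label co-occurrence
    cont = np.zeros((k, k))
    for i, la in enumerate(ula):
        for j, lb in enumerate(ulb):
            cont[i, j] = np.sum((a == la) & (b == lb))
    rows, cols = linear_sum_assignment(-cont)
    matched = int(cont[rows, cols].sum())
    from sklearn.metrics import rand_score

    return ClusterComparison(
        sample_ids=sample_ids if sample_ids is not None else [str(i) for i in range(m)],
        assignment_a=a,
        assignment_b=b,
        k=k,
        ccr_percent=100.0 * matched / m,
        misclassification_count=m - matched,
        rand_percent=100.0 * float(rand_score(a, b)),
    )


def to_newick(t: Dendrogram) -> str:
    """Newick serialization with branch lengths from merge heights."""
    m = t.n_samples
    heights = {i: 0.0 for i in range(m)}
    nodes = {i: t.sample_ids[i] for i in range(m)}
    for step, (ci, cj, h, _) in enumerate(t.merges):
        ci, cj = int(ci), int(cj)
        left, right = nodes.pop(ci), nodes.pop(cj)
        bl_l = max(h - heights[ci], 0.0)
        bl_r = max(h - heights[cj], 0.0)
        new = m + step
        nodes[new] = f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"
        heights[new] = h
    (root,) = nodes.values()
    return root + ";"
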