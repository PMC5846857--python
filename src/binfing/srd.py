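"""Sum of ranking differences (SRD) with randomization and bootstrap validation.

SRD compares column variables against a consensus reference: every column
(and the reference) is rank-transformed by increasing magnitude, and a
column's SRD is the sum of absolute differences between its ranks and the
reference ranks.  Small SRD means the variable ranks the objects like the
consensus does.  Values are normalized by the maximal attainable SRD
(realized by reversing the reference ordering) and reported in percent.

Two validation layers accompany the statistic:

* CRRN (comparison of ranks with random numbers): the distribution of SRD
  for a uniformly random permutation against the reference, giving the
  chance band an observed SRD must beat.
* bootstrap cross-validation: rows (sample pairs) are resampled with
  replacement, the consensus is recomputed inside each resample, and the
  spread of normalized SRD across resamples is reported.

Average (fractional) ranks are used for ties throughout, so heavily tied
similarity columns remain comparable.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .engine import SRDInputMatrix

__all__ = [
    "RankVector",
    "SRDResult",
    "BootstrapSRDResult",
    "CRRNDistribution",
    "rank_transform",
    "consensus_reference",
    "srd",
    "srd_max",
    "crrn_distribution",
    "run_srd",
    "bootstrap_srd",
]

_CONSENSUS_MODES = ("average", "min", "max", "median")


@dataclass(frozen=True)
class RankVector:
    """Average ranks of a column (rank 1 = smallest value)."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        expected = self.n * (self.n + 1) / 2
        if not math.isclose(float(self.values.sum()), expected, rel_tol=1e-9):
            raise ValueError("ranks do not sum to n(n+1)/2")


@dataclass(frozen=True)
class SRDResult:
    measure_id: str
    srd: float
    srd_max: float
    srd_norm: float  # percent of srd_max
    null_percentiles: tuple[float, float, float]  # 5% / median / 95%, percent


@dataclass(frozen=True)
class BootstrapSRDResult:
    measure_id: str
    iterations: int
    mean_srd_norm: float
    sd: float
    interval: tuple[float, float]  # 2.5% / 97.5% percentile interval


@dataclass(frozen=True)
class CRRNDistribution:
    """Probability mass of SRD under uniformly random tie-free rankings."""

    n: int
    values: np.ndarray  # achievable SRD values
    pmf: np.ndarray
    srd_max: float
    method: str

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def percentile(self, q: float) -> float:
        """Smallest normalized SRD (percent) with CDF >= q."""
        idx = int(np.searchsorted(self.cdf(), q))
        idx = min(idx, len(self.values) - 1)
        return 100.0 * float(self.values[idx]) / self.srd_max

    def percentiles(self, qs=(0.05, 0.5, 0.95)) -> tuple[float, ...]:
        return tuple(self.percentile(q) for q in qs)


def rank_transform(column) -> RankVector:
    """Average ranks by increasing magnitude (ties share fractional ranks)."""
    col = np.asarray(column, dtype=float)
    if col.size == 0:
        raise ValueError("cannot rank an empty column")
    if not np.all(np.isfinite(col)):
        raise ValueError("non-finite values in column")
    return RankVector(rankdata(col, method="average"), col.size)


def consensus_reference(input_matrix: SRDInputMatrix | np.ndarray, mode: str = "average") -> np.ndarray:
    """Row-wise consensus of the input columns (the synthetic 'ideal' column)."""
    if mode not in _CONSENSUS_MODES:
        raise ValueError(f"unknown consensus mode {mode!r}; choose from {_CONSENSUS_MODES}")
    values = input_matrix.values if isinstance(input_matrix, SRDInputMatrix) else np.asarray(input_matrix, dtype=float)
    if values.ndim != 2:
        raise ValueError("input must be 2-D (rows x variables)")
    fn = {"average": np.mean, "min": np.min, "max": np.max, "median": np.median}[mode]
    return fn(values, axis=1)


def srd(column_ranks: RankVector, reference_ranks: RankVector) -> float:
    """Sum of absolute rank differences between a column and the reference."""
    if column_ranks.n != reference_ranks.n:
        raise ValueError(f"rank length mismatch: {column_ranks.n} vs {reference_ranks.n}")
    return float(np.abs(column_ranks.values - reference_ranks.values).sum())


def srd_max(reference_ranks: RankVector) -> float:
    """Maximal attainable SRD against this reference.

    Computed as the SRD of the reference's reversed ordering, which for a
    tie-free reference equals n^2/2 (n even) or (n^2 - 1)/2 (n odd) and
    handles tied references consistently.  A constant reference yields 0,
    flagging normalization as undefined.
    """
    r = reference_ranks.values
    reversed_ranks = (reference_ranks.n + 1) - r
    return float(np.abs(r - reversed_ranks).sum())


def _exact_footrule_pmf(n: int):
    """Enumerate SRD = sum |pi(i) - i| over all n! permutations."""
    counts: dict[int, int] = {}
    base = np.arange(1, n + 1)
    for perm in itertools.permutations(range(1, n + 1)):
        d = int(np.abs(np.asarray(perm) - base).sum())
        counts[d] = counts.get(d, 0) + 1
    values = np.array(sorted(counts), dtype=float)
    pmf = np.array([counts[int(v)] for v in values], dtype=float)
    return values, pmf / pmf.sum()


def crrn_distribution(n: int, method: str = "exact", draws: int = 10_000,
                      seed: int | np.random.Generator | None = None) -> CRRNDistribution:
    """Null distribution of SRD for a random ranking of *n* objects.

    ``exact`` enumerates all n! permutations (n <= 9); ``monte_carlo`` draws
    random permutations.  Values are SRD against a fixed tie-free reference;
    normalized percentiles use srd_max = n^2/2 (even) or (n^2-1)/2 (odd).
    """
    if n < 2:
        raise ValueError("CRRN needs at least 2 objects")
    smax = n * n / 2 if n % 2 == 0 else (n * n - 1) / 2
    if method == "exact":
        if n > 9:
            raise ValueError(
                f"exact CRRN enumerates n! permutations and is limited to n <= 9 "
                f"(got n={n}); use method='monte_carlo'"
            )
        values, pmf = _exact_footrule_pmf(n)
    elif method == "monte_carlo":
        if draws < 1:
            raise ValueError("draws must be positive")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        base = np.arange(1, n + 1)
        perms = np.argsort(rng.random((draws, n)), axis=1) + 1  # uniform permutations
        d = np.abs(perms - base).sum(axis=1)
        values, counts = np.unique(d, return_counts=True)
        pmf = counts / counts.sum()
        values = values.astype(float)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CRRNDistribution(n=n, values=values, pmf=pmf, srd_max=float(smax), method=method)


def run_srd(input_matrix: SRDInputMatrix, mode: str = "average",
            seed: int | np.random.Generator | None = None,
            crrn_draws: int = 10_000) -> list[SRDResult]:
    """SRD of every measure column against the consensus reference.

    Null percentiles (5% / median / 95% of the CRRN distribution) are
    attached from exact enumeration when the number of rows allows it,
    otherwise from a seeded Monte Carlo sample.
    """
    ref = consensus_reference(input_matrix, mode)
    ref_ranks = rank_transform(ref)
    smax = srd_max(ref_ranks)
    if smax == 0:
        raise ValueError(
            "consensus reference is constant across rows; SRD normalization undefined"
        )
    n = input_matrix.n_pairs
    method = "exact" if n <= 9 else "monte_carlo"
    null = crrn_distribution(n, method=method, draws=crrn_draws, seed=seed)
    pct = null.percentiles()
    results = []
    for j, mid in enumerate(input_matrix.measure_ids):
        col_ranks = rank_transform(input_matrix.values[:, j])
        value = srd(col_ranks, ref_ranks)
        results.append(
            SRDResult(
                measure_id=mid,
                srd=value,
                srd_max=smax,
                srd_norm=100.0 * value / smax,
                null_percentiles=pct,
            )
        )
    return results


def _srd_norm_columns(values: np.ndarray, mode: str) -> np.ndarray | None:
    """Normalized SRD of every column of *values*; None for a constant reference."""
    ref = consensus_reference(values, mode)
    ref_ranks = rankdata(ref, method="average")
    smax = np.abs(ref_ranks - (len(ref_ranks) + 1 - ref_ranks)).sum()
    if smax == 0:
        return None
    col_ranks = rankdata(values, method="average", axis=0)
    return 100.0 * np.abs(col_ranks - ref_ranks[:, None]).sum(axis=0) / smax


def bootstrap_srd(input_matrix: SRDInputMatrix, iterations: int = 100,
                  seed: int | np.random.Generator | None = None,
                  mode: str = "average") -> list[BootstrapSRDResult]:
    """Bootstrap cross-validation of normalized SRD.

    Rows of the unfolded matrix (sample pairs) are resampled with
    replacement to the original size; the consensus reference is recomputed
    inside each resample.  Resamples whose reference is constant (no ranking
    information) are redrawn.
    """
    if iterations < 2:
        raise ValueError("need at least 2 bootstrap iterations")
    n = input_matrix.n_pairs
    if n < 5:
        raise ValueError(f"need at least 5 rows to bootstrap, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    attempts = 0
    while len(rows) < iterations:
        attempts += 1
        if attempts > 20 * iterations:
            raise ValueError("could not draw non-degenerate bootstrap resamples")
        idx = rng.integers(0, n, size=n)
        norm = _srd_norm_columns(input_matrix.values[idx], mode)
        if norm is not None:
            rows.append(norm)
    norms = np.asarray(rows)
    lo, hi = np.percentile(norms, [2.5, 97.5], axis=0)
    return [
        BootstrapSRDResult(
            measure_id=mid,
            iterations=iterations,
            mean_srd_norm=float(norms[:, j].mean()),
            sd=float(norms[:, j].std(ddof=1)),
            interval=(float(lo[j]), float(hi[j])),
        )
        for j, mid in enumerate(input_matrix.measure_ids)
    ]
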