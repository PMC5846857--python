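"""Sum of ranking differences: ranks, consensus, normalization, CRRN, bootstrap."""
import itertools
import math

import numpy as np
import pytest

from binfing.engine import SRDInputMatrix
from binfing.srd import (RankVector, bootstrap_srd, consensus_reference,
                         crrn_distribution, rank_transform, run_srd, srd,
                         srd_max)


def footrule_oracle(n):
    """Independent enumeration: multiset of sum|pi(i)-i| over all n! permutations."""
    out = {}
    for perm in itertools.permutations(range(1, n + 1)):
        d = sum(abs(v - i) for i, v in enumerate(perm, start=1))
        out[d] = out.get(d, 0) + 1
    return out


def make_input(values, ids=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    row_ids = [(f"s{i}", f"s{j}") for i in range(n) for j in range(i)][:n] or \
              [(f"r{i}", f"r{i}b") for i in range(n)]
    row_ids = [(f"p{i}", f"q{i}") for i in range(n)]
    cols = ids or [f"v{j}" for j in range(values.shape[1])]
    return SRDInputMatrix(row_ids, cols, values)


class TestRankTransform:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ((0.1, 0.3, 0.2), (1, 3, 2)),
            ((0.2, 0.2, 0.5), (1.5, 1.5, 3)),
            ((7, 7, 7, 7), (2.5, 2.5, 2.5, 2.5)),
        ],
    )
    def test_examples(self, column, expected):
        assert rank_transform(column).values.tolist() == list(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_transform([])

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(1, 50))
            rv = rank_transform(rng.normal(size=n))
            assert rv.values.sum() == pytest.approx(n * (n + 1) / 2)


class TestConsensus:
    def test_average_and_max(self):
        X = make_input([[0, 1], [1, 1]])
        assert consensus_reference(X, "average").tolist() == [0.5, 1.0]
        assert consensus_reference(X, "max").tolist() == [1.0, 1.0]

    def test_single_column_average_is_identity(self):
        X = make_input([[0.3], [0.7], [0.1]])
        assert consensus_reference(X, "average").tolist() == [0.3, 0.7, 0.1]

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            consensus_reference(make_input([[0, 1], [1, 1]]), "mode")


class TestSRD:
    def test_identity_is_zero(self):
        r = RankVector(np.array([1.0, 2, 3, 4]), 4)
        assert srd(r, r) == 0

    def test_reversal_n4(self):
        a = RankVector(np.array([4.0, 3, 2, 1]), 4)
        b = RankVector(np.array([1.0, 2, 3, 4]), 4)
        assert srd(a, b) == 8  # exhaustive max over the 24 permutations of n=4

    def test_single_swap(self):
        a = RankVector(np.array([2.0, 1, 3, 4]), 4)
        b = RankVector(np.array([1.0, 2, 3, 4]), 4)
        assert srd(a, b) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            srd(RankVector(np.array([1.0, 2]), 2), RankVector(np.array([1.0, 2, 3]), 3))

    def test_symmetry_tie_free(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(2, 12))
            x = rank_transform(rng.permutation(n))
            y = rank_transform(rng.permutation(n))
            assert srd(x, y) == srd(y, x)

    def test_monotone_transform_invariance(self):
        """SRD is unchanged by any strictly increasing transform of a column
        (1,000 random columns)."""
        rng = np.random.default_rng(11)
        ref = rank_transform(rng.normal(size=30))
        for _ in range(1000):
            col = rng.normal(size=30)
            before = srd(rank_transform(col), ref)
            after = srd(rank_transform(np.exp(2.0 * col) + 5.0), ref)
            assert before == after


class TestSRDMax:
    @pytest.mark.parametrize("n", range(2, 7))
    def test_matches_exhaustive_enumeration(self, n):
        ref = RankVector(np.arange(1.0, n + 1), n)
        oracle = max(
            sum(abs(v - i) for i, v in enumerate(perm, start=1))
            for perm in itertools.permutations(range(1, n + 1))
        )
        assert srd_max(ref) == oracle
        assert oracle == (n * n // 2 if n % 2 == 0 else (n * n - 1) // 2)

    def test_constant_reference_flags_degenerate(self):
        ref = rank_transform([3.0, 3.0, 3.0, 3.0])
        assert srd_max(ref) == 0


class TestCRRN:
    def test_n3_exact_pmf(self):
        dist = crrn_distribution(3, "exact")
        assert dist.values.tolist() == [0, 2, 4]
        assert dist.pmf.tolist() == pytest.approx([1 / 6, 2 / 6, 3 / 6])

    def test_n4_probability_of_zero(self):
        dist = crrn_distribution(4, "exact")
        assert dist.pmf[dist.values.tolist().index(0)] == pytest.approx(1 / 24)

    @pytest.mark.parametrize("n", range(2, 8))
    def test_exact_matches_enumeration_oracle(self, n):
        oracle = footrule_oracle(n)
        dist = crrn_distribution(n, "exact")
        total = math.factorial(n)
        assert dist.values.tolist() == sorted(oracle)
        for v, p in zip(dist.values, dist.pmf):
            assert p == pytest.approx(oracle[int(v)] / total)

    def test_pmf_sums_to_one(self):
        for n in (2, 5, 9):
            assert crrn_distribution(n, "exact").pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mean_matches_oracle(self):
        for n in range(2, 8):
            oracle = footrule_oracle(n)
            total = math.factorial(n)
            mean_oracle = sum(d * c for d, c in oracle.items()) / total
            dist = crrn_distribution(n, "exact")
            assert float((dist.values * dist.pmf).sum()) == pytest.approx(mean_oracle)

    def test_exact_rejected_above_nine(self):
        with pytest.raises(ValueError, match="monte_carlo"):
            crrn_distribution(10, "exact")

    def test_monte_carlo_close_to_exact_n8(self):
        exact = crrn_distribution(8, "exact")
        mc = crrn_distribution(8, "monte_carlo", draws=100_000, seed=123)
        pe = dict(zip(exact.values, exact.pmf))
        pm = dict(zip(mc.values, mc.pmf))
        tvd = 0.5 * sum(abs(pe.get(v, 0) - pm.get(v, 0)) for v in set(pe) | set(pm))
        assert tvd <= 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            crrn_distribution(1)


class TestRunSRD:
    def test_column_equal_to_consensus_scores_zero(self):
        rng = np.random.default_rng(2)
        base = rng.random((20, 4))
        consensus = base.mean(axis=1, keepdims=True)
        X = make_input(np.hstack([base, consensus]), ids=list("abcd") + ["avg"])
        res = run_srd(X, seed=0)
        assert dict((r.measure_id, r.srd_norm) for r in res)["avg"] == 0.0

    def test_duplicate_columns_identical_srd(self):
        rng = np.random.default_rng(3)
        col = rng.random(15)
        X = make_input(np.column_stack([col, rng.random(15), col]))
        res = run_srd(X, seed=0)
        assert res[0].srd == res[2].srd

    def test_norm_in_bounds(self):
        rng = np.random.default_rng(4)
        X = make_input(rng.random((20, 5)))
        for r in run_srd(X, seed=0):
            assert 0 <= r.srd_norm <= 100

    def test_reference_vs_itself_scores_zero(self):
        col = np.arange(10.0)
        X = make_input(np.column_stack([col, col]))
        res = run_srd(X, seed=0)
        assert res[0].srd_norm == 0.0

    def test_reversed_reference_scores_100(self):
        col = np.arange(12.0)
        X = make_input(np.column_stack([col, col, col[::-1]]))
        res = run_srd(X, mode="median", seed=0)
        assert dict((r.measure_id, r.srd_norm) for r in res)["v2"] == 100.0

    def test_constant_reference_rejected(self):
        X = make_input(np.column_stack([np.arange(6.0), 5 - np.arange(6.0)]))
        with pytest.raises(ValueError, match="constant"):
            run_srd(X, mode="average", seed=0)


class TestBootstrap:
    def _input(self, n=40, k=6, seed=8):
        rng = np.random.default_rng(seed)
        return make_input(rng.random((n, k)))

    def test_deterministic_under_seed(self):
        X = self._input()
        assert bootstrap_srd(X, 60, seed=99) == bootstrap_srd(X, 60, seed=99)

    def test_consensus_duplicate_column_near_zero(self):
        rng = np.random.default_rng(9)
        base = rng.random((30, 3))
        withmean = np.hstack([base, base, base.mean(axis=1, keepdims=True)])
        # the mean column equals the recomputed consensus in every resample
        X = make_input(withmean)
        res = bootstrap_srd(X, 80, seed=1)
        assert res[-1].mean_srd_norm == pytest.approx(0.0, abs=1e-9)

    def test_bootstrap_mean_consistent_with_full_data(self):
        """Bootstrap mean within 2 sd of the full-data normalized SRD."""
        rng = np.random.default_rng(10)
        X = make_input(rng.random((60, 10)))
        full = {r.measure_id: r.srd_norm for r in run_srd(X, seed=0)}
        for b in bootstrap_srd(X, 100, seed=2):
            assert abs(b.mean_srd_norm - full[b.measure_id]) <= max(2 * b.sd, 1e-9)

    def test_too_few_iterations_or_rows(self):
        X = self._input()
        with pytest.raises(ValueError, match="iterations"):
            bootstrap_srd(X, 1, seed=0)
        small = make_input(np.random.default_rng(0).random((4, 3)))
        with pytest.raises(ValueError, match="rows"):
            bootstrap_srd(small, 10, seed=0)
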