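"""Ward clustering on precomputed dissimilarities and partition agreement."""
import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from binfing.catalog import get_measure
from binfing.cluster import (DistanceMatrix, binary_distance, ccr, cut_tree,
                             quantitative_distance, to_newick, ward_linkage)
from binfing.engine import SimilarityMatrix, pairwise_similarity
from binfing.io import QuantitativeMatrix


def dmat(values, ids=None):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(ids or [f"s{i}" for i in range(len(values))], values)


class TestBinaryDistance:
    def test_complement_of_similarity(self):
        sim = SimilarityMatrix(["a", "b"], "SM", np.array([[1.0, 0.5], [0.5, 1.0]]))
        d = binary_distance(sim)
        assert d.values[0, 1] == 0.5
        assert d.values[0, 0] == 0.0

    def test_symmetric_output(self, synthetic_pair):
        sim = pairwise_similarity(synthetic_pair.binary, get_measure("BUB"))
        d = binary_distance(sim)
        assert np.allclose(d.values, d.values.T)


class TestQuantitativeDistance:
    def test_identical_and_negated_profiles(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        # rows: x, x (r=1) and a profile anti-correlated with x (|r|=1)
        q = QuantitativeMatrix(
            ["a", "b", "c"], ["m1", "m2", "m3", "m4"],
            np.vstack([base, base, base[::-1]]),
        )
        d = quantitative_distance(q)
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d.values[0, 2] == pytest.approx(0.0, abs=1e-12)  # |r| = 1 by absolute value

    def test_orthogonal_profiles(self):
        # standardized profiles of a and b are exactly orthogonal (r = 0)
        q = QuantitativeMatrix(
            ["a", "b", "c", "d"], ["m1", "m2", "m3", "m4"],
            np.array([
                [3.0, 1.0, 3.0, 1.0],
                [3.0, 3.0, 1.0, 1.0],
                [1.0, 3.0, 1.0, 3.0],
                [1.0, 1.0, 3.0, 3.0],
            ]),
        )
        d = quantitative_distance(q)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_constant_columns_dropped_with_warning(self):
        q = QuantitativeMatrix(
            ["a", "b", "c"], ["m1", "m2", "m3"],
            np.array([[1.0, 5.0, 1.0], [2.0, 5.0, 2.0], [3.0, 5.0, 1.5]]),
        )
        with pytest.warns(UserWarning, match="constant"):
            quantitative_distance(q)

    def test_too_few_usable_metabolites(self):
        q = QuantitativeMatrix(
            ["a", "b"], ["m1", "m2"], np.array([[1.0, 1.0], [2.0, 1.0]])
        )
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="non-constant"):
                quantitative_distance(q)


class TestWard:
    def test_first_merge_and_lance_williams_update(self):
        # d(1,2)=1, d(1,3)=5, d(2,3)=5 -> first merge {1,2};
        # then d({1,2},3) = (2*5 + 2*5 - 1*1)/3 = 19/3
        d = dmat([[0, 1, 5], [1, 0, 5], [5, 5, 0]])
        t = ward_linkage(d)
        assert (t.merges[0, 0], t.merges[0, 1]) == (0, 1)
        assert t.merges[0, 2] == pytest.approx(1.0)
        assert t.merges[1, 2] == pytest.approx(19 / 3)

    def test_merge_count(self):
        rng = np.random.default_rng(0)
        X = rng.random((17, 5))
        D = np.abs(X[:, None, :] - X[None, :, :]).sum(-1)
        np.fill_diagonal(D, 0)
        t = ward_linkage(dmat(D))
        assert t.merges.shape == (16, 4)

    def test_scaling_invariance_of_topology(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 4))
        D = np.abs(X[:, None, :] - X[None, :, :]).sum(-1)
        np.fill_diagonal(D, 0)
        t1 = ward_linkage(dmat(D))
        t2 = ward_linkage(dmat(D * 7.3))
        assert np.array_equal(t1.merges[:, :2], t2.merges[:, :2])
        assert np.allclose(t2.merges[:, 2], 7.3 * t1.merges[:, 2])

    def test_d2_dialect_matches_scipy_ward(self):
        """The squared-distance dialect reproduces scipy's Ward linkage on a
        Euclidean distance matrix (independent implementation cross-check)."""
        rng = np.random.default_rng(2)
        X = rng.random((12, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        t = ward_linkage(dmat(D), dialect="d2")
        Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
        assert np.allclose(np.sort(t.merges[:, 2]), np.sort(Z[:, 2]), atol=1e-9)
        lab_mine = cut_tree(t, 3)
        lab_scipy = hierarchy.cut_tree(Z, 3).ravel()
        assert ccr(lab_mine, lab_scipy, k=3).ccr_percent == 100.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(DistanceMatrix(["a"], np.zeros((1, 1))))


class TestCutTree:
    @pytest.fixture
    def tree(self):
        return ward_linkage(dmat([[0, 1, 5], [1, 0, 5], [5, 5, 0]]))

    def test_k1_all_together(self, tree):
        assert len(set(cut_tree(tree, 1))) == 1

    def test_km_all_singletons(self, tree):
        assert len(set(cut_tree(tree, 3))) == 3

    def test_k2_nearest_pair_together(self, tree):
        labels = cut_tree(tree, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_invalid_k(self, tree):
        for k in (0, 4):
            with pytest.raises(ValueError):
                cut_tree(tree, k)


class TestCCR:
    def test_identical_assignments(self):
        c = ccr([0, 0, 1, 1], [0, 0, 1, 1])
        assert c.ccr_percent == 100.0 and c.misclassification_count == 0

    def test_label_swap_invariance(self):
        c = ccr([0, 0, 1, 1], [1, 1, 0, 0])
        assert c.ccr_percent == 100.0

    def test_one_mismatch(self):
        c = ccr(list("AAAB"), list("AABB"))
        assert c.ccr_percent == 75.0 and c.misclassification_count == 1

    def test_permutation_invariance_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.integers(0, 2, 15)
            b = rng.integers(0, 2, 15)
            base = ccr(a, b).ccr_percent
            assert ccr(1 - a, b).ccr_percent == base
            assert ccr(a, 1 - b).ccr_percent == base
            assert ccr(a, b).rand_percent == ccr(1 - a, b).rand_percent

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            ccr([0, 1], [0, 1, 1])

    def test_too_many_labels(self):
        with pytest.raises(ValueError, match="more than"):
            ccr([0, 1, 2], [0, 1, 1], k=2)


class TestNewick:
    def test_well_formed_and_complete(self):
        t = ward_linkage(dmat([[0, 1, 5], [1, 0, 5], [5, 5, 0]], ids=["x", "y", "z"]))
        nwk = to_newick(t)
        assert nwk.endswith(";")
        for leaf in ("x", "y", "z"):
            assert leaf in nwk
        assert nwk.count("(") == 2  # m - 1 internal nodes


class TestPipelineProperty:
    def test_perfect_structure_gives_full_agreement(self):
        """Well-separated groups with zero flip noise: binary (BUB) clustering
        agrees 100% with the quantitative-reference clustering.  Three groups
        are used because the absolute-correlation reference distance cannot
        distinguish two balanced complementary groups."""
        from binfing.synth import SyntheticSpec, generate

        for seed in range(5):
            ds = generate(SyntheticSpec(n_groups=3, samples_per_group=6,
                                        flip_noise=0.0, seed=seed))
            bt = ward_linkage(binary_distance(
                pairwise_similarity(ds.binary, get_measure("BUB"))))
            with pytest.warns(UserWarning):
                qt = ward_linkage(quantitative_distance(ds.quantitative))
            agreement = ccr(cut_tree(bt, 3), cut_tree(qt, 3), k=3)
            assert agreement.ccr_percent == 100.0

    def test_group_free_noise_is_at_chance(self):
        """With flip noise 0.5 the bits are independent of group structure and
        CCR against the true labels falls to the chance band of the optimal
        2-label matching."""
        from binfing.synth import SyntheticSpec, generate

        rng = np.random.default_rng(0)
        vals, chance = [], []
        for seed in range(40):
            ds = generate(SyntheticSpec(flip_noise=0.5, seed=seed))
            bt = ward_linkage(binary_distance(
                pairwise_similarity(ds.binary, get_measure("BUB"))))
            labels = cut_tree(bt, 2)
            vals.append(ccr(labels, ds.true_labels, k=2).ccr_percent)
            chance.append(ccr(labels, rng.permutation(ds.true_labels), k=2).ccr_percent)
        chance = np.asarray(chance)
        band = (chance.mean() - 3 * chance.std(ddof=1) / np.sqrt(len(chance)),
                chance.mean() + 3 * chance.std(ddof=1) / np.sqrt(len(chance)))
        assert band[0] <= np.mean(vals) <= band[1]
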