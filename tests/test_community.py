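"""Bray-Curtis, UPGMA, cophenetic validation, tree cutting, Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

import oracles
from trflptools.community import (
    bray_curtis,
    cophenetic_correlation,
    cut_tree,
    kruskal_wallis,
    to_newick,
    upgma,
)


def dm3():
    """d(A,B)=0.2, d(A,C)=d(B,C)=0.6 — exactly representable ultrametric."""
    data = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
    return DistanceMatrix(data, ids=["A", "B", "C"])


def random_dm(rng, n):
    condensed = rng.uniform(0.05, 1.0, n * (n - 1) // 2)
    return DistanceMatrix(squareform(condensed), ids=[f"s{i}" for i in range(n)])


class TestBrayCurtis:
    def test_identical_rows_are_zero(self):
        df = pd.DataFrame([[0.2, 0.8], [0.2, 0.8]], index=["a", "b"])
        assert bray_curtis(df)["a", "b"] == 0.0

    def test_disjoint_supports_are_one(self):
        df = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"])
        assert bray_curtis(df)["a", "b"] == 1.0

    def test_hand_computed_value(self):
        df = pd.DataFrame([[1, 3], [3, 1]], index=["a", "b"])
        assert bray_curtis(df)["a", "b"] == pytest.approx(0.5)  # 4/8

    def test_all_zero_pair_defined_as_zero(self):
        df = pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=list("abc"))
        dm = bray_curtis(df)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[1, -1], [1, 1]]))

    def test_bounded_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.dirichlet([1] * 6, size=10))
        dm = bray_curtis(df)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        np.testing.assert_allclose(dm.data, dm.data.T)
        assert np.diag(dm.data).sum() == 0


class TestUpgma:
    def test_two_leaves_merge_at_their_distance(self):
        dm = DistanceMatrix(np.array([[0, 0.4], [0.4, 0]]), ids=["A", "B"])
        tree = upgma(dm)
        assert tree.root_height == pytest.approx(0.4)

    def test_three_leaf_hand_execution(self):
        tree = upgma(dm3())
        heights = sorted(tree.linkage[:, 2])
        assert heights == pytest.approx([0.2, 0.6])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(np.zeros((1, 1)), ids=["A"]))

    def test_heights_non_decreasing_to_root(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            tree = upgma(random_dm(rng, 8))
            merge_heights = tree.linkage[:, 2]
            # scipy emits merges in non-decreasing height order for UPGMA
            assert np.all(np.diff(merge_heights) >= -1e-12)

    def test_agreement_with_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            dm = random_dm(rng, n)
            tree = upgma(dm)
            want = oracles.brute_upgma_cophenetic(dm.data)
            np.testing.assert_allclose(tree.cophenetic_matrix().data, want,
                                       atol=1e-10)


class TestCophenetic:
    def test_ultrametric_input_has_correlation_one(self):
        dm = dm3()
        assert cophenetic_correlation(dm, upgma(dm)) == pytest.approx(1.0)

    def test_matrix_equal_to_own_cophenetic_matrix(self):
        dm = dm3()
        coph = upgma(dm).cophenetic_matrix()
        assert cophenetic_correlation(coph, upgma(coph)) == pytest.approx(1.0)

    def test_correlation_decreases_with_perturbation(self):
        rng = np.random.default_rng(14)
        base = upgma(random_dm(rng, 8)).cophenetic_matrix()
        noise = rng.normal(0, 1, base.data.shape)
        noise = np.abs(noise + noise.T)
        np.fill_diagonal(noise, 0)
        corrs = []
        for eps in (0.0, 0.05, 0.25):
            data = base.data + eps * noise
            dm = DistanceMatrix((data + data.T) / 2, ids=base.ids)
            corrs.append(cophenetic_correlation(dm, upgma(dm)))
        assert corrs[0] == pytest.approx(1.0)
        assert corrs[0] >= corrs[1] >= corrs[2]

    def test_undefined_below_three_samples(self):
        dm = DistanceMatrix(np.array([[0, 0.4], [0.4, 0]]), ids=["A", "B"])
        with pytest.raises(ValueError):
            cophenetic_correlation(dm, upgma(dm))

    def test_matches_direct_pearson_oracle(self):
        rng = np.random.default_rng(77)
        dm = random_dm(rng, 7)
        tree = upgma(dm)
        got = cophenetic_correlation(dm, tree)
        want = oracles.pearson(dm.condensed_form(),
                               tree.cophenetic_matrix().condensed_form())
        assert got == pytest.approx(want)


class TestCutTree:
    def test_below_all_merges_gives_singletons(self):
        labels = cut_tree(upgma(dm3()), 0.1)
        assert labels.nunique() == 3

    def test_at_root_gives_one_cluster(self):
        labels = cut_tree(upgma(dm3()), 0.6)
        assert labels.nunique() == 1

    def test_three_leaf_example_at_intermediate_height(self):
        labels = cut_tree(upgma(dm3()), 0.3)
        assert labels["A"] == labels["B"] != labels["C"]

    def test_newick_export_preserves_cophenetic_distances(self):
        import io
        from skbio import TreeNode

        tree = upgma(dm3())
        parsed = TreeNode.read(io.StringIO(to_newick(tree)))
        tips = {t.name: t for t in parsed.tips()}
        assert tips["A"].distance(tips["B"]) == pytest.approx(0.2)
        assert tips["A"].distance(tips["C"]) == pytest.approx(0.6)


class TestKruskalWallis:
    def test_symmetric_ranks_give_zero(self):
        h, _ = kruskal_wallis([1, 2, 1, 2], ["a", "a", "b", "b"])
        assert h == pytest.approx(0.0)

    def test_hand_computed_h_and_p(self):
        # ranks 1..6, R1=6, R2=15: H = 12/42*(12+75) - 21 = 3.857
        h, p = kruskal_wallis([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert h == pytest.approx(3.857, abs=5e-4)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_groups_give_zero(self):
        h, p = kruskal_wallis([5, 5, 5, 5, 5, 5], list("aabbcc"))
        assert h == 0.0 and p == 1.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3], ["a", "a", "a"])

    def test_group_concentrated_abundance_is_detected(self, matrix, study):
        # a taxon planted only in the lactate pool must separate carbons
        meta = study.metadata.set_index("sample_id")
        carbon = meta.loc[matrix.abundance.index, "carbon"]
        h, p = kruskal_wallis(matrix.abundance["Desulfovibrio"].to_numpy(),
                              carbon.to_numpy())
        assert p < 0.05
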