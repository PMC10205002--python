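import numpy as np
import pytest
from oracles import bm_cov_by_edge_enumeration, star_newick

from glandcov import (
    Tree,
    bm_covariance,
    gls_mean,
    prune_to,
    read_newick,
    simulate_tree,
    whitener,
)
from glandcov.errors import (
    AlignmentError,
    ConditioningError,
    DuplicateTipLabelError,
    MissingBranchLengthError,
    MissingTaxonError,
    NewickParseError,
)


class TestReadNewick:
    def test_literal_readback(self, three_tip_tree):
        assert set(three_tip_tree.tips) == {"A", "B", "C"}
        d = three_tip_tree.root_to_tip_distances()
        assert np.allclose(d.to_numpy(), 2.0)

    def test_two_tip_tree(self):
        t = Tree.from_newick("(A:1,B:1);")
        assert t.n_tips == 2

    def test_file_roundtrip(self, tmp_path, three_tip_tree):
        p = tmp_path / "t.nwk"
        p.write_text("((A:1,B:1):1,C:2);\n")
        assert read_newick(p).tips == three_tip_tree.tips

    @pytest.mark.parametrize(
        "newick,err",
        [
            ("((A:1,A:1):1,C:2);", DuplicateTipLabelError),
            ("((A:1,B):1,C:2);", MissingBranchLengthError),
            ("not a tree((", NewickParseError),
            ("(A:1);", NewickParseError),  # fewer than 2 tips
        ],
    )
    def test_invalid_inputs(self, newick, err):
        with pytest.raises(err):
            Tree.from_newick(newick)


class TestPrune:
    def test_path_additivity(self, three_tip_tree):
        sub = prune_to(three_tip_tree, {"A", "C"})
        D = sub.tip_distance_matrix()
        assert D.loc["A", "C"] == pytest.approx(4.0)

    def test_prune_to_all_is_identity(self, three_tip_tree):
        sub = prune_to(three_tip_tree, set(three_tip_tree.tips))
        assert sub.tip_distance_matrix().loc[three_tip_tree.tips, three_tip_tree.tips].equals(
            three_tip_tree.tip_distance_matrix()
        )

    def test_pruned_distances_equal_original_submatrix(self):
        tree = simulate_tree(10, seed=3)
        keep = list(np.random.default_rng(0).choice(tree.tips, 5, replace=False))
        D_full = tree.tip_distance_matrix().loc[keep, keep]
        D_sub = prune_to(tree, keep).tip_distance_matrix().loc[keep, keep]
        assert np.allclose(D_full.to_numpy(), D_sub.to_numpy())

    def test_missing_taxon_lists_offenders(self, three_tip_tree):
        with pytest.raises(MissingTaxonError, match="Z"):
            prune_to(three_tip_tree, {"A", "Z"})


class TestBMCovariance:
    def test_forced_three_tip_values(self, three_tip_tree):
        cov = bm_covariance(three_tip_tree, ["A", "B", "C"])
        assert np.allclose(cov.C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_scaled_identity(self):
        t = Tree.from_newick(star_newick(list("abcd"), t=2.5))
        assert np.allclose(bm_covariance(t).C, 2.5 * np.eye(4))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_edge_enumeration_oracle(self, seed):
        tree = simulate_tree(8, seed=seed)
        assert np.allclose(bm_covariance(tree).C, bm_cov_by_edge_enumeration(tree))

    def test_order_permutes_rows(self, three_tip_tree):
        c1 = bm_covariance(three_tip_tree, ["A", "B", "C"]).C
        c2 = bm_covariance(three_tip_tree, ["C", "A", "B"]).C
        assert c2[1, 2] == c1[0, 1] and c2[0, 0] == c1[2, 2]

    def test_bad_order_raises(self, three_tip_tree):
        with pytest.raises(AlignmentError):
            bm_covariance(three_tip_tree, ["A", "B", "X"])

    def test_psd_and_ultrametric_diag_on_random_trees(self):
        for seed in range(20):
            tree = simulate_tree(7, seed=100 + seed)
            C = bm_covariance(tree).C
            w = np.linalg.eigvalsh(C)
            assert w.min() > 0  # positive terminal branches -> PD
            assert np.allclose(np.diag(C), np.diag(C)[0])  # Yule trees are ultrametric

    def test_non_ultrametric_accepted(self):
        C = bm_covariance(Tree.from_newick("((A:1,B:3):1,C:0.5);")).C
        assert not np.allclose(np.diag(C), np.diag(C)[0])


class TestWhitener:
    def test_identity_cases(self):
        assert np.allclose(whitener(np.eye(3)), np.eye(3))
        assert np.allclose(whitener(4 * np.eye(3)), 0.5 * np.eye(3))

    def test_whitens_random_spd(self, rng):
        A = rng.standard_normal((6, 6))
        C = A @ A.T + 6 * np.eye(6)
        E = whitener(C)
        assert np.abs(E @ C @ E.T - np.eye(6)).max() < 1e-10
        assert np.allclose(E, E.T)

    def test_whitens_tree_covariances(self):
        for seed in range(5):
            C = bm_covariance(simulate_tree(10, seed=seed)).C
            E = whitener(C)
            assert np.abs(E @ C @ E.T - np.eye(10)).max() < 1e-10

    def test_singular_raises(self):
        C = np.ones((3, 3))
        with pytest.raises(ConditioningError):
            whitener(C)


class TestGLSMean:
    def test_identity_cov_gives_arithmetic_mean(self, rng):
        Y = rng.standard_normal((9, 3))
        assert np.allclose(gls_mean(np.eye(9), Y), Y.mean(axis=0))

    def test_constant_column_invariant_to_cov(self):
        C = bm_covariance(simulate_tree(6, seed=1)).C
        Y = np.full((6, 2), 3.7)
        assert np.allclose(gls_mean(C, Y), 3.7)

    def test_matches_explicit_inverse_formula(self, rng):
        C = bm_covariance(simulate_tree(7, seed=9)).C
        Y = rng.standard_normal((7, 4))
        Ci = np.linalg.inv(C)
        ones = np.ones(7)
        expected = (ones @ Ci @ Y) / (ones @ Ci @ ones)
        assert np.allclose(gls_mean(C, Y), expected)
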