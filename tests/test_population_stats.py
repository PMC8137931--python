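"""Welch ANOVA + letters, environmental regressions, PCA, UPGMA clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hydrotime as ht


def hand_welch_F(groups):
    """Textbook Welch statistic, computed independently of the package."""
    k = len(groups)
    w = {g: len(v) / np.var(v, ddof=1) for g, v in groups.items()}
    W = sum(w.values())
    xw = sum(w[g] * np.mean(v) for g, v in groups.items()) / W
    num = sum(w[g] * (np.mean(v) - xw) ** 2 for g, v in groups.items()) / (k - 1)
    lam = 3 * sum((1 - w[g] / W) ** 2 / (len(v) - 1) for g, v in groups.items()) / (
        k * k - 1
    )
    return num / (1 + 2 * (k - 2) / 3 * lam)


class TestWelchAnova:
    def test_identical_groups(self):
        res = ht.welch_anova({"a": [1, 2, 3, 4], "b": [1.0, 2.0, 3.0, 4.0]})
        assert res.F == 0.0
        assert res.p == 1.0
        assert res.letters["a"] == res.letters["b"]

    def test_clearly_separated_groups(self):
        groups = {"a": [0, 0.1, -0.1, 0], "b": [5, 5.1, 4.9, 5]}
        res = ht.welch_anova(groups)
        assert res.p < 0.001
        assert set(res.letters["a"]) & set(res.letters["b"]) == set()
        assert res.F == pytest.approx(hand_welch_F({k: np.asarray(v, float) for k, v in groups.items()}))

    def test_matches_hand_formula_unbalanced(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 6),
            "b": rng.normal(0.5, 3, 11),
            "c": rng.normal(-0.5, 0.3, 8),
        }
        res = ht.welch_anova(groups, letters=False)
        assert res.F == pytest.approx(hand_welch_F(groups), rel=1e-9)

    def test_zero_variance_group_named(self):
        with pytest.raises(ValueError, match="bad"):
            ht.welch_anova({"ok": [1.0, 2.0, 3.0], "bad": [2.0, 2.0, 2.0]})

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            ht.welch_anova({"a": [1.0], "b": [1.0, 2.0]})

    def test_letters_consistent_with_pairwise(self):
        """Two groups share a letter iff Games-Howell does not reject."""
        rng = np.random.default_rng(7)
        groups = {
            f"g{j}": rng.normal(mu, sd, 8)
            for j, (mu, sd) in enumerate(
                [(0, 1), (0.2, 1), (3, 1), (3.1, 2), (8, 0.5)]
            )
        }
        res = ht.welch_anova(groups)
        for _, row in res.pairwise.iterrows():
            a, b = str(row["A"]), str(row["B"])
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share == (row["pval"] > res.alpha)


class TestRegressEnv:
    def test_exact_line(self):
        reg = ht.regress_env([1, 2, 3, 4], [2, 4, 6, 8])
        assert reg.slope == pytest.approx(2.0)
        assert reg.r2 == pytest.approx(1.0)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        reg = ht.regress_env(x, y)
        assert reg.r2 == pytest.approx(stats.pearsonr(x, y)[0] ** 2, rel=1e-12)

    def test_seed_weight_vs_psi_b50(self):
        """Published thousand-seed weights against published psi_b50: a weak,
        well-defined association (r2 = squared correlation, in [0, 1])."""
        t1, t2 = ht.load_fixture("table1"), ht.load_fixture("table2")
        reg = ht.regress_env(
            t1["thousand_seed_weight_g"], t2.loc[t1.index, "psi_b50_MPa"]
        )
        assert 0.0 <= reg.r2 <= 1.0
        r = stats.pearsonr(t1["thousand_seed_weight_g"], t2.loc[t1.index, "psi_b50_MPa"])[0]
        assert reg.r2 == pytest.approx(r**2, rel=1e-12)

    def test_too_few_or_constant_x(self):
        with pytest.raises(ValueError):
            ht.regress_env([1, 2], [3, 4])
        with pytest.raises(ValueError):
            ht.regress_env([1, 1, 1], [3, 4, 5])


class TestPCA:
    def test_perfectly_correlated_pair(self):
        df = pd.DataFrame({"u": [1.0, 2, 3, 4], "v": [2.0, 4, 6, 8]})
        res = ht.pca_env(df)
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)
        assert res.proportion[0] == pytest.approx(1.0)

    def test_eigenvalues_sum_to_variable_count(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        res = ht.pca_env(df)
        assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)
        assert res.proportion.sum() == pytest.approx(1.0)

    def test_independent_variables_give_flat_spectrum(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(4000, 5)))
        res = ht.pca_env(df)
        assert np.all(np.abs(res.eigenvalues - 1.0) < 0.12)

    def test_missing_values_listed(self):
        df = pd.DataFrame({"u": [1.0, np.nan, 3, 5], "v": [2.0, 4, 6, 1]})
        with pytest.raises(ValueError, match="u"):
            ht.pca_env(df)

    def test_scores_reproduce_standardized_data(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        res = ht.pca_env(df)
        z = (df - df.mean()) / df.std(ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, z.to_numpy())


class TestClustering:
    def test_close_pair_merges_first(self):
        m = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]], index=["A", "B", "C"]
        )
        res = ht.hcluster_average(m, standardize=False)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_hand_computed_upgma_heights(self):
        """A=(0,0), B=(0,1), C=(4,0): merge {A,B} at 1, then at mean(4, sqrt 17)."""
        m = pd.DataFrame(
            [[0.0, 0.0], [0.0, 1.0], [4.0, 0.0]],
            index=["A", "B", "C"], columns=["x", "y"],
        )
        res = ht.hcluster_average(m, standardize=False)
        assert res.linkage[0, 2] == pytest.approx(1.0)
        assert res.linkage[1, 2] == pytest.approx((4.0 + np.sqrt(17.0)) / 2, abs=1e-6)
        assert res.newick.endswith(";")
        assert {"A", "B", "C"} <= set(res.labels)

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(21)
        m = pd.DataFrame(rng.normal(size=(12, 4)), index=[f"p{i}" for i in range(12)])
        res = ht.hcluster_average(m)
        assert np.all(np.diff(res.merge_heights) >= -1e-12)

    def test_newick_parses_and_is_ultrametric(self):
        """Branch lengths encode merge heights: root-to-leaf distances are equal."""
        import io as _io

        from Bio import Phylo

        rng = np.random.default_rng(22)
        m = pd.DataFrame(rng.normal(size=(6, 3)), index=list("abcdef"))
        res = ht.hcluster_average(m)
        tree = Phylo.read(_io.StringIO(res.newick), "newick")
        depths = tree.depths()
        leaf_depths = [d for t, d in depths.items() if t.is_terminal()]
        assert np.allclose(leaf_depths, res.merge_heights[-1], atol=1e-9)
        assert sorted(t.name for t in tree.get_terminals()) == list("abcdef")

    def test_duplicate_labels_rejected(self):
        m = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "A"])
        with pytest.raises(ValueError, match="duplicate"):
            ht.hcluster_average(m)

    def test_categoricals_enter_as_one_hot(self):
        m = pd.DataFrame({"x": [0.0, 0.1, 5.0, 5.1]}, index=list("abcd"))
        cat = pd.DataFrame({"soil": ["s1", "s1", "s2", "s2"]}, index=list("abcd"))
        res = ht.hcluster_average(m, categorical=cat)
        first_two = set(res.linkage[:2, :2].astype(int).ravel())
        assert first_two <= {0, 1, 2, 3, 4, 5}
        # a/b and c/d are the two tight pairs both in x and in soil class
        assert set(res.linkage[0, :2].astype(int)) in ({0, 1}, {2, 3})


class TestCompactLetterDisplay:
    def test_chain_structure(self):
        """a~b and b~c not different, a vs c different: b shares letters with both."""
        nd = {("a", "b"): True, ("b", "c"): True, ("a", "c"): False}
        letters = ht.compact_letter_display(["a", "b", "c"], nd)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_all_different(self):
        nd = {("a", "b"): False, ("b", "c"): False, ("a", "c"): False}
        letters = ht.compact_letter_display(["a", "b", "c"], nd)
        assert len({letters["a"], letters["b"], letters["c"]}) == 3
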