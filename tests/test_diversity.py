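import numpy as np
import pandas as pd
import pytest
from scipy import stats

import skbio

from dietbiome.diversity import (
    DistanceMatrix,
    beta_distance,
    kruskal_dunn,
    observed_richness,
    pcoa_coordinates,
    permanova_sequential,
    read_tree,
    richness_outlier_filter,
)
from dietbiome.io_formats import AbundanceTable, ValidationError


def _table(rows, ids=None, cols=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = cols or [chr(65 + j) for j in range(rows.shape[1])]
    return AbundanceTable(pd.DataFrame(rows, index=ids, columns=cols))


class TestRichness:
    def test_counts_strictly_positive_features(self):
        t = _table([[50, 50, 0], [0.0001, 0, 0]])
        r = observed_richness(t)
        assert list(r) == [2, 1]

    def test_invariant_to_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, (5, 20)) * (rng.random((5, 20)) > 0.5)
        x[:, 0] += 0.1  # avoid zero-sum rows
        a = observed_richness(_table(x))
        b = observed_richness(_table(x * 0.25))
        assert (a == b).all()


class TestOutlierFilter:
    def test_central_interval_removes_about_5_percent(self):
        rng = np.random.default_rng(1)
        r = pd.Series(rng.normal(250, 40, 1000), index=[f"s{i}" for i in range(1000)])
        kept, removed = richness_outlier_filter(r)
        lo, hi = np.quantile(r, [0.025, 0.975])
        oracle_removed = set(r.index[(r < lo) | (r > hi)])
        assert set(removed) == oracle_removed
        assert 0.03 <= len(removed) / 1000 <= 0.07

    def test_single_extreme_value_removed(self):
        r = pd.Series(
            np.concatenate([np.linspace(200, 300, 99), [900.0]]),
            index=[f"s{i}" for i in range(100)],
        )
        _, removed = richness_outlier_filter(r)
        assert "s99" in removed

    def test_constant_richness_removes_none(self):
        r = pd.Series(5.0, index=[f"s{i}" for i in range(50)])
        kept, removed = richness_outlier_filter(r)
        assert removed == [] and len(kept) == 50

    def test_too_few_samples_skips_filter(self):
        r = pd.Series([1.0, 2.0, 100.0], index=list("abc"))
        kept, removed = richness_outlier_filter(r)
        assert removed == [] and len(kept) == 3


class TestKruskalDunn:
    def test_h_matches_hand_computed_rank_statistic(self):
        groups = np.repeat(["a", "b", "c"], 3)
        values = np.array([1, 2, 3, 10, 11, 12, 20, 21, 22], dtype=float)
        res = kruskal_dunn(values, groups)
        # brute-force rank computation (no ties): H = 12/(N(N+1)) Σ n_i R̄_i² − 3(N+1)
        ranks = stats.rankdata(values)
        h_oracle = 12 / (9 * 10) * sum(
            3 * ranks[groups == g].mean() ** 2 for g in "abc"
        ) - 3 * 10
        assert res.h == pytest.approx(h_oracle, abs=1e-10)

    def test_identical_groups_give_zero_z(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = kruskal_dunn(values, np.repeat(["a", "b"], 3))
        assert res.pairwise["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_dunn_equals_rank_sum_z(self):
        # tie-free data: Dunn z must equal the normal rank-sum statistic
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 15)
        values = np.concatenate([x, y])
        groups = np.array(["x"] * 12 + ["y"] * 15)
        res = kruskal_dunn(values, groups)
        n, n1, n2 = 27, 12, 15
        ranks = stats.rankdata(values)
        z_oracle = (ranks[:12].mean() - ranks[12:].mean()) / np.sqrt(
            n * (n + 1) / 12 * (1 / n1 + 1 / n2)
        )
        assert res.pairwise["z"].iloc[0] == pytest.approx(z_oracle, abs=1e-10)

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(3)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            values = rng.normal(size=45)
            groups = np.repeat(["a", "b", "c"], 15)
            if kruskal_dunn(values, groups).p < 0.05:
                rejections += 1
        assert rejections / n_sim <= 0.075

    def test_small_group_excluded(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 9.0])
        groups = np.array(["a", "a", "b", "b", "c"])
        res = kruskal_dunn(values, groups)
        assert res.n_groups == 2


TOY_NEWICK = "((A:1,B:1):1,C:2);"


class TestBetaDistance:
    def test_identical_samples_distance_zero(self):
        t = _table([[50, 30, 20], [50, 30, 20]])
        for metric in ("bray_curtis", "aitchison"):
            dm = beta_distance(t, metric)
            assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-9)
        dm = beta_distance(t, "unifrac_unweighted", tree=read_tree(TOY_NEWICK))
        assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_unifrac_toy_tree_hand_enumerated(self):
        # branches: A=1, B=1, internal(AB)=1, C=2
        tree = read_tree(TOY_NEWICK)
        t = _table([[100, 0, 0], [0, 0, 100], [50, 50, 0], [50, 0, 50]])
        dm = beta_distance(t, "unifrac_unweighted", tree=tree).frame
        # disjoint single leaves through the root: all branches unique
        assert dm.loc["s0", "s1"] == pytest.approx(1.0, abs=1e-12)
        # {A,B} vs {A,C}: unique B(1)+C(2) over union A+B+internal+C = 3/5
        assert dm.loc["s2", "s3"] == pytest.approx(0.6, abs=1e-12)

    def test_unifrac_bounds_and_symmetry(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (6, 3)) * (rng.random((6, 3)) > 0.3)
        x[:, 0] += 0.05
        dm = beta_distance(_table(x), "unifrac_unweighted", tree=read_tree(TOY_NEWICK))
        assert (dm.matrix >= 0).all() and (dm.matrix <= 1 + 1e-12).all()
        assert np.abs(dm.matrix - dm.matrix.T).max() <= 1e-12

    def test_missing_tree_or_leaf_errors(self):
        t = _table([[50, 50]], cols=["A", "Zmissing"])
        with pytest.raises(ValidationError):
            beta_distance(t, "unifrac_unweighted")
        with pytest.raises(ValidationError):
            beta_distance(t, "unifrac_unweighted", tree=read_tree(TOY_NEWICK))

    def test_zero_sum_sample_rejected(self):
        t = _table([[50, 50, 0], [1e-9, 0, 0]])
        t.data.iloc[1] = 0.0
        with pytest.raises(ValidationError):
            beta_distance(t, "bray_curtis")

    def test_bray_curtis_matches_skbio_directly(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, (5, 8))
        dm = beta_distance(_table(x), "bray_curtis")
        ref = skbio.diversity.beta_diversity("braycurtis", x).data
        np.testing.assert_allclose(dm.matrix, ref, atol=1e-12)


class TestPermanova:
    def _clustered(self, sep=8.0, n=20, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, (n, 4))
        b = rng.normal(sep, 1, (n, 4))
        X = np.vstack([a, b])
        ids = [f"s{i}" for i in range(2 * n)]
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(ids, squareform(pdist(X)))
        terms = pd.DataFrame({"grp": ["a"] * n + ["b"] * n}, index=ids)
        return dm, terms

    def test_separated_clusters_reach_minimum_p(self):
        dm, terms = self._clustered()
        res = permanova_sequential(dm, terms, n_perm=999, seed=1)
        assert res.p("grp") == pytest.approx(1.0 / 1000.0)

    def test_r2_partition_sums_to_one(self, small_sim):
        _, table, metadata, _, _ = small_sim
        ids = list(metadata.data.index[metadata.data["cohort"] == "C1"][:80])
        dm = beta_distance(table.subset_samples(ids), "bray_curtis")
        terms = metadata.subset(ids).data[["sex", "age", "bmi", "diet"]]
        res = permanova_sequential(dm, terms, n_perm=99, seed=0)
        assert res.terms["R2"].drop("Total").sum() == pytest.approx(1.0, abs=1e-9)
        assert (res.terms["R2"].drop(["Total"]) >= -1e-12).all()

    def test_single_term_f_matches_skbio_permanova(self):
        dm, terms = self._clustered(sep=2.0, n=15, seed=3)
        res = permanova_sequential(dm, terms, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.matrix, ids=dm.sample_ids),
            grouping=terms["grp"].to_numpy(),
            permutations=0,
        )
        assert res.terms.loc["grp", "F"] == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(7)
        from scipy.spatial.distance import pdist, squareform

        rejections = 0
        n_sim = 150
        for _ in range(n_sim):
            X = rng.normal(size=(24, 3))
            ids = [f"s{i}" for i in range(24)]
            dm = DistanceMatrix(ids, squareform(pdist(X)))
            terms = pd.DataFrame({"grp": rng.permutation(["a"] * 12 + ["b"] * 12)}, index=ids)
            p = permanova_sequential(dm, terms, n_perm=99, seed=int(rng.integers(1 << 30))).p("grp")
            rejections += p <= 0.05
        assert 0.01 <= rejections / n_sim <= 0.10

    def test_singular_term_rejected(self):
        dm, terms = self._clustered(n=10)
        terms["dup"] = terms["grp"]
        with pytest.raises(ValidationError):
            permanova_sequential(dm, terms, n_perm=9, seed=0)

    def test_pcoa_exportable(self):
        dm, _ = self._clustered(n=10)
        coords = pcoa_coordinates(dm)
        assert list(coords.columns) == ["PCo1", "PCo2"]
        assert len(coords) == 20
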