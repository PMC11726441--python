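import numpy as np
import pandas as pd
import pytest

from dietbiome.io_formats import SampleMetadata, ValidationError
from dietbiome.ml_validation import (
    RFSpec,
    assert_no_leakage,
    average_roc,
    fit_predict_auc,
    make_splits,
    predict_presence_from_ffq,
    run_diet_classification,
)

FAST_RF = RFSpec(n_trees=30)


class TestRFSpec:
    def test_features_per_split_rule(self):
        assert RFSpec().max_features(200) == 20
        assert RFSpec().max_features(3) == 1  # floor at 1 after rounding


class TestMakeSplits:
    def test_lodo_yields_one_split_per_cohort(self, small_sim):
        _, _, metadata, _, _ = small_sim
        splits = make_splits(metadata, "lodo", ("omnivore", "vegan"))
        assert len(splits) == 3
        assert_no_leakage(splits)
        cohorts = metadata.data["cohort"]
        for train, test in splits:
            assert cohorts.loc[test].nunique() == 1
            assert cohorts.loc[train].nunique() == 2

    def test_cross_lodo_train_size_bookkeeping(self, small_sim):
        _, _, metadata, _, _ = small_sim
        pair = ("omnivore", "vegan")
        in_pair = metadata.data[metadata.data["diet"].isin(pair)]
        n_target = int((in_pair["cohort"] == "C1").sum())
        n_other = int((in_pair["cohort"] != "C1").sum())
        splits = make_splits(metadata, "cross_lodo", pair, target_cohort="C1",
                             n_repeats=1, n_folds=5, seed=0)
        for train, test in splits:
            assert len(train) + len(test) == n_target + n_other
            assert len(test) == pytest.approx(n_target / 5, abs=2)
        tgt_ids = metadata.data.index[metadata.data["cohort"] == "C1"]
        assert_no_leakage(splits, tgt_ids)

    def test_no_split_shares_ids(self, small_sim):
        _, _, metadata, _, _ = small_sim
        for scheme in ("cv", "cross_lodo"):
            splits = make_splits(metadata, scheme, ("omnivore", "vegetarian"),
                                 target_cohort="C2", n_repeats=2, n_folds=4, seed=1)
            for train, test in splits:
                assert not set(train) & set(test)

    def test_fold_reduction_for_small_minority(self, small_sim):
        _, _, metadata, _, _ = small_sim
        n_vegan_c1 = int(
            ((metadata.data["cohort"] == "C1") & (metadata.data["diet"] == "vegan")).sum()
        )
        splits = make_splits(metadata, "cv", ("omnivore", "vegan"), target_cohort="C1",
                             n_repeats=1, n_folds=50, seed=0)
        assert len(splits) == min(50, n_vegan_c1)

    def test_identical_seeds_reproduce_splits(self, small_sim):
        _, _, metadata, _, _ = small_sim
        a = make_splits(metadata, "cross_lodo", ("omnivore", "vegan"),
                        target_cohort="C1", n_repeats=2, n_folds=3, seed=5)
        b = make_splits(metadata, "cross_lodo", ("omnivore", "vegan"),
                        target_cohort="C1", n_repeats=2, n_folds=3, seed=5)
        assert a == b


class TestFitPredictAuc:
    def _toy(self, separable: bool, n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2),
                      index=[f"s{i}" for i in range(n)])
        if separable:
            x = np.where(y == "b", 5.0, 0.0)[:, None] + rng.normal(0, 0.1, (n, 1))
        else:
            x = np.ones((n, 1))
        X = pd.DataFrame(x, index=y.index, columns=["f"])
        ids = list(y.index)
        # held-out quarter from each class so the test set has both labels
        test = ids[: n // 8] + ids[n // 2 : n // 2 + n // 8]
        train = [s for s in ids if s not in set(test)]
        return train, test, X, y

    def test_perfectly_separating_feature_gives_auc_one(self):
        train, test, X, y = self._toy(separable=True)
        auc, _, _ = fit_predict_auc(train, test, X, y, FAST_RF)
        assert auc == pytest.approx(1.0)

    def test_constant_features_give_chance_auc(self):
        train, test, X, y = self._toy(separable=False)
        auc, _, _ = fit_predict_auc(train, test, X, y, FAST_RF)
        assert auc == pytest.approx(0.5, abs=1e-9)

    def test_single_class_test_set_skipped(self):
        train, _, X, y = self._toy(separable=True)
        only_a = [s for s in y.index if y[s] == "a"][:5]
        assert fit_predict_auc(train, only_a, X, y, FAST_RF) is None


class TestAverageRoc:
    def test_identical_curves_zero_width_band(self):
        curve = (np.array([0.0, 0.5, 1.0]), np.array([0.0, 0.8, 1.0]))
        grid, mean, lo, hi = average_roc([curve] * 5)
        np.testing.assert_allclose(lo, hi, atol=1e-12)
        assert mean[0] == pytest.approx(0.0) and mean[-1] == pytest.approx(1.0)

    def test_band_shrinks_with_more_tests(self):
        rng = np.random.default_rng(0)
        def noisy():
            t = np.sort(np.concatenate([[0, 1], rng.uniform(size=5)]))
            return (t, np.clip(t + rng.normal(0, 0.05, t.size), 0, 1))
        w = {}
        for n in (8, 64):
            _, mean, lo, hi = average_roc([noisy() for _ in range(n)], seed=1)
            w[n] = np.mean(hi - lo)
        # bootstrap-t width should scale roughly as 1/sqrt(n): ratio ~ 2.8
        assert 1.8 <= w[8] / w[64] <= 4.5

    def test_single_test_has_no_band(self):
        grid, mean, lo, hi = average_roc([(np.array([0.0, 1.0]), np.array([0.0, 1.0]))])
        assert lo is None and hi is None


class TestDietClassification:
    def test_planted_signal_recovered_cross_lodo(self, small_sim):
        _, table, metadata, _, _ = small_sim
        res = run_diet_classification(
            table, metadata, ("omnivore", "vegan"), scheme="cross_lodo",
            rf=FAST_RF, n_repeats=2, n_folds=3, seed=0,
        )
        assert res.mean_auc >= 0.85

    def test_determinism_bit_for_bit(self, small_sim):
        _, table, metadata, _, _ = small_sim
        kw = dict(scheme="cv", rf=FAST_RF, n_repeats=1, n_folds=3, seed=3)
        a = run_diet_classification(table, metadata, ("omnivore", "vegetarian"), **kw)
        b = run_diet_classification(table, metadata, ("omnivore", "vegetarian"), **kw)
        assert a.all_aucs == b.all_aucs
        for c in a.per_cohort:
            np.testing.assert_array_equal(a.per_cohort[c].roc_mean, b.per_cohort[c].roc_mean)

    def test_lodo_scheme_runs(self, small_sim):
        _, table, metadata, _, _ = small_sim
        res = run_diet_classification(
            table, metadata, ("omnivore", "vegan"), scheme="lodo", rf=FAST_RF, seed=0
        )
        assert set(res.per_cohort) == {"C1", "C2", "C3"}
        assert all(len(r.aucs) == 1 for r in res.per_cohort.values())

    def test_covariate_variant_runs(self, small_sim):
        _, table, metadata, _, _ = small_sim
        res = run_diet_classification(
            table, metadata, ("omnivore", "vegan"), scheme="lodo", rf=FAST_RF,
            with_covariates=True, seed=0,
        )
        assert 0.0 <= res.mean_auc <= 1.0


class TestPresenceFromFFQ:
    def test_coupled_features_predictable_and_window_enforced(self, small_sim):
        _, table, metadata, ffq, truth = small_sim
        food_feats = list(truth["food_features"])
        prev = (table.data > 0).mean()
        in_window = [f for f in food_feats if 0.10 <= prev[f] <= 0.90]
        if not in_window:
            pytest.skip("no coupled feature inside the prevalence window at this seed")
        res = predict_presence_from_ffq(
            table, ffq, metadata, rf=FAST_RF, n_repeats=1, n_folds=3, seed=0,
            features=in_window,
        )
        assert res["auc"].mean() > 0.6

    def test_feature_at_extreme_prevalence_excluded(self, small_sim):
        from dietbiome.io_formats import AbundanceTable

        _, table, metadata, ffq, _ = small_sim
        # plant a 95%-prevalence feature: outside the [0.10, 0.90] window
        rng = np.random.default_rng(0)
        data = table.data * 0.5
        data["ubiq"] = np.where(rng.random(len(data)) < 0.95, 1.0, 0.0)
        res = predict_presence_from_ffq(
            AbundanceTable(data), ffq, metadata, rf=FAST_RF,
            n_repeats=1, n_folds=3, seed=0, features=["ubiq"],
        )
        assert res.empty
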