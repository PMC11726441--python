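import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietbiome.food_overlap import (
    call_food_sgbs,
    compare_health_ranks,
    dunn_contrasts_food,
    per_sample_food_stats,
    presence_table,
    prevalence_chisq,
)
from dietbiome.io_formats import AbundanceTable, FoodCatalogTable, ValidationError
from dietbiome.synthetic_data import simulate_food_catalog, simulate_health_ranks


def _catalog(rows):
    df = pd.DataFrame(rows).set_index("feature_id")
    return FoodCatalogTable(df)


class TestCallFoodSGBs:
    def test_threshold_rules_exactly_as_printed(self):
        cat = _catalog(
            [
                # detected in 5 samples, 20% dairy prevalence -> dairy signature
                {"feature_id": "f1", "n_food_samples_detected": 5,
                 "prevalence_meat": 0.0, "prevalence_dairy": 0.2,
                 "prevalence_fruits_vegetables": 0.0},
                # only 3 samples -> not a food SGB (>=4 rule)
                {"feature_id": "f2", "n_food_samples_detected": 3,
                 "prevalence_meat": 0.5, "prevalence_dairy": 0.5,
                 "prevalence_fruits_vegetables": 0.5},
                # called, but prevalence exactly at 0.001 -> strict > excludes
                {"feature_id": "f3", "n_food_samples_detected": 10,
                 "prevalence_meat": 0.001, "prevalence_dairy": 0.0,
                 "prevalence_fruits_vegetables": 0.0},
                # boundary count 4 is inclusive
                {"feature_id": "f4", "n_food_samples_detected": 4,
                 "prevalence_meat": 0.3, "prevalence_dairy": 0.0,
                 "prevalence_fruits_vegetables": 0.0},
            ]
        )
        called = call_food_sgbs(cat)
        assert set(called.food_features) == {"f1", "f3", "f4"}
        assert called.signatures["dairy"] == ["f1"]
        assert called.signatures["meat"] == ["f4"]  # f3 excluded by strict >

    def test_monotone_in_thresholds(self):
        cfg_rows = [
            {"feature_id": f"f{i}", "n_food_samples_detected": i,
             "prevalence_meat": i / 20, "prevalence_dairy": 0.0,
             "prevalence_fruits_vegetables": 0.0}
            for i in range(12)
        ]
        cat = _catalog(cfg_rows)
        loose = set(call_food_sgbs(cat, min_samples=4).food_features)
        tight = set(call_food_sgbs(cat, min_samples=8).food_features)
        assert tight <= loose


class TestPerSampleStats:
    def _setup(self):
        table = AbundanceTable(
            pd.DataFrame(
                [[1.0, 2.0, 97.0], [0.0, 0.0, 100.0]],
                index=["s1", "s2"], columns=["f1", "f2", "f3"],
            )
        )
        cat = call_food_sgbs(
            _catalog(
                [
                    {"feature_id": "f1", "n_food_samples_detected": 6,
                     "prevalence_meat": 0.2, "prevalence_dairy": 0.0,
                     "prevalence_fruits_vegetables": 0.0},
                    {"feature_id": "f2", "n_food_samples_detected": 9,
                     "prevalence_meat": 0.0, "prevalence_dairy": 0.4,
                     "prevalence_fruits_vegetables": 0.0},
                    {"feature_id": "f3", "n_food_samples_detected": 0,
                     "prevalence_meat": 0.0, "prevalence_dairy": 0.0,
                     "prevalence_fruits_vegetables": 0.0},
                ]
            )
        )
        return table, cat

    def test_counts_and_cumulative(self):
        table, cat = self._setup()
        out = per_sample_food_stats(table, food_catalog=cat)
        assert out.loc["s1", "n_food_features"] == 2
        assert out.loc["s1", "cumulative_abundance"] == pytest.approx(3.0)
        # food-free sample retained as zero
        assert out.loc["s2", "n_food_features"] == 0
        assert out.loc["s2", "cumulative_abundance"] == pytest.approx(0.0)

    def test_count_invariant_to_rescaling_but_cumulative_not(self):
        table, cat = self._setup()
        scaled = AbundanceTable(table.data * 0.5)
        a = per_sample_food_stats(table, food_catalog=cat)
        b = per_sample_food_stats(scaled, food_catalog=cat)
        assert (a["n_food_features"] == b["n_food_features"]).all()
        assert b.loc["s1", "cumulative_abundance"] == pytest.approx(1.5)

    def test_cumulative_bounded_by_total(self):
        table, cat = self._setup()
        out = per_sample_food_stats(table, food_catalog=cat)
        assert (out["cumulative_abundance"] <= 100.0 + 1e-9).all()

    def test_signature_stratified_long_format(self):
        table, cat = self._setup()
        out = per_sample_food_stats(table, food_catalog=cat, group_by_signature=True)
        assert set(out["category"]) == {"meat", "dairy", "fruits_vegetables"}


class TestPrevalenceChisq:
    def test_equal_prevalence_gives_large_p(self):
        tab = np.array([[50, 50], [50, 50], [50, 50]])
        _, p = prevalence_chisq(tab, n_mc=999, seed=0)
        assert p > 0.5

    def test_extreme_table_hits_floor(self):
        tab = np.array([[100, 0], [0, 100], [50, 50]])
        _, p = prevalence_chisq(tab, n_mc=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_matches_asymptotic_chi2_on_large_tables(self):
        tab = np.array([[400, 600], [450, 550], [380, 620]])
        chi2, p_mc = prevalence_chisq(tab, n_mc=19_999, seed=1)
        ref = stats.chi2_contingency(tab, correction=False)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
        assert p_mc == pytest.approx(ref.pvalue, abs=0.02)

    def test_fixed_seed_reproducible_and_bounded(self):
        tab = np.array([[30, 20], [25, 25], [10, 40]])
        r1 = prevalence_chisq(tab, n_mc=999, seed=5)
        r2 = prevalence_chisq(tab, n_mc=999, seed=5)
        assert r1 == r2
        assert 1.0 / 1000.0 <= r1[1] <= 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            prevalence_chisq(np.array([[0, 0], [5, 5]]))


class TestHealthRanks:
    def test_identical_sets_give_null_result(self):
        ranks = pd.Series({"a": 0.2, "b": 0.5, "c": 0.8})
        res = compare_health_ranks(["a", "b", "c"], ["a", "b", "c"], ranks)
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.df == 4

    def test_separated_rank_distributions_detected(self):
        # analogue of favourable (~0.35) vs unfavourable (~0.55) signatures
        rng = np.random.default_rng(0)
        ranks = pd.Series(
            np.concatenate([
                np.clip(rng.normal(0.35, 0.1, 100), 0, 1),
                np.clip(rng.normal(0.55, 0.1, 100), 0, 1),
            ]),
            index=[f"g{i}" for i in range(200)],
        )
        res = compare_health_ranks(ranks.index[:100], ranks.index[100:], ranks)
        assert res.p < 0.001
        assert res.mean_a < res.mean_b
        assert res.levene_p > 0.05

    def test_unranked_features_dropped(self):
        ranks = pd.Series({"a": 0.1, "b": 0.2, "c": 0.8, "d": 0.9})
        res = compare_health_ranks(["a", "b", "zzz"], ["c", "d"], ranks)
        assert res.n_a == 2 and res.n_b == 2


class TestDunnContrasts:
    def test_planted_food_deficit_in_vegans_detected(self, small_sim):
        cfg, table, metadata, _, truth = small_sim
        catalog = call_food_sgbs(simulate_food_catalog(cfg))
        stats_df = per_sample_food_stats(table, metadata, catalog)
        # vegans exclude meat and dairy, omnivores don't; presence coupling
        # makes food features commoner where their foods are eaten
        res = dunn_contrasts_food(stats_df, value="n_food_features")
        assert len(res) == 3  # one stratum per cohort
        for r in res.values():
            assert {"z", "p", "q"} <= set(r.pairwise.columns)

    def test_single_diet_stratum_skipped(self, small_sim):
        cfg, table, metadata, _, _ = small_sim
        catalog = call_food_sgbs(simulate_food_catalog(cfg))
        stats_df = per_sample_food_stats(table, metadata, catalog)
        stats_df = stats_df[stats_df["diet"] == "omnivore"]
        assert dunn_contrasts_food(stats_df) == {}


def test_presence_table_shapes(small_sim):
    _, table, metadata, _, _ = small_sim
    tab = presence_table(table, metadata, table.feature_ids[0])
    assert list(tab.columns) == ["present", "absent"]
    assert tab.to_numpy().sum() == len(table.sample_ids)
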