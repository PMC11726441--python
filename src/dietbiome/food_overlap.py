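"""Food-derived microbes in gut metagenomes.

Calls food SGBs from a catalog of food-metagenome summaries (detected at
≥0.1 % relative abundance in ≥4 food samples), labels meat / dairy /
fruits-and-vegetables signatures (strictly >0.1 % prevalence in that food
category), quantifies per-sample counts and cumulative abundance of food
features by diet pattern, tests prevalence differences with a fixed-margin
Monte-Carlo chi-squared, and compares cardiometabolic health-rank
distributions between diet-signature feature sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import KruskalDunnResult, kruskal_dunn
from .io_formats import AbundanceTable, FoodCatalogTable, SampleMetadata, ValidationError, align_samples

logger = logging.getLogger(__name__)


@dataclass
class FoodSGBCatalog:
    """Food-feature calls and per-category signature labels."""

    food_features: list[str]
    signatures: dict[str, list[str]]  # category -> feature ids (subset of calls)
    abundance_threshold: float = 0.1  # percent, baked into the source catalog
    min_samples: int = 4
    signature_prevalence: float = 0.001

    def __post_init__(self) -> None:
        called = set(self.food_features)
        for cat, feats in self.signatures.items():
            extra = set(feats) - called
            if extra:
                raise ValidationError(
                    f"signature features not in the called food set ({cat}): {sorted(extra)[:3]}"
                )

    def category_of(self, feature_id: str) -> list[str]:
        return [c for c, feats in self.signatures.items() if feature_id in feats]


def call_food_sgbs(
    catalog: FoodCatalogTable,
    abundance_threshold: float = 0.1,
    min_samples: int = 4,
    signature_prevalence: float = 0.001,
) -> FoodSGBCatalog:
    """Apply the food-SGB call and signature rules to a catalog.

    A feature is a food SGB when detected (at the catalog's ≥0.1 % abundance
    threshold) in at least ``min_samples`` food samples (inclusive, ≥4); a
    called food SGB is a signature of a category when its prevalence there
    strictly exceeds ``signature_prevalence`` (>0.1 % as a fraction).
    Raising either threshold never adds a food SGB.
    """
    df = catalog.data
    called = df.index[df["n_food_samples_detected"] >= min_samples].tolist()
    signatures = {}
    for cat in catalog.categories:
        prev = df.loc[called, f"prevalence_{cat}"]
        signatures[cat] = prev.index[prev > signature_prevalence].tolist()
    return FoodSGBCatalog(
        food_features=called,
        signatures=signatures,
        abundance_threshold=abundance_threshold,
        min_samples=min_samples,
        signature_prevalence=signature_prevalence,
    )


def per_sample_food_stats(
    table: AbundanceTable,
    metadata: SampleMetadata | None = None,
    food_catalog: FoodSGBCatalog | None = None,
    group_by_signature: bool = False,
) -> pd.DataFrame:
    """Per-sample count of distinct food features present (abundance > 0)
    and their cumulative relative abundance (percent).

    With ``group_by_signature`` the stats are computed per signature
    category (long format with a ``category`` column); samples with no food
    feature are retained as zeros — they feed the zero-inflated downstream
    comparisons.
    """
    if food_catalog is None or not food_catalog.food_features:
        raise ValidationError("food catalog is empty")
    present_feats = [f for f in food_catalog.food_features if f in table.data.columns]

    def _stats(feats: list[str], category: str | None) -> pd.DataFrame:
        sub = table.data[feats] if feats else pd.DataFrame(0.0, index=table.data.index, columns=[])
        out = pd.DataFrame(
            {
                "n_food_features": (sub > 0).sum(axis=1) if feats else 0,
                "cumulative_abundance": sub.sum(axis=1) if feats else 0.0,
            },
            index=table.data.index,
        )
        if category is not None:
            out.insert(0, "category", category)
        return out

    if group_by_signature:
        frames = []
        for cat, feats in food_catalog.signatures.items():
            feats = [f for f in feats if f in table.data.columns]
            frames.append(_stats(feats, cat))
        stats_df = pd.concat(frames)
    else:
        stats_df = _stats(present_feats, None)
    if metadata is not None:
        meta = metadata.data[["cohort", "diet"]]
        stats_df = stats_df.join(meta, how="inner")
    return stats_df


def prevalence_chisq(
    counts: pd.DataFrame | np.ndarray, n_mc: int = 99_999, seed: int | None = None
) -> tuple[float, float]:
    """Pearson chi-squared on a diet × present/absent table with a
    Monte-Carlo p-value under the fixed-margins conditional null.

    p = (1 + #{replicate chi2 >= observed}) / (n_mc + 1); the smallest
    attainable p is 1/(n_mc + 1).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValidationError("counts must be a 2-d table of nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError("zero margin in contingency table")
    expected = np.outer(row, col) / obs.sum()
    chi2_obs = float(((obs - expected) ** 2 / expected).sum())
    rng = np.random.default_rng(seed)
    tables = stats.random_table(row.astype(int), col.astype(int)).rvs(
        size=n_mc, random_state=rng
    )
    chi2_rep = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
    p = (1.0 + float(np.sum(chi2_rep >= chi2_obs - 1e-12))) / (n_mc + 1.0)
    return chi2_obs, p


def presence_table(
    table: AbundanceTable, metadata: SampleMetadata, feature_id: str
) -> pd.DataFrame:
    """Diet × present/absent counts for one feature."""
    present = table.data[feature_id] > 0
    diets = metadata.data.loc[present.index, "diet"]
    return pd.DataFrame(
        {
            "present": present.groupby(diets).sum().astype(int),
            "absent": (~present).groupby(diets).sum().astype(int),
        }
    )


@dataclass
class HealthRankComparison:
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    levene_p: float
    t: float
    df: int
    p: float


def compare_health_ranks(
    features_a, features_b, ranks: pd.Series
) -> HealthRankComparison:
    """Equal-variance two-sample t-test on health ranks of two signature
    sets, with Levene's test reported as the variance check.  Unranked
    features are dropped (logged)."""
    a = ranks.reindex(list(features_a)).dropna().to_numpy(dtype=float)
    b = ranks.reindex(list(features_b)).dropna().to_numpy(dtype=float)
    dropped = (len(list(features_a)) - a.size) + (len(list(features_b)) - b.size)
    if dropped:
        logger.info("%d features without a health rank dropped", dropped)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both sets need >= 2 ranked features")
    lev_p = float(stats.levene(a, b).pvalue) if not (
        np.allclose(a, a[0]) and np.allclose(b, b[0])
    ) else 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if not np.isfinite(t):  # identical constant sets
        t, p = 0.0, 1.0
    return HealthRankComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()), n_a=int(a.size), n_b=int(b.size),
        levene_p=lev_p, t=float(t), df=int(a.size + b.size - 2), p=float(p),
    )


def dunn_contrasts_food(
    stats_df: pd.DataFrame,
    value: str = "n_food_features",
    by: tuple[str, ...] = ("cohort",),
) -> dict[tuple, KruskalDunnResult]:
    """Kruskal–Wallis + Dunn/BH contrasts of a per-sample food statistic
    between diet patterns within each stratum (cohort and, when the stats
    are long-format, signature category).

    Strata with fewer than two diet groups are skipped with a warning.
    """
    if "category" in stats_df.columns and "category" not in by:
        by = tuple(by) + ("category",)
    out: dict[tuple, KruskalDunnResult] = {}
    for key, sub in stats_df.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        if sub["diet"].nunique() < 2:
            logger.warning("stratum %s has a single diet group; skipped", key)
            continue
        try:
            out[key] = kruskal_dunn(sub[value].to_numpy(dtype=float), sub["diet"].to_numpy())
        except ValidationError as exc:
            logger.warning("stratum %s skipped: %s", key, exc)
    return out
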