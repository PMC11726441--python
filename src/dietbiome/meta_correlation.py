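"""Partial Spearman correlations of feature abundance with dietary exposures,
pooled across cohorts on the Fisher-Z scale.

Per cohort, abundance (arcsin-sqrt transformed; Spearman is rank-invariant so
the transform is cosmetic) and the exposure are rank-transformed,
residualized on sex/age/BMI and correlated; per-cohort correlations are
converted to Fisher Z, pooled with the same DerSimonian–Laird machinery as
the differential-abundance stage, back-transformed, and BH-adjusted across
features.

Correlations with a food group are computed only in the diet populations
that consume it: meat in omnivores; dairy in omnivores and vegetarians;
fruits and vegetables in everyone; hPDI within each diet pattern separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceTable, FFQTable, SampleMetadata, ValidationError, align_samples
from .meta_diffabund import DLResult, arcsin_sqrt, bh_adjust, dersimonian_laird

logger = logging.getLogger(__name__)

#: which diet labels consume each food group
ELIGIBLE_DIETS: dict[str, tuple[str, ...]] = {
    "red_meat": ("omnivore",),
    "white_meat": ("omnivore",),
    "fish": ("omnivore",),
    "dairy": ("omnivore", "vegetarian"),
    "fruits": ("omnivore", "vegetarian", "vegan"),
    "vegetables": ("omnivore", "vegetarian", "vegan"),
}


def partial_spearman(x, y, covariates=None) -> float:
    """Spearman correlation of x and y after removing covariate effects.

    All variables — x, y and every covariate column — are rank-transformed
    (average ranks on ties); the ranked x and y are residualized on the
    ranked covariates by least squares and the statistic is the Pearson
    correlation of the residuals.  Ranking the covariates too makes the
    adjustment remove monotone (not just linear) confounding, which is the
    standard Spearman analogue of a partial correlation.  With no
    covariates this is the classical Spearman rho.  Constant input is
    undefined (NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != x.size and C.shape[1] == x.size:
            C = C.T
    k = 0 if C is None else C.shape[1]
    if x.size != y.size or x.size <= k + 3:
        raise ValidationError("need n > n_covariates + 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if C is not None:
        C = np.column_stack([stats.rankdata(C[:, j]) for j in range(C.shape[1])])
        Z = np.column_stack([np.ones(x.size), C])
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return math.nan
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class PooledCorrelation:
    rho: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    i2: float
    k: int


def fisher_pool(
    rhos, ns, k_covariates: int = 0, df_mode: str = "partial"
) -> PooledCorrelation:
    """DerSimonian–Laird pooling of correlations on the Fisher-Z scale.

    z = atanh(rho) with se 1/sqrt(n − 3 − k) under the partial-correlation
    degrees-of-freedom correction (``df_mode='classic'`` reproduces the
    plain 1/sqrt(n − 3)).  The pooled z and its CI are back-transformed with
    tanh, so the CI stays inside (−1, 1).
    """
    rhos = np.asarray(rhos, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (np.abs(rhos) >= 1).any():
        raise ValidationError("correlation of ±1 has infinite Fisher Z")
    kc = k_covariates if df_mode == "partial" else 0
    if df_mode not in ("partial", "classic"):
        raise ValueError(f"unknown df_mode {df_mode!r}")
    if (ns <= kc + 4).any():
        raise ValidationError("effective n too small for Fisher-Z variance")
    z = np.arctanh(rhos)
    var_z = 1.0 / (ns - 3.0 - kc)
    dl: DLResult = dersimonian_laird(z, var_z)
    return PooledCorrelation(
        rho=float(np.tanh(dl.pooled)),
        ci_low=float(np.tanh(dl.ci_low)),
        ci_high=float(np.tanh(dl.ci_high)),
        z=dl.z,
        p=dl.p,
        tau2=dl.tau2,
        i2=dl.i2,
        k=dl.k,
    )


def food_group_intake(ffq: FFQTable, group: str) -> pd.Series:
    """Per-sample total intake of a food group (sum of its mapped items).

    Samples with a missing item value get NaN and are excluded from that
    group's correlations downstream.
    """
    items = ffq.items_in_group(group)
    return ffq.intakes[items].sum(axis=1, skipna=False).rename(group)


def run_correlation_meta(
    table: AbundanceTable,
    metadata: SampleMetadata,
    exposure: pd.Series,
    eligible_diets: tuple[str, ...] = ("omnivore", "vegetarian", "vegan"),
    q_threshold: float = 0.1,
    df_mode: str = "partial",
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-cohort partial Spearman of every feature with the exposure over
    the eligible diet population, Fisher-Z pooled, BH across features.

    ``exposure`` is indexed by sample id (a food-group intake or an hPDI
    score).  Returns one row per feature with pooled rho, CI, p, q, tau2,
    I2, k and the total n used.
    """
    table, metadata = align_samples(table, metadata)
    meta_df = metadata.data
    k_cov = 3  # sex, age, bmi

    per_cohort: dict[str, list[tuple[str, float, int]]] = {f: [] for f in table.feature_ids}
    any_cohort = False
    for cohort in metadata.cohorts:
        sub = meta_df[(meta_df["cohort"] == cohort) & meta_df["diet"].isin(eligible_diets)]
        expo = exposure.reindex(sub.index)
        sex = pd.Categorical(sub["sex"]).codes.astype(float)
        sex[sex < 0] = np.nan
        cov = np.column_stack([sex, sub["age"].to_numpy(float), sub["bmi"].to_numpy(float)])
        keep = np.isfinite(cov).all(axis=1) & np.isfinite(expo.to_numpy(float))
        sub, cov, expo = sub[keep], cov[keep], expo[keep]
        n = len(sub)
        if n < max(min_n, k_cov + 5):
            logger.info("cohort %s: only %d eligible samples; skipped", cohort, n)
            continue
        any_cohort = True
        T = arcsin_sqrt(table.data.loc[sub.index].to_numpy(float))
        x = expo.to_numpy(float)
        for j, feat in enumerate(table.feature_ids):
            rho = partial_spearman(T[:, j], x, cov)
            if math.isfinite(rho) and abs(rho) < 1:
                per_cohort[feat].append((cohort, rho, n))
    if not any_cohort:
        raise ValidationError("eligible population empty (or too small) in every cohort")

    rows = []
    for feat, effs in per_cohort.items():
        if not effs:
            continue
        pooled = fisher_pool(
            [e[1] for e in effs], [e[2] for e in effs], k_covariates=k_cov, df_mode=df_mode
        )
        rows.append(
            {
                "feature_id": feat,
                "rho": pooled.rho,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "z": pooled.z,
                "p": pooled.p,
                "tau2": pooled.tau2,
                "i2": pooled.i2,
                "k": pooled.k,
                "n_total": int(sum(e[2] for e in effs)),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValidationError("no feature yielded a defined correlation")
    df["q"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < q_threshold
    return df.sort_values("p", kind="mergesort").reset_index(drop=True)


def run_hpdi_correlation_meta(
    table: AbundanceTable,
    metadata: SampleMetadata,
    hpdi_scores: pd.Series,
    diets: tuple[str, ...] = ("omnivore", "vegetarian"),
    **kwargs,
) -> dict[str, pd.DataFrame]:
    """hPDI correlations computed within each diet pattern separately."""
    out = {}
    for diet in diets:
        out[diet] = run_correlation_meta(
            table, metadata, hpdi_scores, eligible_diets=(diet,), **kwargs
        )
    return out
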