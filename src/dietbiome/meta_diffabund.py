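"""Cross-cohort differential abundance of compositional features.

The core statistic: per cohort, a linear model of the arcsin-square-root
transformed relative abundance on the diet contrast plus sex/age/BMI; the diet
coefficient is standardized by the residual standard deviation into an
adjusted Cohen's d, and per-cohort effects are pooled with a
DerSimonian–Laird random-effects meta-analysis.  Two Benjamini–Hochberg
families are maintained: Wald p-values within each cohort, and pooled
p-values across features within each meta-analysis.

Sign convention: d > 0 means the feature is more abundant in the *comparison*
group (the second element of the diet pair); the first element is the
reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AbundanceTable, SampleMetadata, ValidationError, align_samples

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# transforms and elementary statistics
# ---------------------------------------------------------------------------


def arcsin_sqrt(abundance_percent):
    """Variance-stabilizing arcsin-square-root transform of percent abundances.

    Maps [0, 100] onto [0, pi/2]:  asin(sqrt(a / 100)).
    """
    a = np.asarray(abundance_percent, dtype=float)
    if (a < 0).any() or (a > 100).any():
        raise ValidationError("abundance outside [0, 100]")
    out = np.arcsin(np.sqrt(a / 100.0))
    if np.isscalar(abundance_percent) or np.ndim(abundance_percent) == 0:
        return float(out)
    return out


def _design_matrix(group: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(group, dtype=float), group.astype(float)]
    if covariates is not None and covariates.size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != group.shape[0]:
            cov = cov.T
        cols.extend(cov.T)
    return np.column_stack(cols)


def _ols_smd_matrix(
    Y: np.ndarray, group: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized adjusted-Cohen's-d over the columns of Y.

    Returns (d, var_d, wald_p) arrays; columns with zero residual variance
    come back NaN and are skipped by the caller.
    """
    X = _design_matrix(group, covariates)
    n, p = X.shape
    if n <= p:
        raise ValidationError("too few samples for the adjusted model")
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("rank-deficient model matrix (collinear covariates)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        sd_res = np.sqrt(sigma2)
        d = beta[1] / sd_res
        se_beta = np.sqrt(xtx_inv[1, 1] * sigma2)
        tstat = beta[1] / se_beta
    n1 = int(np.sum(group == 0))
    n2 = int(np.sum(group == 1))
    var_d = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    wald_p = 2.0 * stats.t.sf(np.abs(tstat), df)
    bad = ~np.isfinite(d)
    d = np.where(bad, np.nan, d)
    var_d = np.where(bad, np.nan, var_d)
    wald_p = np.where(bad, np.nan, wald_p)
    return d, var_d, wald_p


def adjusted_cohens_d(y, group, covariates=None) -> tuple[float, float, float]:
    """Covariate-adjusted standardized mean difference for one feature.

    OLS of ``y`` on the binary group indicator plus covariates;
    d = beta_group / residual SD, with the usual SMD sampling variance
    (n1+n2)/(n1*n2) + d^2 / (2(n1+n2)).  The Wald p uses a t reference with
    residual degrees of freedom.  With no covariates this reduces to the
    classical two-group Cohen's d on the pooled standard deviation.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if set(np.unique(group)) - {0, 1}:
        raise ValidationError("group indicator must be binary 0/1")
    if (group == 0).sum() == 0 or (group == 1).sum() == 0:
        raise ValidationError("both groups must be nonempty")
    d, var_d, p = _ols_smd_matrix(y[:, None], group, covariates)
    if not np.isfinite(d[0]):
        raise ValidationError("zero residual variance; d undefined")
    return float(d[0]), float(var_d[0]), float(p[0])


@dataclass
class DLResult:
    """DerSimonian–Laird pooled effect."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    i2: float  # percent
    q_het: float
    k: int


def dersimonian_laird(effects, variances) -> DLResult:
    """Moment-based random-effects pooling of per-cohort effects.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed-effect
    weights w = 1/v; pooled effect uses w* = 1/(v + tau^2).  A single study
    degenerates to itself (tau^2 = 0, I^2 reported as 0).
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.ndim != 1 or y.shape != v.shape or y.size == 0:
        raise ValidationError("effects and variances must be equal-length 1-d arrays")
    if (v <= 0).any():
        raise ValidationError("all sampling variances must be positive")
    k = y.size
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    if k > 1:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    else:
        tau2 = 0.0
        i2 = 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    z = pooled / se
    p = 2.0 * stats.norm.sf(abs(z))
    return DLResult(
        pooled=pooled,
        se=se,
        ci_low=pooled - 1.959963984540054 * se,
        ci_high=pooled + 1.959963984540054 * se,
        z=float(z),
        p=float(p),
        tau2=float(tau2),
        i2=float(i2),
        q_het=q,
        k=k,
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j, capped at 1.

    NaN entries are passed through and do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values outside [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[mask] = qv
    return out


# ---------------------------------------------------------------------------
# full per-feature meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class CohortEffect:
    cohort: str
    feature_id: str
    reference: str
    comparison: str
    d: float
    var_d: float
    n_ref: int
    n_cmp: int
    wald_p: float
    q: float = math.nan  # BH within this cohort's family

    def to_record(self) -> dict:
        return vars(self).copy()


@dataclass
class MetaResult:
    feature_id: str
    reference: str
    comparison: str
    pooled_d: float
    se_pooled: float
    ci_low: float
    ci_high: float
    z: float
    wald_p: float
    q: float
    tau2: float
    i2: float
    q_het: float
    k: int
    cohort_effects: list[CohortEffect] = field(default_factory=list, repr=False)

    def to_record(self) -> dict:
        rec = vars(self).copy()
        rec.pop("cohort_effects")
        return rec


@dataclass
class DiffAbundMeta:
    """Bundle of pooled per-feature results for one diet pair."""

    reference: str
    comparison: str
    results: list[MetaResult]
    q_threshold: float = 0.1

    @property
    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_records([r.to_record() for r in self.results])
        return df.reindex(df["pooled_d"].abs().sort_values(ascending=False).index)

    @property
    def cohort_frame(self) -> pd.DataFrame:
        recs = [e.to_record() for r in self.results for e in r.cohort_effects]
        return pd.DataFrame.from_records(recs)

    def significant(self, q_threshold: float | None = None) -> list[str]:
        thr = self.q_threshold if q_threshold is None else q_threshold
        return [r.feature_id for r in self.results if np.isfinite(r.q) and r.q < thr]

    def top(self, n: int = 30) -> pd.DataFrame:
        """Features ranked by |pooled SMD| (the paper-style 'top 30' view)."""
        return self.frame.head(n)


def _covariate_matrix(meta_df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sex dummy + age + BMI with listwise deletion; returns (cov, keep_mask)."""
    sex = pd.Categorical(meta_df["sex"]).codes.astype(float)
    sex[sex < 0] = np.nan
    cov = np.column_stack(
        [sex, meta_df["age"].to_numpy(dtype=float), meta_df["bmi"].to_numpy(dtype=float)]
    )
    keep = np.isfinite(cov).all(axis=1)
    return cov, keep


def run_diffabund_meta(
    table: AbundanceTable,
    metadata: SampleMetadata,
    diet_pair: tuple[str, str],
    min_group_size: int = 3,
    q_threshold: float = 0.1,
    adjust_covariates: bool = True,
) -> DiffAbundMeta:
    """Per-cohort adjusted SMDs on arcsin-sqrt abundances, pooled by
    DerSimonian–Laird, BH-adjusted across features within the meta-analysis.

    Cohorts lacking ``min_group_size`` samples in either diet group are
    skipped for all features; features with zero residual variance in a
    cohort are skipped in that cohort only (k is reported per feature).
    """
    ref, cmp = diet_pair
    table, metadata = align_samples(table, metadata)
    meta_df = metadata.data
    features = table.feature_ids
    per_feature: dict[str, list[CohortEffect]] = {f: [] for f in features}

    n_cohorts_used = 0
    for cohort in metadata.cohorts:
        in_pair = (meta_df["cohort"] == cohort) & meta_df["diet"].isin([ref, cmp])
        sub = meta_df[in_pair]
        if adjust_covariates:
            cov, keep = _covariate_matrix(sub)
            dropped = int((~keep).sum())
            if dropped:
                logger.info("cohort %s: %d samples dropped for missing covariates", cohort, dropped)
            sub = sub[keep]
            cov = cov[keep]
        else:
            cov = None
        n_ref = int((sub["diet"] == ref).sum())
        n_cmp = int((sub["diet"] == cmp).sum())
        if n_ref < min_group_size or n_cmp < min_group_size:
            logger.info(
                "cohort %s skipped for pair (%s, %s): group sizes %d/%d below %d",
                cohort, ref, cmp, n_ref, n_cmp, min_group_size,
            )
            continue
        n_cohorts_used += 1
        group = (sub["diet"] == cmp).to_numpy().astype(float)
        Y = arcsin_sqrt(table.data.loc[sub.index].to_numpy(dtype=float))
        d, var_d, wald_p = _ols_smd_matrix(Y, group, cov)
        qvals = bh_adjust(wald_p)  # per-cohort BH family
        for j, feat in enumerate(features):
            if not np.isfinite(d[j]):
                continue
            per_feature[feat].append(
                CohortEffect(
                    cohort=cohort, feature_id=feat, reference=ref, comparison=cmp,
                    d=float(d[j]), var_d=float(var_d[j]), n_ref=n_ref, n_cmp=n_cmp,
                    wald_p=float(wald_p[j]), q=float(qvals[j]),
                )
            )

    if n_cohorts_used == 0:
        raise ValidationError(
            f"no cohort has both diet groups at size >= {min_group_size} for ({ref}, {cmp})"
        )

    results: list[MetaResult] = []
    for feat in features:
        effs = per_feature[feat]
        if not effs:
            continue
        dl = dersimonian_laird([e.d for e in effs], [e.var_d for e in effs])
        results.append(
            MetaResult(
                feature_id=feat, reference=ref, comparison=cmp,
                pooled_d=dl.pooled, se_pooled=dl.se, ci_low=dl.ci_low,
                ci_high=dl.ci_high, z=dl.z, wald_p=dl.p, q=math.nan,
                tau2=dl.tau2, i2=dl.i2, q_het=dl.q_het, k=dl.k,
                cohort_effects=effs,
            )
        )
    qvals = bh_adjust([r.wald_p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return DiffAbundMeta(reference=ref, comparison=cmp, results=results, q_threshold=q_threshold)


def filter_pathway_table(
    table: AbundanceTable,
    metadata: SampleMetadata,
    min_prevalence: float = 0.05,
    coverage: pd.DataFrame | None = None,
    min_coverage: float = 0.2,
    drop_name_patterns: tuple[str, ...] = ("UNMAPPED", "UNINTEGRATED"),
) -> AbundanceTable:
    """Pre-filter a functional-pathway abundance table before meta-analysis.

    Drops unmapped/unintegrated pathways, pathways whose nonzero prevalence
    falls below ``min_prevalence`` within at least one diet pattern, and —
    when a per-sample coverage table is supplied — pathways whose mean
    coverage is below ``min_coverage``.
    """
    table, metadata = align_samples(table, metadata)
    df = table.data
    keep = [
        f for f in df.columns
        if not any(pat.lower() in f.lower() for pat in drop_name_patterns)
    ]
    df = df[keep]
    diets = metadata.data["diet"]
    prev_ok = pd.Series(True, index=df.columns)
    for diet in diets.unique():
        sub = df.loc[diets[diets == diet].index]
        prev = (sub > 0).mean(axis=0)
        prev_ok &= prev >= min_prevalence
    df = df.loc[:, prev_ok]
    if coverage is not None:
        shared = [f for f in df.columns if f in coverage.columns]
        cov_ok = coverage[shared].mean(axis=0) >= min_coverage
        df = df[[f for f in shared if cov_ok[f]]]
    if df.shape[1] == 0:
        raise ValidationError("pathway filter removed every feature")
    return AbundanceTable(df)
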