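"""Random-forest validation of diet-pattern signal in the microbiome.

Three schemes mirror the multi-cohort design:

* ``cv`` — repeated stratified k-fold within one cohort;
* ``lodo`` — leave-one-dataset-out: train on all other cohorts, test on the
  held-out cohort;
* ``cross_lodo`` — the cv folds of the target cohort with every pair-labelled
  sample of all other cohorts appended to each training set as support; test
  folds come only from the target cohort.

The forest follows the study configuration (1,000 trees, 10 samples per
leaf, no depth limit, Gini, 10 % of features per split); a scaled desk
profile (200 trees, 5×5 folds) is first-class so experiments finish at desk
scale.  Per-test AUCs are averaged; ROC curves are linearly interpolated
onto a common FPR grid with bootstrap-t confidence bands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .io_formats import AbundanceTable, FFQTable, SampleMetadata, ValidationError, align_samples
from .meta_diffabund import dersimonian_laird

logger = logging.getLogger(__name__)


@dataclass
class RFSpec:
    """Random-forest hyperparameters (study defaults)."""

    n_trees: int = 1000
    min_samples_leaf: int = 10
    max_depth: int | None = None
    criterion: str = "gini"
    features_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")

    def max_features(self, n_features: int) -> int:
        return max(1, round(self.features_fraction * n_features))

    def build(self, n_features: int, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_samples_leaf,
            max_depth=self.max_depth,
            criterion=self.criterion,
            max_features=self.max_features(n_features),
            random_state=seed,
            n_jobs=1,
        )

    @classmethod
    def scaled(cls) -> "RFSpec":
        """Desk-scale profile: 200 trees, same leaf/feature rules."""
        return cls(n_trees=200)


#: (rf spec, n_repeats, n_folds) per named profile
PROFILES: dict[str, tuple[RFSpec, int, int]] = {
    "full": (RFSpec(), 10, 10),
    "scaled": (RFSpec.scaled(), 5, 5),
}


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def make_splits(
    metadata: SampleMetadata,
    scheme: str,
    pair: tuple[str, str],
    target_cohort: str | None = None,
    n_repeats: int = 10,
    n_folds: int = 10,
    seed: int = 0,
) -> list[tuple[list[str], list[str]]]:
    """Train/test sample-id splits for one scheme and target cohort.

    Test sets never contain non-target-cohort samples (cv and cross-LODO)
    and train∩test is always empty.  Cross-LODO support samples are
    restricted to the two diet labels of the pair.  Cohorts too small for
    the requested fold count get fewer folds with a warning.
    """
    meta_df = metadata.data
    in_pair = meta_df[meta_df["diet"].isin(pair)]
    if scheme == "lodo":
        cohorts = [target_cohort] if target_cohort else sorted(in_pair["cohort"].unique())
        splits = []
        for tgt in cohorts:
            test = in_pair.index[in_pair["cohort"] == tgt].tolist()
            train = in_pair.index[in_pair["cohort"] != tgt].tolist()
            if not test or not train:
                raise ValidationError(f"lodo target {tgt!r} yields an empty split")
            splits.append((train, test))
        return splits
    if scheme not in ("cv", "cross_lodo"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if target_cohort is None:
        raise ValidationError(f"{scheme} requires a target cohort")

    tgt = in_pair[in_pair["cohort"] == target_cohort]
    y = tgt["diet"].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError(
            f"target cohort {target_cohort!r} lacks both classes of {pair}"
        )
    k = min(n_folds, int(counts.min()))
    if k < 2:
        raise ValidationError(f"minority class too small for cross-validation in {target_cohort!r}")
    if k < n_folds:
        logger.warning("cohort %s: reducing folds %d -> %d", target_cohort, n_folds, k)

    support = (
        in_pair.index[in_pair["cohort"] != target_cohort].tolist()
        if scheme == "cross_lodo"
        else []
    )
    ids = np.array(tgt.index)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(97,)))
    splits = []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        for tr_idx, te_idx in skf.split(ids, y):
            train = ids[tr_idx].tolist() + support
            test = ids[te_idx].tolist()
            splits.append((train, test))
    return splits


def assert_no_leakage(splits, target_ids=None) -> None:
    """Raise if any split shares ids between train and test, or a test id
    falls outside the target cohort."""
    target = None if target_ids is None else set(target_ids)
    for train, test in splits:
        overlap = set(train) & set(test)
        if overlap:
            raise ValidationError(f"train/test leakage: {sorted(overlap)[:3]}")
        if target is not None and set(test) - target:
            raise ValidationError("test ids outside the target cohort")


# ---------------------------------------------------------------------------
# single experiment
# ---------------------------------------------------------------------------


def fit_predict_auc(
    train_ids, test_ids, features: pd.DataFrame, labels: pd.Series,
    rf: RFSpec, seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray] | None:
    """Fit the forest on the training ids, return (AUC, fpr, tpr) on the test
    ids, or None when the test set has a single class (skipped, logged)."""
    y_train = labels.loc[train_ids]
    y_test = labels.loc[test_ids]
    if y_train.nunique() < 2:
        raise ValidationError("training set has a single class")
    if y_test.nunique() < 2:
        logger.info("single-class test set skipped (%d samples)", len(test_ids))
        return None
    clf = rf.build(features.shape[1], seed)
    clf.fit(features.loc[train_ids].to_numpy(), y_train.to_numpy())
    pos = clf.classes_[1]
    scores = clf.predict_proba(features.loc[test_ids].to_numpy())[:, 1]
    y_bin = (y_test.to_numpy() == pos).astype(int)
    auc = roc_auc_score(y_bin, scores)
    fpr, tpr, _ = roc_curve(y_bin, scores)
    return float(auc), fpr, tpr


def average_roc(
    roc_points: list[tuple[np.ndarray, np.ndarray]],
    fpr_grid: np.ndarray | None = None,
    ci_level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Linearly interpolate per-test ROC curves onto a common FPR grid and
    average; the CI band is mean ± t × bootstrap SE of the mean TPR
    (resampling tests with replacement).  A single test has no band."""
    if fpr_grid is None:
        fpr_grid = np.linspace(0.0, 1.0, 101)
    curves = np.array([np.interp(fpr_grid, fpr, tpr) for fpr, tpr in roc_points])
    mean = curves.mean(axis=0)
    n = curves.shape[0]
    if n < 2:
        return fpr_grid, mean, None, None
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, fpr_grid.size))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = curves[idx].mean(axis=0)
    se = boots.std(axis=0, ddof=1)
    tq = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
    lo = np.clip(mean - tq * se, 0.0, 1.0)
    hi = np.clip(mean + tq * se, 0.0, 1.0)
    return fpr_grid, mean, lo, hi


# ---------------------------------------------------------------------------
# full experiments
# ---------------------------------------------------------------------------


@dataclass
class ValidationResult:
    scheme: str
    target_cohort: str
    pair: tuple[str, str]
    aucs: list[float]
    roc_grid: np.ndarray = field(repr=False)
    roc_mean: np.ndarray = field(repr=False)
    roc_lo: np.ndarray | None = field(repr=False)
    roc_hi: np.ndarray | None = field(repr=False)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    def roc_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"fpr": self.roc_grid, "tpr_mean": self.roc_mean})
        if self.roc_lo is not None:
            df["tpr_lo"] = self.roc_lo
            df["tpr_hi"] = self.roc_hi
        return df


@dataclass
class DietClassification:
    scheme: str
    pair: tuple[str, str]
    per_cohort: dict[str, ValidationResult]

    @property
    def all_aucs(self) -> list[float]:
        return [a for r in self.per_cohort.values() for a in r.aucs]

    @property
    def mean_auc(self) -> float:
        """Arithmetic mean over every per-test AUC of every cohort."""
        return float(np.mean(self.all_aucs))

    @property
    def cohort_mean_aucs(self) -> dict[str, float]:
        return {c: r.mean_auc for c, r in self.per_cohort.items()}


def _feature_frame(
    table: AbundanceTable, metadata: SampleMetadata, with_covariates: bool
) -> pd.DataFrame:
    X = table.data.copy()
    if with_covariates:
        meta = metadata.data
        X["cov_sex"] = pd.Categorical(meta.loc[X.index, "sex"]).codes.astype(float)
        X["cov_age"] = meta.loc[X.index, "age"].astype(float)
        X["cov_bmi"] = meta.loc[X.index, "bmi"].astype(float)
    return X


def run_diet_classification(
    table: AbundanceTable,
    metadata: SampleMetadata,
    pair: tuple[str, str],
    scheme: str = "cross_lodo",
    rf: RFSpec | None = None,
    n_repeats: int = 10,
    n_folds: int = 10,
    with_covariates: bool = False,
    seed: int = 0,
    permute_labels: bool = False,
) -> DietClassification:
    """Run one classification experiment over every target cohort.

    ``permute_labels`` randomly permutes the diet labels of the pair
    population before splitting — the negative control for leakage and
    overfitting (expected mean AUC ~0.5).  A fresh permutation is drawn for
    each cross-validation repetition: one global permutation would let its
    chance correlation with the features propagate into every fold, so
    averaging over independent permutations estimates the null mean rather
    than one permutation's realization.
    """
    rf = rf or RFSpec()
    table, metadata = align_samples(table, metadata)
    base_labels = metadata.data["diet"].copy()
    pair_idx = base_labels.index[base_labels.isin(pair)]

    def labels_for(rep: int) -> pd.Series:
        if not permute_labels:
            return base_labels
        # blocked permutation: shuffle within each cohort so per-cohort class
        # counts (the blocking structure cross-LODO conditions on) are kept
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7919, rep)))
        lab = base_labels.copy()
        for cohort in sorted(metadata.data["cohort"].unique()):
            idx = pair_idx[metadata.data.loc[pair_idx, "cohort"] == cohort]
            lab.loc[idx] = rng.permutation(lab.loc[idx].to_numpy())
        return lab

    features = _feature_frame(table, metadata, with_covariates)

    meta_df = metadata.data
    cohorts = sorted(meta_df["cohort"].unique())
    per_cohort: dict[str, ValidationResult] = {}
    for ci, cohort in enumerate(cohorts):
        reps = range(n_repeats) if scheme in ("cv", "cross_lodo") else [0]
        aucs, rocs = [], []
        skipped = None
        for rep in reps:
            labels = labels_for(rep)
            # (permuted) labels drive the stratification too
            strat_meta = SampleMetadata(meta_df.assign(diet=labels))
            try:
                splits = make_splits(
                    strat_meta, scheme, pair, target_cohort=cohort,
                    n_repeats=1, n_folds=n_folds, seed=seed + 1000 * rep + ci,
                )
            except ValidationError as exc:
                skipped = exc
                break
            if scheme in ("cv", "cross_lodo"):
                tgt_ids = meta_df.index[meta_df["cohort"] == cohort]
                assert_no_leakage(splits, tgt_ids)
            else:
                assert_no_leakage(splits)
            seeder = np.random.SeedSequence(seed, spawn_key=(ci, rep, 1))
            rf_seeds = np.random.default_rng(seeder).integers(0, 2**31 - 1, size=len(splits))
            for split_i, (train, test) in enumerate(splits):
                out = fit_predict_auc(
                    train, test, features, labels, rf, seed=int(rf_seeds[split_i])
                )
                if out is None:
                    continue
                auc, fpr, tpr = out
                aucs.append(auc)
                rocs.append((fpr, tpr))
        if skipped is not None:
            logger.warning("cohort %s skipped: %s", cohort, skipped)
            continue
        if not aucs:
            logger.warning("cohort %s produced no valid test folds", cohort)
            continue
        grid, mean_curve, lo, hi = average_roc(rocs, seed=seed + 101 + ci)
        per_cohort[cohort] = ValidationResult(
            scheme=scheme, target_cohort=cohort, pair=pair, aucs=aucs,
            roc_grid=grid, roc_mean=mean_curve, roc_lo=lo, roc_hi=hi,
        )
    if not per_cohort:
        raise ValidationError("no cohort produced a valid experiment")
    return DietClassification(scheme=scheme, pair=pair, per_cohort=per_cohort)


def predict_presence_from_ffq(
    table: AbundanceTable,
    ffq: FFQTable,
    metadata: SampleMetadata,
    prevalence_window: tuple[float, float] = (0.10, 0.90),
    rf: RFSpec | None = None,
    n_repeats: int = 2,
    n_folds: int = 5,
    seed: int = 0,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Predict each feature's presence/absence from FFQ intakes, per cohort,
    and meta-analyse the per-cohort AUCs.

    Only features whose within-cohort prevalence lies inside the window are
    modelled in that cohort; the per-cohort AUC standard error is the SD of
    per-fold AUCs divided by sqrt(number of tests), and cohort AUCs are
    pooled by DerSimonian–Laird.
    """
    rf = rf or RFSpec.scaled()
    table, metadata = align_samples(table, metadata)
    shared = [s for s in table.sample_ids if s in set(ffq.sample_ids)]
    table = table.subset_samples(shared)
    metadata = metadata.subset(shared)
    X = ffq.intakes.loc[shared]
    feats = features if features is not None else table.feature_ids
    meta_df = metadata.data
    lo, hi = prevalence_window

    rows = []
    root = np.random.SeedSequence(seed, spawn_key=(4242,))
    for fi, feat in enumerate(feats):
        presence = (table.data[feat] > 0).astype(int)
        cohort_aucs: list[tuple[float, float]] = []
        for ci, cohort in enumerate(metadata.cohorts):
            ids = meta_df.index[meta_df["cohort"] == cohort]
            y = presence.loc[ids].to_numpy()
            prev = y.mean()
            if not (lo <= prev <= hi):
                continue
            k = min(n_folds, int(min(y.sum(), (1 - y).sum())))
            if k < 2:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(4242, fi, ci))
            )
            fold_aucs = []
            Xc = X.loc[ids].to_numpy()
            for rep in range(n_repeats):
                skf = StratifiedKFold(n_splits=k, shuffle=True,
                                      random_state=int(rng.integers(0, 2**31 - 1)))
                for tr, te in skf.split(Xc, y):
                    if len(np.unique(y[te])) < 2:
                        continue
                    clf = rf.build(Xc.shape[1], int(rng.integers(0, 2**31 - 1)))
                    clf.fit(Xc[tr], y[tr])
                    fold_aucs.append(
                        roc_auc_score(y[te], clf.predict_proba(Xc[te])[:, 1])
                    )
            if len(fold_aucs) < 2:
                continue
            se = float(np.std(fold_aucs, ddof=1) / math.sqrt(len(fold_aucs)))
            cohort_aucs.append((float(np.mean(fold_aucs)), max(se, 1e-4)))
        if not cohort_aucs:
            logger.info("feature %s outside the prevalence window in all cohorts", feat)
            continue
        dl = dersimonian_laird([a for a, _ in cohort_aucs], [s**2 for _, s in cohort_aucs])
        rows.append(
            {
                "feature_id": feat,
                "auc": dl.pooled,
                "se": dl.se,
                "ci_low": dl.ci_low,
                "ci_high": dl.ci_high,
                "i2": dl.i2,
                "k": dl.k,
            }
        )
    return pd.DataFrame(rows)
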