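"""Synthetic multi-cohort diet–microbiome datasets with known planted structure.

The generator emulates the study design every downstream stage expects:
several cohorts of unequal size; heavily unbalanced diet labels (~92 %
omnivore, 5 % vegetarian, 3 % vegan); a few hundred sparse compositional
features closed to 100 per sample; sex/age/BMI covariates; per-feature diet
effects planted in standardized-mean-difference units on the arcsin-sqrt
scale; FFQ intakes statistically coupled to diet labels and to the presence
of designated food-derived features.

Effects are planted on the transformed scale through an empirical
calibration loop: the target SMD is converted into a shift of the
arcsin-sqrt value of comparison-group samples, abundances are re-closed, the
realized Cohen's d is measured, and the shift is rescaled until it matches
the target.  The realized per-cohort d and final shift are recorded in the
truth record so tests can assert against what was actually planted.

One global seed fans out to per-cohort child streams via
``numpy.random.SeedSequence(seed, spawn_key=...)``, so adding a cohort never
perturbs existing cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    AbundanceTable,
    FFQTable,
    FoodCatalogTable,
    SampleMetadata,
    ValidationError,
    write_abundance_table,
    write_ffq,
    write_food_catalog,
    write_health_ranks,
    write_metadata,
)
from .meta_diffabund import arcsin_sqrt

DIETS = ("omnivore", "vegetarian", "vegan")

#: 18 hPDI food groups: 7 healthy plant (positive), 5 less-healthy plant and
#: 6 animal groups (reverse).  red/white meat, dairy, fruits and vegetables
#: double as the food groups used for intake–abundance correlations.
HPDI_GROUPS: dict[str, str] = {
    "whole_grains": "positive",
    "fruits": "positive",
    "vegetables": "positive",
    "nuts": "positive",
    "legumes": "positive",
    "vegetable_oils": "positive",
    "tea_coffee": "positive",
    "fruit_juices": "reverse",
    "refined_grains": "reverse",
    "potatoes": "reverse",
    "sugary_drinks": "reverse",
    "sweets": "reverse",
    "animal_fat": "reverse",
    "dairy": "reverse",
    "eggs": "reverse",
    "fish": "reverse",
    "red_meat": "reverse",
    "white_meat": "reverse",
}

_HEALTHY_PLANT = [g for g, f in HPDI_GROUPS.items() if f == "positive"]
_UNHEALTHY_PLANT = ["fruit_juices", "refined_grains", "potatoes", "sugary_drinks", "sweets"]
_ANIMAL = ["animal_fat", "dairy", "eggs", "fish", "red_meat", "white_meat"]
_MEAT_GROUPS = ("red_meat", "white_meat", "fish")
_VEGAN_EXCLUDED = ("red_meat", "white_meat", "fish", "dairy", "eggs", "animal_fat")

FOOD_CATEGORIES = ("meat", "dairy", "fruits_vegetables")
_CATEGORY_TO_GROUPS = {
    "meat": ["red_meat", "white_meat"],
    "dairy": ["dairy"],
    "fruits_vegetables": ["fruits", "vegetables"],
}


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror the multi-cohort study the pipeline targets: five cohorts
    of very unequal size and ~92/5/3 omnivore/vegetarian/vegan proportions.
    Tests and desk-scale runs pass smaller ``cohort_sizes``.
    """

    cohort_sizes: tuple[int, ...] = (1062, 12353, 7931, 118, 97)
    diet_proportions: tuple[float, float, float] = (0.92, 0.05, 0.03)
    n_features: int = 300
    n_signature_features: int = 10
    planted_smd: float | tuple[float, ...] = 0.5
    signature_pair: tuple[str, str] = ("omnivore", "vegan")
    #: per-feature detection prevalence drawn uniformly from this range
    prevalence_range: tuple[float, float] = (0.10, 0.95)
    #: signature features are kept common so abundance effects dominate
    signature_prevalence: float = 0.90
    cohort_shift_sd: float = 0.3
    feature_logmean_sd: float = 2.0
    feature_noise_sd: float = 1.0
    age_mean: float = 50.0
    age_sd: float = 12.0
    bmi_mean: float = 25.0
    bmi_sd: float = 4.0
    sex_female_p: float = 0.5
    #: diet → healthy-plant intake shift, in log-intake SD units
    ffq_coupling: float = 1.0
    #: log-intake boost of a food category's items when its feature is present
    ffq_presence_coupling: float = 2.0
    n_food_features_per_category: int = 4
    food_feature_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.diet_proportions) - 1.0) > 1e-9:
            raise ValidationError("diet proportions must sum to 1")
        smds = self.smd_values()
        if not np.isfinite(smds).all():
            raise ValidationError("planted_smd must be finite")
        if self.n_signature_features > self.n_features:
            raise ValidationError("n_signature_features exceeds n_features")
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi <= 1):
            raise ValidationError("prevalence range must lie in (0, 1]")
        if not (0 < self.signature_prevalence <= 1):
            raise ValidationError("signature prevalence must lie in (0, 1]")
        if set(self.signature_pair) - set(DIETS):
            raise ValidationError(f"signature pair must be drawn from {DIETS}")

    def smd_values(self) -> np.ndarray:
        """Signed planted SMDs, one per signature feature.

        A scalar target is expanded with alternating signs so both enrichment
        directions are represented.
        """
        if np.isscalar(self.planted_smd):
            signs = np.where(np.arange(self.n_signature_features) % 2 == 0, 1.0, -1.0)
            return float(self.planted_smd) * signs
        arr = np.asarray(self.planted_smd, dtype=float)
        if arr.size != self.n_signature_features:
            raise ValidationError("planted_smd length must equal n_signature_features")
        return arr

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("cohort_sizes", "diet_proportions", "planted_smd", "signature_pair",
                    "prevalence_range", "food_feature_ids"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# shared feature-level parameters (identical across ops for a given config)
# ---------------------------------------------------------------------------


def _feature_rng(config: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1 << 20,)))


def _cohort_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


@dataclass
class _FeatureParams:
    feature_ids: list[str]
    log_mean: np.ndarray
    prevalence: np.ndarray
    signature_idx: np.ndarray  # indices of planted features
    smd: np.ndarray  # signed target SMD per signature feature
    food_assignment: dict[str, str]  # feature_id -> category


def _feature_params(config: SimulationConfig) -> _FeatureParams:
    rng = _feature_rng(config)
    m = config.n_features
    ids = [f"SGB{i + 1:04d}" for i in range(m)]
    log_mean = rng.normal(0.0, config.feature_logmean_sd, size=m)
    lo, hi = config.prevalence_range
    prevalence = rng.uniform(lo, hi, size=m)
    signature_idx = np.sort(rng.choice(m, size=config.n_signature_features, replace=False))
    prevalence[signature_idx] = config.signature_prevalence
    if config.food_feature_ids is not None:
        food_ids = list(config.food_feature_ids)
        unknown = set(food_ids) - set(ids)
        if unknown:
            raise ValidationError(f"food_feature_ids not in feature set: {sorted(unknown)}")
        cats = [FOOD_CATEGORIES[i % len(FOOD_CATEGORIES)] for i in range(len(food_ids))]
        assignment = dict(zip(food_ids, cats))
    else:
        pool = np.setdiff1d(np.arange(m), signature_idx)
        n_food = config.n_food_features_per_category * len(FOOD_CATEGORIES)
        chosen = rng.choice(pool, size=min(n_food, pool.size), replace=False)
        assignment = {
            ids[j]: FOOD_CATEGORIES[k % len(FOOD_CATEGORIES)]
            for k, j in enumerate(np.sort(chosen))
        }
    # food features must be reliably detectable in gut samples
    for fid in assignment:
        prevalence[ids.index(fid)] = max(prevalence[ids.index(fid)], 0.5)
    return _FeatureParams(
        feature_ids=ids, log_mean=log_mean, prevalence=prevalence,
        signature_idx=signature_idx, smd=config.smd_values(), food_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def _closure(v: np.ndarray) -> np.ndarray:
    sums = v.sum(axis=1, keepdims=True)
    return 100.0 * v / sums


def _plain_cohens_d(t: np.ndarray, group: np.ndarray) -> float:
    t1, t2 = t[group == 0], t[group == 1]
    n1, n2 = t1.size, t2.size
    if n1 < 2 or n2 < 2:
        return math.nan
    s_pool = math.sqrt(
        ((n1 - 1) * t1.var(ddof=1) + (n2 - 1) * t2.var(ddof=1)) / (n1 + n2 - 2)
    )
    if s_pool == 0:
        return math.nan
    return (t2.mean() - t1.mean()) / s_pool


def _plant_effects(
    v: np.ndarray,
    mask: np.ndarray,
    diets: np.ndarray,
    params: _FeatureParams,
    pair: tuple[str, str],
    n_iter: int = 4,
) -> tuple[np.ndarray, dict[str, dict]]:
    """Shift comparison-group samples on the arcsin-sqrt scale so the realized
    Cohen's d over the diet pair matches each feature's target SMD."""
    ref, cmp = pair
    in_pair = np.isin(diets, [ref, cmp])
    group = (diets == cmp).astype(float)[in_pair]
    base_v = v * mask
    p_base = _closure(base_v)
    t_base = arcsin_sqrt(p_base)
    eps = 1e-4

    # initial shift: target d times the pair-population SD of the transform
    shifts: dict[int, float] = {}
    for j, d_target in zip(params.signature_idx, params.smd):
        t_pair = t_base[in_pair, j]
        sd_t = float(t_pair.std(ddof=1)) if t_pair.size > 1 else 0.0
        shifts[j] = d_target * (sd_t if sd_t > 0 else 0.05)

    def _apply(shifts: dict[int, float]) -> np.ndarray:
        # positive d raises the comparison group; negative d raises the
        # reference group instead (shifting down would clip at zero abundance)
        v_work = base_v.copy()
        for j, s in shifts.items():
            target_diet = cmp if s >= 0 else ref
            apply = (diets == target_diet) & (mask[:, j] > 0)
            if not apply.any():
                continue
            t_new = np.clip(
                t_base[:, j] + np.where(apply, abs(s), 0.0), eps, math.pi / 2 - eps
            )
            p_new = 100.0 * np.sin(t_new) ** 2
            nz = base_v[:, j] > 0
            v_work[nz, j] = base_v[nz, j] * p_new[nz] / p_base[nz, j]
        return v_work

    v_work = _apply(shifts)
    # refine the shift against the realized d only when both groups are large
    # enough that the realized value reflects attenuation (zeros, closure)
    # rather than sampling noise; tiny groups keep the analytic shift, which
    # is unbiased for the target
    n_ref_g = int((group == 0).sum())
    n_cmp_g = int((group == 1).sum())
    if min(n_ref_g, n_cmp_g) >= 10:
        for _ in range(n_iter - 1):
            t_fin = arcsin_sqrt(_closure(v_work))
            converged = True
            for j, d_target in zip(params.signature_idx, params.smd):
                realized = _plain_cohens_d(t_fin[in_pair, j], group)
                if math.isfinite(realized) and realized * d_target > 1e-3:
                    ratio = float(np.clip(d_target / realized, 0.25, 4.0))
                    if abs(ratio - 1.0) > 0.02:
                        converged = False
                    shifts[j] *= ratio
            if converged:
                break
            v_work = _apply(shifts)

    t_final = arcsin_sqrt(_closure(v_work))
    calib: dict[str, dict] = {}
    for j, d_target in zip(params.signature_idx, params.smd):
        calib[params.feature_ids[j]] = {
            "target_smd": float(d_target),
            "shift": float(shifts[j]),
            "realized_d": float(_plain_cohens_d(t_final[in_pair, j], group)),
        }
    return v_work, calib


def _simulate_ffq_items() -> pd.DataFrame:
    """Two items per hPDI group; the group map io_formats expects."""
    rows = []
    for group, flag in HPDI_GROUPS.items():
        for k in (1, 2):
            rows.append({"item": f"{group}_item{k}", "group": group, "hpdi_flag": flag})
    return pd.DataFrame(rows).set_index("item")


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[AbundanceTable, SampleMetadata, FFQTable, dict]:
    """Generate abundances, metadata and FFQ for every cohort plus a truth record."""
    params = _feature_params(config)
    m = config.n_features
    group_map = _simulate_ffq_items()
    items = list(group_map.index)
    item_group = group_map["group"].to_dict()

    abund_frames, meta_frames, ffq_frames = [], [], []
    calibration: dict[str, dict[str, dict]] = {}
    ref, cmp = config.signature_pair
    props = np.asarray(config.diet_proportions, dtype=float)

    for ci, n in enumerate(config.cohort_sizes):
        rng = _cohort_rng(config, ci)
        cohort = f"C{ci + 1}"
        diets = rng.choice(DIETS, size=n, p=props)
        # a requested contrast needs both labels somewhere; checked globally below
        sex = np.where(rng.random(n) < config.sex_female_p, "female", "male")
        age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 95.0)
        bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, n), 15.0, 60.0)
        sample_ids = [f"{cohort}_S{i + 1:05d}" for i in range(n)]

        cohort_shift = rng.normal(0.0, config.cohort_shift_sd, size=m)
        logv = (
            params.log_mean[None, :]
            + cohort_shift[None, :]
            + rng.normal(0.0, config.feature_noise_sd, size=(n, m))
        )
        v = np.exp(logv)
        mask = (rng.random((n, m)) < params.prevalence[None, :]).astype(float)
        # no sample may be entirely zero after inflation
        dead = mask.sum(axis=1) == 0
        if dead.any():
            mask[dead, np.argmax(v[dead], axis=1)] = 1.0

        v_planted, calib = _plant_effects(v, mask, diets, params, (ref, cmp))
        p = _closure(v_planted)
        calibration[cohort] = calib

        abund_frames.append(pd.DataFrame(p, index=sample_ids, columns=params.feature_ids))
        meta_frames.append(
            pd.DataFrame(
                {"cohort": cohort, "diet": diets, "sex": sex, "age": age, "bmi": bmi},
                index=sample_ids,
            )
        )

        # --- FFQ intakes coupled to diet labels and food-feature presence ---
        log_intake = rng.normal(1.0, 0.5, size=(n, len(items)))
        diet_idx = {d: diets == d for d in DIETS}
        t_abund = arcsin_sqrt(p)
        for k, item in enumerate(items):
            g = item_group[item]
            if g in _HEALTHY_PLANT:
                log_intake[diet_idx["vegetarian"], k] += 0.5 * config.ffq_coupling
                log_intake[diet_idx["vegan"], k] += 1.0 * config.ffq_coupling
            elif g in _UNHEALTHY_PLANT:
                log_intake[diet_idx["vegetarian"], k] -= 0.25 * config.ffq_coupling
                log_intake[diet_idx["vegan"], k] -= 0.5 * config.ffq_coupling
        for fid, cat in params.food_assignment.items():
            j = params.feature_ids.index(fid)
            present = p[:, j] > 0
            tz = t_abund[:, j]
            tsd = tz.std()
            t_std = (tz - tz.mean()) / tsd if tsd > 0 else np.zeros(n)
            for g in _CATEGORY_TO_GROUPS[cat]:
                for k, item in enumerate(items):
                    if item_group[item] == g:
                        log_intake[present, k] += config.ffq_presence_coupling / 2.0
                        log_intake[:, k] += 0.3 * config.ffq_presence_coupling * t_std
        intake = np.exp(log_intake)
        for g in _MEAT_GROUPS:
            cols = [k for k, it in enumerate(items) if item_group[it] == g]
            intake[np.ix_(~diet_idx["omnivore"], cols)] = 0.0
        for g in _VEGAN_EXCLUDED:
            cols = [k for k, it in enumerate(items) if item_group[it] == g]
            intake[np.ix_(diet_idx["vegan"], cols)] = 0.0
        ffq_frames.append(pd.DataFrame(intake, index=sample_ids, columns=items))

    table = AbundanceTable(pd.concat(abund_frames))
    metadata = SampleMetadata(pd.concat(meta_frames))
    ffq = FFQTable(intakes=pd.concat(ffq_frames), group_map=group_map.copy())

    if config.n_signature_features > 0:
        have = set(metadata.data["diet"])
        if not {ref, cmp} <= have:
            raise ValidationError(
                f"infeasible config: planted contrast ({ref}, {cmp}) but generated "
                f"diet labels are {sorted(have)}; increase cohort sizes or proportions"
            )

    truth = {
        "seed": config.seed,
        "signature_pair": [ref, cmp],
        "planted_effects": [
            {
                "feature_id": params.feature_ids[j],
                "smd": float(d),
                "calibration": {
                    cohort: calibration[cohort][params.feature_ids[j]]
                    for cohort in calibration
                },
            }
            for j, d in zip(params.signature_idx, params.smd)
        ],
        "food_features": dict(params.food_assignment),
        "ffq_coupling": config.ffq_coupling,
        "ffq_presence_coupling": config.ffq_presence_coupling,
        "cohort_sizes": list(config.cohort_sizes),
        "diet_proportions": list(config.diet_proportions),
    }
    return table, metadata, ffq, truth


def simulate_food_catalog(config: SimulationConfig) -> FoodCatalogTable:
    """cFMD-style per-feature food-sample summaries consistent with
    :func:`simulate_cohorts` for the same config.

    Designated food features are detected in ≥ 4 food samples with prevalence
    above the 0.1 % signature threshold in their assigned category; all other
    features fall below the ≥4-sample call rule.
    """
    params = _feature_params(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1 << 21,)))
    rows = []
    for fid in params.feature_ids:
        cat = params.food_assignment.get(fid)
        row = {"feature_id": fid}
        if cat is not None:
            row["n_food_samples_detected"] = int(rng.integers(4, 40))
            for c in FOOD_CATEGORIES:
                if c == cat:
                    row[f"prevalence_{c}"] = float(rng.uniform(0.05, 0.6))
                else:
                    row[f"prevalence_{c}"] = float(rng.uniform(0.0, 0.0008))
        else:
            row["n_food_samples_detected"] = int(rng.integers(0, 4))
            for c in FOOD_CATEGORIES:
                row[f"prevalence_{c}"] = float(rng.uniform(0.0, 0.0008))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("feature_id")
    return FoodCatalogTable(df)


def simulate_health_ranks(config: SimulationConfig) -> pd.Series:
    """Per-feature cardiometabolic-health ranks in [0, 1] (0 = favourable).

    Features planted as enriched in the comparison diet (vegan by default)
    receive favourable ranks (~0.38) and reference-enriched features
    unfavourable ones (~0.53), so signature sets separate as in the study;
    everything else is uniform.
    """
    params = _feature_params(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1 << 22,)))
    ranks = rng.uniform(0.0, 1.0, size=config.n_features)
    for j, d in zip(params.signature_idx, params.smd):
        center = 0.38 if d > 0 else 0.53
        ranks[j] = np.clip(rng.normal(center, 0.08), 0.0, 1.0)
    return pd.Series(ranks, index=params.feature_ids, name="rank")


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Emit every artifact in the file dialects the io layer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, metadata, ffq, truth = simulate_cohorts(config)
    paths = {
        "abundance": str(outdir / "abundance.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "ffq": str(outdir / "ffq.tsv"),
        "group_map": str(outdir / "group_map.tsv"),
        "food_catalog": str(outdir / "food_catalog.tsv"),
        "health_ranks": str(outdir / "health_ranks.tsv"),
        "truth": str(outdir / "truth.json"),
        "config": str(outdir / "sim_config.json"),
    }
    write_abundance_table(table, paths["abundance"])
    write_metadata(metadata, paths["metadata"])
    write_ffq(ffq, paths["ffq"], paths["group_map"])
    write_food_catalog(simulate_food_catalog(config), paths["food_catalog"])
    write_health_ranks(simulate_health_ranks(config), paths["health_ranks"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=1, default=list)
    return paths
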