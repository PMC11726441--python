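"""End-to-end orchestration: simulate → score → diversity → meta-analysis →
machine-learning validation → food overlap, from a single config, with a
machine-readable run manifest.

Every stage writes plain-text artifacts into the run directory and records
their SHA-256 digests in the manifest; rerunning with the same config and
seed reproduces every deterministic output digest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diversity import beta_distance, kruskal_dunn, observed_richness, permanova_sequential, richness_outlier_filter
from .food_overlap import call_food_sgbs, compare_health_ranks, dunn_contrasts_food, per_sample_food_stats, presence_table, prevalence_chisq
from .hpdi import compute_hpdi
from .io_formats import (
    read_abundance_table, read_ffq, read_food_catalog, read_health_ranks,
    read_metadata, write_results,
)
from .meta_correlation import ELIGIBLE_DIETS, food_group_intake, run_correlation_meta
from .meta_diffabund import run_diffabund_meta
from .ml_validation import PROFILES, run_diet_classification
from .synthetic_data import SimulationConfig, simulate_to_dir

logger = logging.getLogger(__name__)

STAGES = ("simulate", "hpdi", "diversity", "diffabund", "corr", "ml", "food_overlap")

DEFAULT_CONFIG: dict = {
    "outdir": "dietbiome_run",
    "seed": 0,
    "profile": "scaled",
    "diet_pairs": [["omnivore", "vegan"]],
    "correlation_groups": ["dairy"],
    "permanova": {"metric": "bray_curtis", "n_perm": 999, "max_samples_per_cohort": 300},
    "simulate": {
        "cohort_sizes": [400, 400, 400],
        "n_features": 200,
        "n_signature_features": 10,
        "planted_smd": 1.0,
    },
    "inputs": {},  # abundance/metadata/ffq/group_map/food_catalog/health_ranks paths
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


class DependencyError(RuntimeError):
    """A stage's required input artifact is missing."""


def run_pipeline(
    config: dict | str | Path | None = None,
    stages: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    ``config`` may be a dict or a YAML path; missing keys fall back to
    :data:`DEFAULT_CONFIG`.  ``seed`` overrides the config seed and funnels
    every source of randomness.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    stages = tuple(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "stages": {},
    }
    inputs = dict(cfg.get("inputs") or {})

    def record(stage: str, outputs: dict[str, str], t0: float, note: str = "") -> None:
        manifest["stages"][stage] = {
            "outputs": {k: {"path": str(v), "sha256": _sha256(Path(v))} for k, v in outputs.items()},
            "seconds": round(time.time() - t0, 3),
            "note": note,
        }

    def need(*keys: str) -> None:
        missing = [k for k in keys if k not in inputs]
        if missing:
            raise DependencyError(
                f"missing input artifacts {missing}; run the 'simulate' stage or "
                "list their paths under config['inputs']"
            )

    if "simulate" in stages:
        t0 = time.time()
        sim_cfg = SimulationConfig.from_dict({**cfg["simulate"], "seed": seed})
        paths = simulate_to_dir(sim_cfg, outdir / "sim")
        inputs.update({k: v for k, v in paths.items()})
        record("simulate", paths, t0)

    profile_name = cfg.get("profile", "scaled")
    rf, n_repeats, n_folds = PROFILES[profile_name]

    table = metadata = ffq = None
    if set(stages) - {"simulate"}:
        need("abundance", "metadata")
        table = read_abundance_table(inputs["abundance"], dialect="plain_tsv")
        metadata = read_metadata(inputs["metadata"])

    if "hpdi" in stages:
        t0 = time.time()
        need("ffq", "group_map")
        ffq = read_ffq(inputs["ffq"], inputs["group_map"])
        scores = compute_hpdi(ffq, cohorts=metadata.data["cohort"])
        out = outdir / "hpdi.tsv"
        scores.scores.rename("hpdi").rename_axis("sample_id").reset_index().to_csv(
            out, sep="\t", index=False, float_format="%.10g"
        )
        inputs["hpdi"] = str(out)
        record("hpdi", {"hpdi": out}, t0, note=f"{len(scores.flagged)} samples flagged")

    if "diversity" in stages:
        t0 = time.time()
        rich = observed_richness(table)
        kept, removed = richness_outlier_filter(rich)
        alpha_rows = []
        for cohort in metadata.cohorts:
            ids = [s for s in kept if metadata.data.loc[s, "cohort"] == cohort]
            diets = metadata.data.loc[ids, "diet"]
            if diets.nunique() < 2:
                continue
            res = kruskal_dunn(rich.loc[ids].to_numpy(), diets.to_numpy())
            for _, row in res.pairwise.iterrows():
                alpha_rows.append({"cohort": cohort, "H": res.h, "kw_p": res.p, **row})
        perm_cfg = cfg["permanova"]
        perm_rows = []
        for cohort in metadata.cohorts:
            ids = metadata.data.index[metadata.data["cohort"] == cohort]
            ids = [s for s in ids if s in set(kept)]
            cap = perm_cfg.get("max_samples_per_cohort")
            if cap and len(ids) > cap:
                ids = list(pd.Index(ids)[:cap])
            sub_meta = metadata.subset(ids)
            if sub_meta.data["diet"].nunique() < 2:
                continue
            dm = beta_distance(table.subset_samples(ids), perm_cfg["metric"])
            terms = sub_meta.data[["sex", "age", "bmi", "diet"]]
            res = permanova_sequential(dm, terms, n_perm=perm_cfg["n_perm"], seed=seed)
            for term, row in res.terms.iterrows():
                perm_rows.append({"cohort": cohort, "term": term, **row})
        rich_out = outdir / "richness.tsv"
        rich.rename_axis("sample_id").reset_index().to_csv(rich_out, sep="\t", index=False)
        alpha_out = outdir / "alpha_dunn.tsv"
        write_results(pd.DataFrame(alpha_rows), alpha_out)
        perm_out = outdir / "permanova.tsv"
        write_results(pd.DataFrame(perm_rows), perm_out)
        record("diversity", {"richness": rich_out, "alpha_dunn": alpha_out, "permanova": perm_out},
               t0, note=f"{len(removed)} richness outliers removed")

    diffabund_results = {}
    if "diffabund" in stages:
        t0 = time.time()
        outs = {}
        for ref, cmp in cfg["diet_pairs"]:
            res = run_diffabund_meta(table, metadata, (ref, cmp))
            diffabund_results[(ref, cmp)] = res
            out = outdir / f"diffabund_{ref}_vs_{cmp}.tsv"
            write_results(res.frame, out)
            outs[f"{ref}_vs_{cmp}"] = out
        record("diffabund", outs, t0)

    if "corr" in stages:
        t0 = time.time()
        need("ffq", "group_map")
        if ffq is None:
            ffq = read_ffq(inputs["ffq"], inputs["group_map"])
        outs = {}
        for group in cfg["correlation_groups"]:
            intake = food_group_intake(ffq, group)
            eligible = ELIGIBLE_DIETS.get(group, ("omnivore", "vegetarian", "vegan"))
            res = run_correlation_meta(table, metadata, intake, eligible_diets=eligible)
            out = outdir / f"corr_{group}.tsv"
            write_results(res, out)
            outs[group] = out
        record("corr", outs, t0)

    if "ml" in stages:
        t0 = time.time()
        outs = {}
        for ref, cmp in cfg["diet_pairs"]:
            res = run_diet_classification(
                table, metadata, (ref, cmp), scheme="cross_lodo", rf=rf,
                n_repeats=n_repeats, n_folds=n_folds, seed=seed,
            )
            payload = {
                "scheme": res.scheme,
                "pair": list(res.pair),
                "mean_auc": res.mean_auc,
                "cohort_mean_aucs": res.cohort_mean_aucs,
            }
            out = outdir / f"ml_{ref}_vs_{cmp}.json"
            with open(out, "w") as fh:
                json.dump(payload, fh, indent=1)
            outs[f"{ref}_vs_{cmp}"] = out
        record("ml", outs, t0, note=f"profile={profile_name}")

    if "food_overlap" in stages:
        t0 = time.time()
        need("food_catalog")
        catalog = call_food_sgbs(read_food_catalog(inputs["food_catalog"]))
        stats_df = per_sample_food_stats(table, metadata, catalog, group_by_signature=True)
        stats_out = outdir / "food_stats.tsv"
        stats_df.rename_axis("sample_id").reset_index().to_csv(
            stats_out, sep="\t", index=False, float_format="%.10g"
        )
        contrasts = dunn_contrasts_food(stats_df)
        rows = []
        for key, res in contrasts.items():
            for _, row in res.pairwise.iterrows():
                rows.append({"stratum": "/".join(map(str, key)), "H": res.h, "kw_p": res.p, **row})
        dunn_out = outdir / "food_dunn.tsv"
        write_results(pd.DataFrame(rows), dunn_out)
        # prevalence chi-squared on the most common food features
        gut_food = [f for f in catalog.food_features if f in table.data.columns]
        prev = (table.data[gut_food] > 0).mean().sort_values(ascending=False)
        chisq_rows = []
        for feat in prev.index[: min(20, len(prev))]:
            tab = presence_table(table, metadata, feat)
            if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any():
                continue
            chi2, p = prevalence_chisq(tab, n_mc=9999, seed=seed)
            chisq_rows.append({"feature_id": feat, "chi2": chi2, "mc_p": p})
        chisq_out = outdir / "food_prevalence_chisq.tsv"
        write_results(pd.DataFrame(chisq_rows), chisq_out)
        outs = {"food_stats": stats_out, "food_dunn": dunn_out, "prevalence_chisq": chisq_out}
        if "health_ranks" in inputs and diffabund_results:
            ranks = read_health_ranks(inputs["health_ranks"])
            rank_rows = []
            for (ref, cmp), res in diffabund_results.items():
                sig = res.significant()
                up = [r.feature_id for r in res.results if r.feature_id in sig and r.pooled_d > 0]
                down = [r.feature_id for r in res.results if r.feature_id in sig and r.pooled_d < 0]
                if len(up) >= 2 and len(down) >= 2:
                    cmp_res = compare_health_ranks(up, down, ranks)
                    rank_rows.append({"pair": f"{ref}_vs_{cmp}", **dataclasses.asdict(cmp_res)})
            ranks_out = outdir / "health_rank_tests.json"
            with open(ranks_out, "w") as fh:
                json.dump(rank_rows, fh, indent=1)
            outs["health_rank_tests"] = ranks_out
        record("food_overlap", outs, t0)

    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
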