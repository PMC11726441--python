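"""Readers and writers for every on-disk artifact of the pipeline.

Abundance tables are held on the *percent* scale (the MetaPhlAn merged-profile
convention): per-sample feature abundances sum to at most 100, possibly less
when an unclassified fraction was dropped upstream.  Statistical transforms
that need proportions divide by 100 at the point of use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIET_LEVELS = ("omnivore", "vegetarian", "vegan")

#: taxonomic rank prefixes in MetaPhlAn lineage strings, shallow → deep
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__", "t__")

_SUM_TOL = 1e-6


class FormatError(ValueError):
    """Malformed on-disk artifact (bad header, duplicate ids, wrong columns)."""


class ValidationError(ValueError):
    """Well-formed file whose contents violate a domain invariant."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class AbundanceTable:
    """Samples × features relative abundances on the percent scale.

    ``data`` is indexed by sample id with feature ids as columns.  Values are
    nonnegative and every row sums to ≤ 100 (+ small tolerance).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("abundance table is empty")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in abundance table")
        if df.columns.duplicated().any():
            raise FormatError("duplicate feature ids in abundance table")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if (values < 0).any():
            raise ValidationError("negative abundance values")
        sums = values.sum(axis=1)
        if (sums > 100.0 + _SUM_TOL).any():
            bad = df.index[sums > 100.0 + _SUM_TOL][:3].tolist()
            raise ValidationError(f"per-sample abundance sums exceed 100: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, ids: Sequence[str]) -> "AbundanceTable":
        return AbundanceTable(self.data.loc[list(ids)])


@dataclass
class SampleMetadata:
    """Per-sample cohort, diet label and the covariates of every adjusted model."""

    data: pd.DataFrame  # index: sample_id; columns: cohort, diet, sex, age, bmi

    REQUIRED = ("cohort", "diet", "sex", "age", "bmi")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")
        bad = set(df["diet"]) - set(DIET_LEVELS)
        if bad:
            raise ValidationError(f"unknown diet labels: {sorted(bad)}")
        for col in ("age", "bmi"):
            vals = df[col].to_numpy(dtype=float)
            if np.nanmin(vals) <= 0:
                raise ValidationError(f"{col} must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.data["cohort"].unique())

    def subset(self, ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(ids)])


@dataclass
class FFQTable:
    """Food-frequency intakes (samples × items) plus the item → group mapping.

    ``group_map`` has one row per item with columns ``group`` and ``hpdi_flag``
    (``positive`` / ``reverse`` for the 18 hPDI groups, empty otherwise).
    Items absent from the map are kept as raw features but excluded from
    group-level sums.
    """

    intakes: pd.DataFrame  # index: sample_id; columns: item ids
    group_map: pd.DataFrame  # index: item; columns: group, hpdi_flag

    def __post_init__(self) -> None:
        if self.intakes.index.duplicated().any():
            raise FormatError("duplicate sample ids in FFQ intakes")
        if self.intakes.columns.duplicated().any():
            raise FormatError("duplicate item ids in FFQ intakes")
        vals = self.intakes.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValidationError("negative FFQ intake")
        unknown = set(self.group_map.index) - set(self.intakes.columns)
        if unknown:
            raise ValidationError(
                f"group map items absent from intake table: {sorted(unknown)[:5]}"
            )
        flags = set(self.group_map["hpdi_flag"].dropna()) - {"positive", "reverse", ""}
        if flags:
            raise ValidationError(f"unknown hPDI flags: {sorted(flags)}")
        by_group = self.group_map.dropna(subset=["hpdi_flag"])
        by_group = by_group[by_group["hpdi_flag"].isin(["positive", "reverse"])]
        mixed = by_group.groupby("group")["hpdi_flag"].nunique()
        if (mixed > 1).any():
            raise ValidationError(
                f"hPDI groups flagged both positive and reverse: "
                f"{mixed.index[mixed > 1].tolist()}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intakes.index)

    @property
    def item_ids(self) -> list[str]:
        return list(self.intakes.columns)

    def groups(self) -> list[str]:
        return sorted(self.group_map["group"].dropna().unique())

    def hpdi_groups(self) -> pd.Series:
        """group → flag for every group carrying an hPDI positive/reverse flag."""
        flagged = self.group_map[self.group_map["hpdi_flag"].isin(["positive", "reverse"])]
        return flagged.drop_duplicates("group").set_index("group")["hpdi_flag"]

    def items_in_group(self, group: str) -> list[str]:
        items = self.group_map.index[self.group_map["group"] == group].tolist()
        if not items:
            raise ValidationError(f"no FFQ items mapped to group {group!r}")
        return items


@dataclass
class FoodCatalogTable:
    """Per-feature summaries over food metagenomes (cFMD-style).

    ``prevalence`` columns (one per food category) hold the fraction of that
    category's food samples in which the feature was detected at ≥ the
    detection threshold (0.1 % relative abundance); ``n_food_samples_detected``
    counts detections across all food samples.
    """

    data: pd.DataFrame  # index: feature_id; columns: n_food_samples_detected + prevalence_<cat>

    def __post_init__(self) -> None:
        df = self.data
        if "n_food_samples_detected" not in df.columns:
            raise FormatError("catalog missing n_food_samples_detected")
        if (df["n_food_samples_detected"] < 0).any():
            raise ValidationError("negative food-sample detection counts")
        for col in self.prevalence_columns:
            v = df[col].to_numpy(dtype=float)
            if (v < 0).any() or (v > 1).any():
                raise ValidationError(f"prevalence column {col} outside [0,1]")

    @property
    def prevalence_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("prevalence_")]

    @property
    def categories(self) -> list[str]:
        return [c[len("prevalence_"):] for c in self.prevalence_columns]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _deepest_rank_prefix(clades: Iterable[str]) -> str:
    best = -1
    for clade in clades:
        last = clade.rsplit("|", 1)[-1]
        prefix = last[:3]
        if prefix in _RANK_PREFIXES:
            best = max(best, _RANK_PREFIXES.index(prefix))
    if best < 0:
        raise FormatError("no recognizable taxonomic rank prefixes in clade names")
    return _RANK_PREFIXES[best]


def read_abundance_table(path: str | Path, dialect: str = "plain_tsv") -> AbundanceTable:
    """Read an abundance table.

    ``metaphlan_merged``: '#'-prefixed comment lines, first column a
    '|'-delimited clade lineage, remaining columns samples; only rows at the
    deepest taxonomic rank present in the file are retained (the SGB /
    species level of a merged profile) and the feature id is the terminal
    lineage label.

    ``plain_tsv``: samples in rows (first column sample id), features in
    columns, already at a single feature level.
    """
    path = Path(path)
    if dialect == "plain_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return AbundanceTable(df)
    if dialect != "metaphlan_merged":
        raise ValueError(f"unknown dialect {dialect!r}")

    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#")
                if stripped.startswith("clade_name") or stripped.startswith("ID"):
                    header = stripped.split("\t")
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            rows.append(fields)
    if header is None or not rows:
        raise ValidationError(f"empty or header-only merged profile: {path}")

    clades = [r[0] for r in rows]
    deepest = _deepest_rank_prefix(clades)
    keep = [r for r in rows if r[0].rsplit("|", 1)[-1].startswith(deepest)]
    if not keep:
        raise ValidationError("no rows at the deepest taxonomic rank")
    sample_ids = header[1:]
    feature_ids = [r[0].rsplit("|", 1)[-1] for r in keep]
    if len(set(feature_ids)) != len(feature_ids):
        raise FormatError("duplicate terminal clade labels in merged profile")
    values = np.array([[float(x) for x in r[1:]] for r in keep], dtype=float)
    df = pd.DataFrame(values.T, index=sample_ids, columns=feature_ids)
    return AbundanceTable(df)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read per-sample metadata TSV; diet labels matched case-insensitively."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError("metadata missing sample_id column")
    df = df.set_index("sample_id")
    missing = [c for c in SampleMetadata.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    diet = df["diet"].astype(str).str.strip().str.lower()
    unknown = set(diet) - set(DIET_LEVELS)
    if unknown:
        raise ValidationError(f"unknown diet labels: {sorted(unknown)}")
    df["diet"] = diet
    df["sex"] = df["sex"].astype(str).str.strip().str.lower()
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.data.rename_axis("sample_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_abundance_table(
    table: AbundanceTable, path: str | Path, dialect: str = "plain_tsv"
) -> None:
    if dialect == "plain_tsv":
        table.data.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")
        return
    if dialect != "metaphlan_merged":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("#mpa_merged_profile\n")
        fh.write("clade_name\t" + "\t".join(table.sample_ids) + "\n")
        vals = table.values
        for j, feat in enumerate(table.feature_ids):
            fh.write(feat + "\t" + "\t".join(f"{v:.10g}" for v in vals[:, j]) + "\n")


def read_ffq(path: str | Path, group_map_path: str | Path) -> FFQTable:
    """Read FFQ intakes (CSV or TSV by extension) joined with a group map."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    intakes = pd.read_csv(path, sep=sep, index_col=0)
    intakes.index = intakes.index.astype(str)
    if (intakes.to_numpy(dtype=float) < 0).any():
        raise ValidationError("negative FFQ intake")
    gm = pd.read_csv(group_map_path, sep="\t", dtype=str).fillna("")
    for col in ("item", "group"):
        if col not in gm.columns:
            raise FormatError(f"group map missing column {col!r}")
    if "hpdi_flag" not in gm.columns:
        gm["hpdi_flag"] = ""
    gm = gm.set_index("item")
    unmapped = [c for c in intakes.columns if c not in gm.index]
    if unmapped:
        logger.warning(
            "%d FFQ items have no group mapping and are excluded from group sums: %s",
            len(unmapped), unmapped[:5],
        )
    return FFQTable(intakes=intakes, group_map=gm)


def write_ffq(ffq: FFQTable, intake_path: str | Path, group_map_path: str | Path) -> None:
    intake_path = Path(intake_path)
    sep = "," if intake_path.suffix.lower() == ".csv" else "\t"
    ffq.intakes.rename_axis("sample_id").to_csv(intake_path, sep=sep, float_format="%.10g")
    ffq.group_map.rename_axis("item").reset_index().to_csv(
        group_map_path, sep="\t", index=False
    )


def read_food_catalog(path: str | Path) -> FoodCatalogTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return FoodCatalogTable(df)


def write_food_catalog(catalog: FoodCatalogTable, path: str | Path) -> None:
    catalog.data.rename_axis("feature_id").to_csv(path, sep="\t", float_format="%.10g")


def read_health_ranks(path: str | Path) -> pd.Series:
    """Read a feature → health-rank table (rank in [0,1], 0 = favourable)."""
    df = pd.read_csv(path, sep="\t")
    if not {"feature_id", "rank"} <= set(df.columns):
        raise FormatError("health-rank table needs feature_id and rank columns")
    ranks = df.set_index("feature_id")["rank"].astype(float)
    if ((ranks < 0) | (ranks > 1)).any():
        raise ValidationError("health ranks outside [0,1]")
    return ranks


def write_health_ranks(ranks: pd.Series, path: str | Path) -> None:
    ranks.rename("rank").rename_axis("feature_id").reset_index().to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# generic results I/O
# ---------------------------------------------------------------------------


def _round_sig(x: float, sig: int = 10) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{sig}g}")


def results_to_frame(results) -> pd.DataFrame:
    """Coerce a result record set (DataFrame, mapping list, dataclass list)."""
    if isinstance(results, pd.DataFrame):
        return results
    records = []
    for rec in results:
        if hasattr(rec, "to_record"):
            records.append(rec.to_record())
        elif isinstance(rec, Mapping):
            records.append(dict(rec))
        else:  # plain dataclass
            records.append(vars(rec))
    return pd.DataFrame.from_records(records)


def write_results(results, path: str | Path, format: str = "tsv") -> None:
    """Write a result record set with deterministic column order and floats
    serialized at 10 significant digits; an empty set produces a header-only
    file (TSV) or an empty list (JSON)."""
    df = results_to_frame(results)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    elif format == "json":
        records = []
        for rec in df.to_dict(orient="records"):
            records.append(
                {k: _round_sig(v) if isinstance(v, float) else v for k, v in rec.items()}
            )
        with open(path, "w") as fh:
            json.dump({"columns": list(df.columns), "records": records}, fh, indent=1)
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            payload = json.load(fh)
        return pd.DataFrame.from_records(payload["records"], columns=payload["columns"])
    raise ValueError(f"unknown results format {format!r}")


def align_samples(
    table: AbundanceTable, metadata: SampleMetadata
) -> tuple[AbundanceTable, SampleMetadata]:
    """Intersect table and metadata on sample id.

    Samples present in the abundance table but absent from metadata are
    dropped with a warning (multi-cohort merges routinely have stragglers).
    """
    shared = [s for s in table.sample_ids if s in set(metadata.sample_ids)]
    dropped = len(table.sample_ids) - len(shared)
    if dropped:
        logger.warning("dropping %d abundance samples missing from metadata", dropped)
    if not shared:
        raise ValidationError("no overlap between abundance table and metadata")
    return table.subset_samples(shared), metadata.subset(shared)
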