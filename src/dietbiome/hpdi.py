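"""Healthful plant-based diet index (hPDI) from FFQ food-group intakes.

Eighteen food groups are each scored 1–5 by quintile of the scored
population's group-intake distribution: healthy plant groups score 5 in the
top quintile (positive direction), while less-healthy plant and animal
groups are reverse-scored (5 in the bottom quintile).  The index is the sum
of the 18 component scores, so it ranges over [18, 90].

The group composition and direction flags are data (they come with the FFQ
group map), not hard-coded: the instrument's item → group mapping varies by
study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FFQTable, ValidationError

logger = logging.getLogger(__name__)

N_HPDI_GROUPS = 18


class ConfigurationError(ValueError):
    """The FFQ group map cannot support the requested index."""


def quintile_score(intake: float, boundaries, direction: str) -> int:
    """Score a single intake 1–5 against 4 quintile cutpoints.

    Positive direction: above the largest cutpoint scores 5, below the
    smallest scores 1.  Reverse direction flips the mapping.  Ties at a
    boundary fall into the lower bin.
    """
    b = np.asarray(boundaries, dtype=float)
    if b.size != 4 or (np.diff(b) < 0).any():
        raise ValidationError("boundaries must be 4 nondecreasing cutpoints")
    if direction not in ("positive", "reverse"):
        raise ValidationError(f"unknown direction {direction!r}")
    bin_ = int(np.searchsorted(b, intake, side="left"))  # count of cutpoints < intake
    return 1 + bin_ if direction == "positive" else 5 - bin_


def _score_column(intakes: np.ndarray, boundaries: np.ndarray, direction: str) -> np.ndarray:
    bins = np.searchsorted(boundaries, intakes, side="left")
    return 1 + bins if direction == "positive" else 5 - bins


@dataclass
class HPDIScores:
    """Per-sample index plus the 1–5 component score of every group."""

    scores: pd.Series  # sample_id -> total (NaN when flagged)
    components: pd.DataFrame  # samples × groups
    flagged: list[str]  # samples with an unresolvable group intake


def compute_hpdi(
    ffq: FFQTable,
    cohorts: pd.Series | None = None,
    stratify_by_cohort: bool = True,
    allow_fewer_groups: bool = False,
) -> HPDIScores:
    """Quintile-score every flagged hPDI group and sum per sample.

    Quintile boundaries are computed from the scored population's group
    intakes — per cohort when ``cohorts`` is given and ``stratify_by_cohort``
    is true (each cohort's own distribution defines its quintiles), pooled
    otherwise.  Samples with any missing group intake are flagged, not
    silently scored.
    """
    flags = ffq.hpdi_groups()
    if len(flags) < N_HPDI_GROUPS and not allow_fewer_groups:
        raise ConfigurationError(
            f"hPDI needs {N_HPDI_GROUPS} flagged groups, found {len(flags)}; "
            "pass allow_fewer_groups=True for an n-group variant"
        )
    groups = list(flags.index)
    # per-sample group intakes (sum of mapped items)
    intake = pd.DataFrame(index=ffq.intakes.index)
    for g in groups:
        intake[g] = ffq.intakes[ffq.items_in_group(g)].sum(axis=1, min_count=1)

    if cohorts is not None and stratify_by_cohort:
        cohorts = cohorts.reindex(intake.index)
        strata = [intake.index[cohorts == c] for c in cohorts.dropna().unique()]
    else:
        strata = [intake.index]

    components = pd.DataFrame(np.nan, index=intake.index, columns=groups)
    for ids in strata:
        sub = intake.loc[ids]
        for g in groups:
            x = sub[g].to_numpy(dtype=float)
            ok = np.isfinite(x)
            if ok.sum() == 0:
                continue
            boundaries = np.quantile(x[ok], [0.2, 0.4, 0.6, 0.8])
            scored = np.full(x.shape, np.nan)
            scored[ok] = _score_column(x[ok], boundaries, flags[g])
            components.loc[ids, g] = scored

    complete = components.notna().all(axis=1)
    flagged = list(components.index[~complete])
    if flagged:
        logger.warning("%d samples flagged with unresolvable hPDI groups", len(flagged))
    totals = components.sum(axis=1).where(complete)
    return HPDIScores(scores=totals, components=components, flagged=flagged)
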