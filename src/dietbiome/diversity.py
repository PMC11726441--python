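"""Alpha and beta diversity statistics.

Alpha diversity is observed richness with a central-percentile outlier rule
and Kruskal–Wallis + Dunn/BH group comparisons.  Beta diversity covers
Bray–Curtis, Aitchison (CLR Euclidean with multiplicative pseudocount) and
unweighted/weighted UniFrac from a newick tree, plus an adonis2-style
sequential-term (Type-I) PERMANOVA with free permutation of sample rows.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import skbio
from skbio.diversity import beta_diversity as _skbio_beta

from .io_formats import AbundanceTable, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------


def observed_richness(table: AbundanceTable) -> pd.Series:
    """Number of features with strictly positive abundance per sample."""
    return pd.Series(
        (table.values > 0).sum(axis=1), index=table.sample_ids, name="observed_richness"
    )


def richness_outlier_filter(
    richness: pd.Series, level: float = 0.95
) -> tuple[list[str], list[str]]:
    """Retain samples inside the central ``level`` percentile interval.

    The interval is [ (1-level)/2, 1-(1-level)/2 ] percentiles of the
    richness distribution (2.5th–97.5th by default).  With fewer than 20
    samples no filtering is applied (warned).  Returns (retained, removed).
    """
    ids = list(richness.index)
    if len(ids) < 20:
        logger.warning("only %d samples; richness outlier filter skipped", len(ids))
        return ids, []
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(richness.to_numpy(dtype=float), [alpha, 1.0 - alpha])
    keep = (richness >= lo) & (richness <= hi)
    removed = list(richness.index[~keep])
    if removed:
        logger.info("richness outlier filter removed %d samples", len(removed))
    return list(richness.index[keep]), removed


@dataclass
class KruskalDunnResult:
    h: float
    p: float
    n_groups: int
    pairwise: pd.DataFrame  # group_a, group_b, z, p, q

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.pairwise[self.pairwise["q"] < q_threshold]


def kruskal_dunn(values, groups, min_group_size: int = 2) -> KruskalDunnResult:
    """Kruskal–Wallis omnibus test followed by Dunn's pairwise z tests.

    Dunn z uses rank-mean differences with the tie-corrected variance
    N(N+1)/12 − ΣT/(12(N−1)); pairwise p-values are BH-adjusted as one
    family.  Groups below ``min_group_size`` are excluded with a warning.
    """
    from .meta_diffabund import bh_adjust

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    small = labels[counts < min_group_size]
    if small.size:
        logger.warning("excluding groups with < %d samples: %s", min_group_size, list(small))
        keep = ~np.isin(groups, small)
        values, groups = values[keep], groups[keep]
        labels = labels[counts >= min_group_size]
    if labels.size < 2:
        raise ValidationError("need at least 2 groups with enough samples")

    samples = [values[groups == g] for g in labels]
    h, p = stats.kruskal(*samples)

    ranks = stats.rankdata(values)
    n = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    size = {g: int((groups == g).sum()) for g in labels}

    rows = []
    for i in range(labels.size):
        for j in range(i + 1, labels.size):
            a, b = labels[i], labels[j]
            se = np.sqrt(sigma2 * (1.0 / size[a] + 1.0 / size[b]))
            z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
            rows.append(
                {"group_a": a, "group_b": b, "z": z, "p": 2.0 * stats.norm.sf(abs(z))}
            )
    pw = pd.DataFrame(rows)
    pw["q"] = bh_adjust(pw["p"].to_numpy())
    return KruskalDunnResult(h=float(h), p=float(p), n_groups=int(labels.size), pairwise=pw)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative sample × sample distances with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValidationError("distance matrix shape mismatch")
        if np.abs(m - m.T).max() > 1e-12:
            raise ValidationError("distance matrix not symmetric")
        np.fill_diagonal(m, 0.0)
        if (m < 0).any():
            raise ValidationError("negative distances")
        self.matrix = m

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.sample_ids)

    def write(self, path: str | Path) -> None:
        self.frame.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(list(ids), self.matrix[np.ix_(idx, idx)])


def read_tree(path_or_newick: str | Path) -> skbio.TreeNode:
    """Read a newick tree from a path or a literal newick string."""
    text = str(path_or_newick)
    if text.strip().startswith("(") or text.strip().endswith(";"):
        return skbio.TreeNode.read(io.StringIO(text))
    return skbio.TreeNode.read(str(path_or_newick))


def beta_distance(
    table: AbundanceTable,
    metric: str,
    tree: skbio.TreeNode | str | Path | None = None,
    pseudocount: float | None = None,
) -> DistanceMatrix:
    """Pairwise sample distances under one of the supported metrics.

    ``bray_curtis`` on percent abundances; ``aitchison`` is Euclidean on the
    centered log-ratio of proportions after multiplicative pseudocount
    replacement of zeros (default: half the smallest nonzero proportion in
    the table); UniFrac metrics need a tree covering every feature.
    """
    X = table.values
    if (X.sum(axis=1) <= 0).any():
        raise ValidationError("zero-sum sample in abundance table")
    ids = table.sample_ids

    if metric == "bray_curtis":
        dm = _skbio_beta("braycurtis", X, ids=ids)
        return DistanceMatrix(ids, dm.data)
    if metric == "aitchison":
        P = X / X.sum(axis=1, keepdims=True)
        if pseudocount is None:
            nz = P[P > 0]
            pseudocount = 0.5 * nz.min()
        P = np.where(P > 0, P, pseudocount)
        P = P / P.sum(axis=1, keepdims=True)
        clr = np.log(P) - np.log(P).mean(axis=1, keepdims=True)
        return DistanceMatrix(ids, squareform(pdist(clr, metric="euclidean")))
    if metric in ("unifrac_unweighted", "unifrac_weighted"):
        if tree is None:
            raise ValidationError(f"{metric} requires a phylogenetic tree")
        if not isinstance(tree, skbio.TreeNode):
            tree = read_tree(tree)
        tips = {t.name for t in tree.tips()}
        missing = [f for f in table.feature_ids if f not in tips]
        if missing:
            raise ValidationError(f"features missing from tree: {missing[:5]}")
        name = "unweighted_unifrac" if metric == "unifrac_unweighted" else "weighted_unifrac"
        kwargs = {"tree": tree, "taxa": table.feature_ids}
        if metric == "unifrac_weighted":
            kwargs["normalized"] = True
        dm = _skbio_beta(name, X, ids=ids, **kwargs)
        return DistanceMatrix(ids, dm.data)
    raise ValueError(f"unknown beta-diversity metric {metric!r}")


def pcoa_coordinates(dist: DistanceMatrix, n_axes: int = 2) -> pd.DataFrame:
    """Classical MDS (PCoA) coordinates of a distance matrix, for plotting
    elsewhere; columns PCo1..PCon plus the proportion explained as attrs."""
    from skbio.stats.ordination import pcoa

    res = pcoa(skbio.DistanceMatrix(dist.matrix, ids=dist.sample_ids), number_of_dimensions=n_axes)
    coords = res.samples.iloc[:, :n_axes]
    coords.columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    coords.attrs["proportion_explained"] = list(res.proportion_explained[:n_axes])
    return coords


# ---------------------------------------------------------------------------
# sequential-term PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    terms: pd.DataFrame  # index: term names + Residual + Total; df, SumOfSqs, R2, F, p
    n_perm: int

    def r2(self, term: str) -> float:
        return float(self.terms.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


def _hat(X: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())))
    q = q[:, :rank]
    return q @ q.T, rank


def permanova_sequential(
    dist: DistanceMatrix,
    terms: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    scale_numeric: bool = True,
) -> PermanovaResult:
    """Sequential (Type-I) PERMANOVA on a Gower-centered distance matrix.

    Terms are added in column order (the caller fixes the order, e.g.
    sex, age, BMI, then diet last); each term's sum of squares is the
    increment in explained trace.  Permutation p-values freely permute
    sample rows of the distance matrix.  Categorical columns are dummy-coded;
    numeric columns are standardized when ``scale_numeric``.
    """
    terms = terms.loc[dist.sample_ids]
    n = len(dist.sample_ids)
    D2 = dist.matrix**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    ss_total = float(np.trace(G))

    blocks: list[tuple[str, np.ndarray]] = []
    for col in terms.columns:
        s = terms[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, drop_first=True).to_numpy(dtype=float)
            if dummies.shape[1] == 0:
                raise ValidationError(f"term {col!r} has a single level")
            blocks.append((col, dummies))
        else:
            x = s.to_numpy(dtype=float)
            if not np.isfinite(x).all():
                raise ValidationError(f"term {col!r} has missing values")
            if scale_numeric:
                sd = x.std(ddof=1)
                if sd == 0:
                    raise ValidationError(f"term {col!r} is constant")
                x = (x - x.mean()) / sd
            blocks.append((col, x[:, None]))

    X = np.ones((n, 1))
    hats, ranks = [], [1]
    for name, block in blocks:
        X = np.column_stack([X, block])
        H, rank = _hat(X)
        if rank <= ranks[-1]:
            raise ValidationError(f"singular model matrix at term {name!r}")
        hats.append(H)
        ranks.append(rank)

    def term_traces(Gmat: np.ndarray) -> np.ndarray:
        tr = np.array([float(np.sum(H * Gmat)) for H in hats])
        prev = np.concatenate([[0.0], tr[:-1]])
        return tr - prev

    ss_terms = term_traces(G)
    df_terms = np.diff(ranks)
    ss_res = ss_total - ss_terms.sum()
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    f_obs = (ss_terms / df_terms) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(blocks))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p = term_traces(Gp)
        ss_res_p = ss_total - ss_p.sum()
        f_p = (ss_p / df_terms) / (ss_res_p / df_res)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for (name, _), df_k, ss_k, f_k, p_k in zip(blocks, df_terms, ss_terms, f_obs, pvals):
        rows.append({"term": name, "df": int(df_k), "SumOfSqs": ss_k,
                     "R2": ss_k / ss_total, "F": f_k, "p": p_k})
    rows.append({"term": "Residual", "df": int(df_res), "SumOfSqs": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total,
                 "R2": 1.0, "F": np.nan, "p": np.nan})
    frame = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(terms=frame, n_perm=n_perm)
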