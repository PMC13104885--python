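"""Metabolic profiling stage 2: pathway activity scores and rankings.

The per-nucleus pathway activity score is the classic binned-control module
score: genes are binned by their dataset-wide average expression, each
pathway gene is matched with control genes drawn from its bin, and the
score is the mean expression of the pathway genes minus the mean of the
pooled control genes.  On top of the score matrix this module provides
dot-plot statistics (fraction of nuclei expressing, normalized level), the
Expression Power Index (EPI) ranking statistic, and the Wilcoxon rank-sum
differential-expression contract with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from .profiling import ClusterAssignment
from .simulate import PathwayCatalog, stable_seed

__all__ = [
    "ModuleScoreMatrix",
    "module_score",
    "score_all_pathways",
    "dotplot_stats",
    "expression_power_index",
    "wilcoxon_de",
]


def _lognorm_dense(adata: ad.AnnData) -> np.ndarray:
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize_log1p first: no 'lognorm' layer")
    x = adata.layers["lognorm"]
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x, float)


@dataclass
class ModuleScoreMatrix:
    """Nuclei x pathways activity scores with the scoring parameters used."""

    scores: pd.DataFrame  # index: nucleus ids, columns: pathway ids
    n_bins: int
    n_ctrl: int
    seed: int

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.columns)


def _expression_bins(avg: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bins of genes by average expression (rank-based)."""
    order = np.argsort(avg, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(avg.size)
    return (ranks * n_bins // avg.size).astype(int)


def module_score(
    adata: ad.AnnData,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control pathway activity score per nucleus.

    For each pathway gene, ``n_ctrl`` control genes are sampled from the
    gene's average-expression bin excluding the pathway's own genes
    (without replacement when the remaining bin holds at least ``n_ctrl``
    genes, with replacement otherwise; if exclusion empties a bin the full
    bin is used).  The score is mean(pathway genes) - mean(pooled
    controls) on the log-normalized layer.  Deterministic for a fixed
    seed.
    """
    x = _lognorm_dense(adata)
    gene_index = {g: i for i, g in enumerate(adata.var_names)}
    set_idx = [gene_index[g] for g in gene_set if g in gene_index]
    if not set_idx:
        raise ValueError("gene set is entirely absent from the matrix")
    in_set = np.zeros(x.shape[1], dtype=bool)
    in_set[set_idx] = True
    avg = x.mean(axis=0)
    bins = _expression_bins(avg, n_bins)
    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        bin_members = np.where((bins == bins[gi]) & ~in_set)[0]
        if bin_members.size == 0:
            bin_members = np.where(bins == bins[gi])[0]
        replace = bin_members.size < n_ctrl
        ctrl_idx.append(rng.choice(bin_members, size=n_ctrl, replace=replace))
    ctrl = np.concatenate(ctrl_idx)
    # C-contiguous gathers so the reduction order is layout-independent
    set_sub = np.ascontiguousarray(x[:, set_idx])
    ctrl_sub = np.ascontiguousarray(x[:, ctrl])
    return set_sub.mean(axis=1) - ctrl_sub.mean(axis=1)


def score_all_pathways(
    adata: ad.AnnData,
    catalog: PathwayCatalog,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreMatrix:
    """Score every catalog pathway; one column per pathway, catalog order.

    Each pathway's control sampling is seeded from (seed, pathway_id), so a
    pathway's score column does not depend on the catalog's ordering.
    Pathways with no gene present in the matrix are dropped with a warning.
    """
    columns: dict[str, np.ndarray] = {}
    for pw in catalog:
        try:
            columns[pw.pathway_id] = module_score(
                adata,
                list(pw.genes),
                n_bins=n_bins,
                n_ctrl=n_ctrl,
                seed=stable_seed(seed, "module_score", pw.pathway_id),
            )
        except ValueError:
            warnings.warn(
                f"pathway {pw.pathway_id!r} has no gene in the matrix; dropped",
                stacklevel=2,
            )
    if not columns:
        raise ValueError("no catalog pathway has any gene in the matrix")
    scores = pd.DataFrame(columns, index=adata.obs_names)
    return ModuleScoreMatrix(scores=scores, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)


def dotplot_stats(
    values: pd.DataFrame, groups: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Dot-plot statistics per (group, column).

    ``fraction`` = share of the group's nuclei with value > 0 (dot size);
    ``mean`` = raw group mean; ``norm_level`` = the mean min-max normalized
    across groups within each column (dot color).
    """
    groups = pd.Series(np.asarray(groups), index=values.index)
    sizes = groups.value_counts()
    if (sizes == 0).any() or sizes.empty:
        raise ValueError("every group must be non-empty")
    frac = (values > 0).groupby(groups).mean()
    mean = values.groupby(groups).mean()
    rng_span = mean.max(axis=0) - mean.min(axis=0)
    norm = (mean - mean.min(axis=0)) / rng_span.replace(0.0, np.nan)
    norm = norm.fillna(0.0)
    out = pd.concat(
        {"fraction": frac.stack(), "mean": mean.stack(), "norm_level": norm.stack()},
        axis=1,
    )
    out.index.names = ["group", "pathway"]
    return out


def expression_power_index(
    scores: ModuleScoreMatrix, assignment: ClusterAssignment
) -> pd.DataFrame:
    """EPI = expression frequency x expression level, ranked per cluster.

    Per (cluster, pathway): f = fraction of the cluster's nuclei with score
    > 0, m = mean score over the cluster's nuclei, EPI = f * max(m, 0).
    Pathways are ranked by EPI descending within each cluster; ties break
    alphabetically by pathway id.
    """
    labels = np.asarray(assignment.labels)
    if labels.size != len(scores.scores):
        raise ValueError("assignment does not cover the score matrix")
    rows = []
    for k in range(assignment.n_clusters):
        members = scores.scores.iloc[labels == k]
        if members.empty:
            raise ValueError(f"cluster {k} is empty")
        f = (members > 0).mean(axis=0)
        m = members.mean(axis=0)
        epi = f * np.maximum(m, 0.0)
        sub = pd.DataFrame(
            {"cluster": k, "pathway": scores.pathway_ids, "frequency": f.values,
             "level": m.values, "epi": epi.values}
        )
        sub = sub.sort_values(["epi", "pathway"], ascending=[False, True], kind="stable")
        sub["rank"] = np.arange(1, len(sub) + 1)
        rows.append(sub)
    return pd.concat(rows, ignore_index=True).set_index(["cluster", "pathway"])


def wilcoxon_de(
    adata: ad.AnnData,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_fraction: float = 0.10,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two nucleus subsets.

    Tests genes detected (raw count > 0) in at least ``min_fraction`` of
    either group.  log2FC = log2((mean expm1 A + 1) / (mean expm1 B + 1))
    on the log-normalized layer; P-values are BH-adjusted over tested
    genes; ``significant`` marks adjusted P < ``alpha_fdr``.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if group_a.dtype == bool:
        group_a = np.where(group_a)[0]
    if group_b.dtype == bool:
        group_b = np.where(group_b)[0]
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    if group_a.size == 0 or group_b.size == 0:
        raise ValueError("both groups must be non-empty")

    x = _lognorm_dense(adata)
    counts = adata.layers["counts"]
    detected = counts > 0
    detected = np.asarray(detected.todense()) if sparse.issparse(detected) else detected
    frac_a = detected[group_a].mean(axis=0)
    frac_b = detected[group_b].mean(axis=0)
    tested = np.where((frac_a >= min_fraction) | (frac_b >= min_fraction))[0]
    if tested.size == 0:
        raise ValueError("no gene passes the expression-fraction filter")

    xa, xb = x[np.ix_(group_a, tested)], x[np.ix_(group_b, tested)]
    res = stats.mannwhitneyu(xa, xb, axis=0, alternative="two-sided")
    pvals = np.atleast_1d(res.pvalue)
    log2fc = np.log2((np.expm1(xa).mean(axis=0) + 1.0) / (np.expm1(xb).mean(axis=0) + 1.0))
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": np.asarray(adata.var_names)[tested],
            "log2fc": log2fc,
            "pval": pvals,
            "padj": padj,
            "frac_a": frac_a[tested],
            "frac_b": frac_b[tested],
            "significant": padj < alpha_fdr,
        }
    ).set_index("gene")
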