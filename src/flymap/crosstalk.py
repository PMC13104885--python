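"""Differential gut-to-brain ligand-receptor (L-R) crosstalk analysis.

For every (source gut cluster, target brain cluster, curated L-R pair) the
interaction score is the product of the ligand's mean log-normalized
expression over the source nuclei and the receptor's over the target
nuclei — zero when either side is silent, monotone in both.  Pair
significance is the more conservative of two rank-sum enrichment tests
(ligand in source vs the rest of its tissue, receptor in target vs the
rest of its tissue).  Pairs are kept when P < 0.05 and both genes are
expressed in more than 10% of the relevant nuclei; differential levels are
score(A) - score(B) between conditions; aggregates count significantly
differential pairs per cluster (clusters under 10 pairs are reported as
omitted) and compare interaction levels per signaling category.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "LRPair",
    "expression_fraction",
    "lr_score",
    "pair_significance",
    "score_lr_table",
    "filter_pairs",
    "differential_lr",
    "correlate_conditions",
    "aggregate_by_cluster",
    "category_comparison",
]

_KEY = ["source_cluster", "target_cluster", "ligand", "receptor"]


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    pathway: str

    def __post_init__(self):
        if self.ligand == self.receptor:
            raise ValueError("ligand and receptor must be distinct genes")
        if not self.pathway:
            raise ValueError("pathway label must be non-empty")


def _dense(layer) -> np.ndarray:
    return np.asarray(layer.todense()) if sparse.issparse(layer) else np.asarray(layer)


def _gene_col(adata: ad.AnnData, gene: str, layer: str) -> np.ndarray:
    if gene not in adata.var_names:
        raise ValueError(f"gene {gene!r} absent from the matrix")
    j = adata.var_names.get_loc(gene)
    return _dense(adata.layers[layer][:, j]).ravel()


def expression_fraction(adata: ad.AnnData, cluster: np.ndarray, gene: str) -> float:
    """Fraction of the cluster's nuclei with raw count > 0 for ``gene``."""
    cluster = np.asarray(cluster)
    if cluster.dtype == bool:
        cluster = np.where(cluster)[0]
    if cluster.size == 0:
        raise ValueError("cluster is empty")
    col = _gene_col(adata, gene, "counts")
    return float((col[cluster] > 0).mean())


def lr_score(
    source_adata: ad.AnnData,
    target_adata: ad.AnnData,
    source: np.ndarray,
    target: np.ndarray,
    pair: LRPair,
) -> float:
    """Product of mean log-normalized ligand (source) and receptor (target)."""
    source = np.asarray(source)
    target = np.asarray(target)
    if source.dtype == bool:
        source = np.where(source)[0]
    if target.dtype == bool:
        target = np.where(target)[0]
    if source.size == 0 or target.size == 0:
        raise ValueError("source and target clusters must be non-empty")
    lig = _gene_col(source_adata, pair.ligand, "lognorm")[source].mean()
    rec = _gene_col(target_adata, pair.receptor, "lognorm")[target].mean()
    return float(lig * rec)


def _enrichment_p(values: np.ndarray, inside: np.ndarray) -> float:
    mask = np.zeros(values.size, dtype=bool)
    mask[inside] = True
    if mask.all():
        raise ValueError("cluster equals the whole tissue; no background to test against")
    a, b = values[mask], values[~mask]
    if np.all(a == a[0]) and np.all(b == a[0]):
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)


def pair_significance(
    source_adata: ad.AnnData,
    target_adata: ad.AnnData,
    source: np.ndarray,
    target: np.ndarray,
    pair: LRPair,
) -> float:
    """Max of the two one-sided enrichment rank-sum P-values.

    Both the ligand (source cluster vs rest of its tissue) and the receptor
    (target cluster vs rest of its tissue) must be enriched for the pair to
    be significant; taking the max enforces that conservatively.
    """
    source = np.asarray(source)
    target = np.asarray(target)
    if source.dtype == bool:
        source = np.where(source)[0]
    if target.dtype == bool:
        target = np.where(target)[0]
    p_lig = _enrichment_p(_gene_col(source_adata, pair.ligand, "lognorm"), source)
    p_rec = _enrichment_p(_gene_col(target_adata, pair.receptor, "lognorm"), target)
    return max(p_lig, p_rec)


def score_lr_table(
    source_adata: ad.AnnData,
    target_adata: ad.AnnData,
    pairs: pd.DataFrame,
    source_clusters: dict[str, np.ndarray],
    target_clusters: dict[str, np.ndarray],
    with_significance: bool = True,
) -> pd.DataFrame:
    """Score every (source cluster, target cluster, pair) combination.

    ``pairs`` needs columns ``ligand, receptor, pathway``; cluster dicts map
    cluster names to nucleus index arrays within their tissue's AnnData.
    Returns one row per combination with score, expression fractions and
    (optionally) the pair P-value.
    """
    rows = []
    for _, row in pairs.iterrows():
        pair = LRPair(row["ligand"], row["receptor"], row["pathway"])
        for s_name, s_idx in source_clusters.items():
            for t_name, t_idx in target_clusters.items():
                rec = {
                    "source_cluster": s_name,
                    "target_cluster": t_name,
                    "ligand": pair.ligand,
                    "receptor": pair.receptor,
                    "pathway": pair.pathway,
                    "score": lr_score(source_adata, target_adata, s_idx, t_idx, pair),
                    "ligand_fraction": expression_fraction(source_adata, s_idx, pair.ligand),
                    "receptor_fraction": expression_fraction(target_adata, t_idx, pair.receptor),
                }
                if with_significance:
                    rec["pval"] = pair_significance(
                        source_adata, target_adata, s_idx, t_idx, pair
                    )
                rows.append(rec)
    return pd.DataFrame(rows)


def filter_pairs(
    table: pd.DataFrame, alpha: float = 0.05, min_fraction: float = 0.10
) -> pd.DataFrame:
    """Keep rows with P < alpha and both expression fractions > min_fraction.

    All three inequalities are strict ("more than 10% of nuclei";
    P = 0.05 exactly does not pass).
    """
    keep = (
        (table["pval"] < alpha)
        & (table["ligand_fraction"] > min_fraction)
        & (table["receptor_fraction"] > min_fraction)
    )
    return table.loc[keep].copy()


def differential_lr(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Differential interaction level: delta = score(A) - score(B) per row.

    Positive delta means up-regulation in condition A.  Both tables must
    cover the same (source, target, pair) universe.
    """
    a = table_a.set_index(_KEY)
    b = table_b.set_index(_KEY)
    if set(a.index) != set(b.index):
        raise ValueError("tables cover different (source, target, pair) universes")
    b = b.reindex(a.index)
    out = a.copy()
    out = out.rename(columns={"score": "score_a", "pval": "pval_a"})
    out["score_b"] = b["score"]
    if "pval" in b.columns:
        out["pval_b"] = b["pval"]
    out["delta"] = out["score_a"] - out["score_b"]
    return out.reset_index()


def correlate_conditions(
    table_a: pd.DataFrame, table_b: pd.DataFrame, n_outliers: int = 5
) -> dict:
    """Pearson correlation of per-pair scores between two conditions.

    Also ranks the rows by absolute residual from the least-squares line of
    score_a on score_b and reports the ``n_outliers`` most discordant pairs.
    """
    a = table_a.set_index(_KEY)["score"]
    b = table_b.set_index(_KEY)["score"]
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common rows to correlate conditions")
    xa, xb = a.loc[common].to_numpy(), b.loc[common].to_numpy()
    r, p = stats.pearsonr(xa, xb)
    slope, intercept = np.polyfit(xb, xa, 1)
    resid = np.abs(xa - (slope * xb + intercept))
    order = np.argsort(-resid, kind="stable")
    outliers = [
        {"row": tuple(common[i]), "abs_residual": float(resid[i]), "rank": rank + 1}
        for rank, i in enumerate(order[:n_outliers])
    ]
    return {"r": float(r), "pval": float(p), "n": int(len(common)), "outliers": outliers}


def aggregate_by_cluster(
    differential: pd.DataFrame, min_pairs: int = 10, alpha: float = 0.05
) -> dict:
    """Count significantly differential pairs per source and target cluster.

    A row counts when its pair is significant in either condition (P <
    alpha) and delta != 0.  Clusters with fewer than ``min_pairs`` such
    pairs are listed as omitted (with the reason), mirroring the convention
    of dropping sparsely connected clusters from chord diagrams.
    """
    sig = pd.Series(False, index=differential.index)
    for col in ("pval_a", "pval_b"):
        if col in differential.columns:
            sig |= differential[col] < alpha
    sig &= differential["delta"] != 0
    report: dict = {"source_clusters": {}, "target_clusters": {}, "omitted": []}
    for side, key in (("source_clusters", "source_cluster"), ("target_clusters", "target_cluster")):
        counts = differential.loc[sig].groupby(key, observed=True).size()
        for cluster in differential[key].unique():
            c = int(counts.get(cluster, 0))
            if c >= min_pairs:
                report[side][cluster] = c
            else:
                report["omitted"].append(
                    {"cluster": str(cluster), "side": side, "count": c,
                     "reason": f"fewer than {min_pairs} differential L-R pairs"}
                )
    return report


def category_comparison(
    table_a: pd.DataFrame, table_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-category comparison of interaction levels between conditions.

    Every row must carry a ``pathway`` category label.  Per category: mean
    score per condition and a two-sided rank-sum P over member-pair scores;
    categories at P >= alpha are flagged ``shown = False``; single-pair
    categories are compared but flagged ``small_n``.
    """
    for t in (table_a, table_b):
        if t["pathway"].isna().any() or (t["pathway"] == "").any():
            raise ValueError("every pair must be mapped to a category")
    rows = []
    cats = sorted(set(table_a["pathway"]) | set(table_b["pathway"]))
    for cat in cats:
        sa = table_a.loc[table_a["pathway"] == cat, "score"].to_numpy()
        sb = table_b.loc[table_b["pathway"] == cat, "score"].to_numpy()
        if sa.size == 0 or sb.size == 0:
            raise ValueError(f"category {cat!r} missing from one condition")
        if np.all(sa == sa[0]) and np.all(sb == sa[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(sa, sb, alternative="two-sided").pvalue)
        rows.append(
            {
                "category": cat,
                "mean_a": float(sa.mean()),
                "mean_b": float(sb.mean()),
                "n_pairs": int(min(sa.size, sb.size)),
                "pval": p,
                "shown": p < alpha,
                "small_n": bool(min(sa.size, sb.size) < 2),
            }
        )
    return pd.DataFrame(rows).set_index("category")
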