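"""Metabolic profiling stage 3: pathway coordination analysis.

Within each condition, pathway activity scores are correlated pairwise
(Pearson, across all of the condition's nuclei), hierarchically ordered
(average linkage on 1 - r), masked at P < 0.05, and segmented into
correlation modules — contiguous dendrogram groups of at least ``min_size``
pathways whose mean pairwise correlation clears a threshold and whose
member pairs are predominantly significant.  Modules found in two
conditions are matched by Jaccard overlap to separate a conserved core
from condition-specific coordination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .scoring import ModuleScoreMatrix

__all__ = [
    "CorrelationMap",
    "CorrelationModule",
    "pathway_correlation",
    "order_by_hclust",
    "significance_mask",
    "detect_modules",
    "compare_conditions",
]


@dataclass
class CorrelationMap:
    """Pathway x pathway Pearson correlations with matched P-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_nuclei: int
    condition: str | None = None
    ordering: list[str] | None = None

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.r.columns)


@dataclass
class CorrelationModule:
    members: tuple[str, ...]
    mean_r: float
    sig_fraction: float


def pathway_correlation(
    scores: ModuleScoreMatrix,
    subset: np.ndarray | None = None,
    condition: str | None = None,
) -> CorrelationMap:
    """Pairwise Pearson correlation of pathway scores over a nucleus subset.

    P-values come from the t-transform of r with n - 2 degrees of freedom.
    Zero-variance pathways yield NaN correlations (reported missing, not an
    error); the diagonal P is 0 by convention and excluded from masks.
    """
    df = scores.scores if subset is None else scores.scores.iloc[np.asarray(subset)]
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 nuclei to correlate pathways")
    if df.shape[1] < 2:
        raise ValueError("need at least 2 pathways")
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.ix_(sd == 0, np.arange(x.shape[1]))] = np.nan
    r[np.ix_(np.arange(x.shape[1]), sd == 0)] = np.nan
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rr * np.sqrt((n - 2) / (1.0 - rr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rr) >= 1.0] = 0.0
    p[np.isnan(rr)] = np.nan
    np.fill_diagonal(p, 0.0)
    cols = df.columns
    return CorrelationMap(
        r=pd.DataFrame(rr, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n_nuclei=n,
        condition=condition,
    )


def _linkage(corr: CorrelationMap):
    r = corr.r.to_numpy(dtype=float).copy()
    if np.isnan(r).any():
        warnings.warn("missing correlations imputed as 0 for ordering", stacklevel=3)
        r = np.nan_to_num(r, nan=0.0)
        np.fill_diagonal(r, 1.0)
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="average")


def order_by_hclust(corr: CorrelationMap) -> list[str]:
    """Dendrogram leaf order from average-linkage clustering on 1 - r."""
    if len(corr.pathway_ids) < 2:
        raise ValueError("need at least 2 pathways to order")
    leaves = hierarchy.leaves_list(_linkage(corr))
    ordering = [corr.pathway_ids[i] for i in leaves]
    corr.ordering = ordering
    return ordering


def significance_mask(corr: CorrelationMap, alpha: float = 0.05) -> pd.DataFrame:
    """Boolean mask of off-diagonal correlations with P < alpha."""
    p = corr.p.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        m = (p < alpha) & ~np.isnan(p)
    np.fill_diagonal(m, False)
    return pd.DataFrame(m, index=corr.p.index, columns=corr.p.columns)


def detect_modules(
    corr: CorrelationMap,
    ordering: list[str] | None = None,
    min_size: int = 3,
    r_threshold: float = 0.3,
    sig_fraction: float = 0.8,
    alpha: float = 0.05,
) -> list[CorrelationModule]:
    """Correlation modules from a dendrogram cut at distance 1 - r_threshold.

    A group qualifies when it has >= ``min_size`` members, mean pairwise r
    >= ``r_threshold``, and >= ``sig_fraction`` of its member pairs
    significant at ``alpha``.  Modules are returned in dendrogram leaf
    order; pairs with missing r are excluded from the module statistics.
    """
    if ordering is None:
        ordering = order_by_hclust(corr)
    z = _linkage(corr)
    flat = hierarchy.fcluster(z, t=1.0 - r_threshold, criterion="distance")
    ids = corr.pathway_ids
    leaf_pos = {pid: i for i, pid in enumerate(ordering)}
    rmat, pmat = corr.r, corr.p
    modules = []
    for group in np.unique(flat):
        members = [ids[i] for i in np.where(flat == group)[0]]
        if len(members) < min_size:
            continue
        members = sorted(members, key=leaf_pos.__getitem__)
        sub_r = rmat.loc[members, members].to_numpy()
        sub_p = pmat.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        pair_r, pair_p = sub_r[iu], sub_p[iu]
        ok = ~np.isnan(pair_r)
        if not ok.any():
            continue
        mean_r = float(pair_r[ok].mean())
        sig = float((pair_p[ok] < alpha).mean())
        if mean_r >= r_threshold and sig >= sig_fraction:
            modules.append(CorrelationModule(tuple(members), mean_r, sig))
    modules.sort(key=lambda m: leaf_pos[m.members[0]])
    return modules


def compare_conditions(
    modules_a: list[CorrelationModule],
    modules_b: list[CorrelationModule],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Match modules across two conditions by Jaccard overlap.

    A module is ``shared`` when some counterpart in the other condition
    overlaps it at Jaccard >= 0.5, otherwise ``condition-specific``.
    """
    if universe is not None:
        for mods, name in ((modules_a, "A"), (modules_b, "B")):
            for m in mods:
                extra = set(m.members) - universe
                if extra:
                    raise ValueError(
                        f"module in condition {name} uses pathways outside the "
                        f"common universe: {sorted(extra)[:3]}"
                    )
    rows = []
    for cond, own, other in (("A", modules_a, modules_b), ("B", modules_b, modules_a)):
        for i, m in enumerate(own):
            best_j, best_k = 0.0, None
            for k, o in enumerate(other):
                s, t = set(m.members), set(o.members)
                j = len(s & t) / len(s | t)
                if j > best_j:
                    best_j, best_k = j, k
            rows.append(
                {
                    "condition": cond,
                    "module": i,
                    "size": len(m.members),
                    "members": ";".join(m.members),
                    "best_jaccard": best_j,
                    "counterpart": best_k,
                    "status": "shared" if best_j >= 0.5 else "condition-specific",
                }
            )
    return pd.DataFrame(rows)
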