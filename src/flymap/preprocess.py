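"""Quality filtering, normalization, and metabolic-matrix extraction.

Single-nucleus counts arrive as an :class:`anndata.AnnData` with a
``layers["counts"]`` matrix (nuclei x genes).  QC keeps nuclei by their
detected-gene count within a closed tissue-specific interval (200-1,600 for
brain, 200-3,000 for gut); normalization is counts-per-10,000 followed by
log1p; the metabolic matrix is the restriction of the gene set to the union
of a metabolic pathway catalog.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import scanpy as sc
from scipy import sparse

from .simulate import PathwayCatalog

__all__ = [
    "QCThresholds",
    "BRAIN_QC",
    "GUT_QC",
    "detected_genes",
    "filter_by_gene_count",
    "normalize_log1p",
    "select_metabolic_genes",
    "top_decile_select",
]


@dataclass(frozen=True)
class QCThresholds:
    """Closed interval of acceptable detected-gene counts per nucleus."""

    min_genes: int
    max_genes: int

    def __post_init__(self):
        if not (0 < self.min_genes <= self.max_genes):
            raise ValueError("need 0 < min_genes <= max_genes")


#: Tissue defaults: 200-1,600 detected genes for brain nuclei; the upper
#: bound is extended to 3,000 for gut nuclei (higher gut RNA content).
BRAIN_QC = QCThresholds(200, 1600)
GUT_QC = QCThresholds(200, 3000)


def _counts(adata: ad.AnnData):
    if "counts" not in adata.layers:
        raise ValueError("AnnData must carry a 'counts' layer of raw counts")
    return adata.layers["counts"]


def detected_genes(adata: ad.AnnData) -> np.ndarray:
    """Number of genes with raw count > 0 per nucleus."""
    counts = _counts(adata)
    if sparse.issparse(counts):
        return np.asarray((counts > 0).sum(axis=1)).ravel()
    return (counts > 0).sum(axis=1)


def filter_by_gene_count(
    adata: ad.AnnData, thresholds: QCThresholds
) -> tuple[ad.AnnData, dict]:
    """Keep nuclei whose detected-gene count lies in the closed QC interval.

    Returns the filtered copy and a retention report
    ``{"kept": int, "removed": int, "thresholds": (min, max)}``.
    """
    n_detected = detected_genes(adata)
    keep = (n_detected >= thresholds.min_genes) & (n_detected <= thresholds.max_genes)
    report = {
        "kept": int(keep.sum()),
        "removed": int((~keep).sum()),
        "thresholds": (thresholds.min_genes, thresholds.max_genes),
    }
    return adata[keep].copy(), report


def normalize_log1p(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Counts-per-``scale`` log1p normalization into ``layers["lognorm"]``.

    Per nucleus: value = ln(1 + count * scale / total_counts).  Delegates to
    scanpy's normalize_total + log1p, which implement exactly this formula.
    """
    counts = _counts(adata)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[np.where(totals == 0)[0]].tolist()
        raise ValueError(f"nuclei with zero total counts cannot be normalized: {bad[:5]}")
    out = adata.copy()
    out.X = counts.copy().astype(np.float64)
    sc.pp.normalize_total(out, target_sum=scale)
    sc.pp.log1p(out)
    out.layers["lognorm"] = out.X.copy()
    return out


def select_metabolic_genes(
    adata: ad.AnnData, catalog: PathwayCatalog
) -> tuple[ad.AnnData, dict]:
    """Restrict the gene set to the catalog's gene union.

    Gene order follows the matrix's existing order; catalog genes absent
    from the matrix are reported, not an error.  Idempotent.
    """
    if len(catalog) == 0:
        raise ValueError("pathway catalog is empty")
    union = set(catalog.gene_union())
    keep_mask = adata.var_names.isin(union)
    if not keep_mask.any():
        raise ValueError("no catalog gene is present in the expression matrix")
    present = set(adata.var_names[keep_mask])
    report = {
        "n_selected": int(keep_mask.sum()),
        "absent_from_matrix": sorted(union - present),
    }
    return adata[:, keep_mask].copy(), report


def top_decile_select(values: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Indices of the ceil(fraction * n) largest values, stable under ties.

    Mirrors the convention of restricting single-nucleus comparisons to the
    top 10% of nuclei per group; ties are broken by input order.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("need at least one value")
    k = int(np.ceil(fraction * n))
    order = np.argsort(-values, kind="stable")  # stable: first-come wins ties
    return np.sort(order[:k])
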