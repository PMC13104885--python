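"""Metabolic profiling stage 1: embedding, clustering, occupancy, composition.

Nuclei are clustered on the metabolic expression matrix alone: per-gene
z-scaling (clipped at +-10), PCA, a kneedle elbow diagnostic for choosing
dimensionality, a Jaccard-weighted shared-nearest-neighbor graph, and
Leiden community detection at a given resolution.  Downstream comparisons
quantify each cluster's occupancy (the share of a condition's nuclei it
holds, compared across conditions as a fold change) and the cell-type
composition transferred from whole-transcriptome annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "Embedding",
    "ClusterAssignment",
    "scale_and_embed",
    "elbow_point",
    "snn_graph",
    "cluster_nuclei",
    "occupancy",
    "transfer_composition",
]


@dataclass
class Embedding:
    coordinates: np.ndarray  # nuclei x components
    component_sds: np.ndarray  # non-increasing
    n_components: int


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # per-nucleus small integers, contiguous from 0
    resolution: float
    seed: int
    nucleus_ids: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def scale_and_embed(
    adata: ad.AnnData, n_components: int = 30, clip: float = 10.0, seed: int = 0
) -> Embedding:
    """Z-scale genes (clip +-``clip``), then project onto principal components.

    Constant genes get all-zero scaled values rather than an error.
    Component standard deviations are returned in decreasing order.
    """
    if "lognorm" not in adata.layers:
        raise ValueError("run normalize_log1p first: no 'lognorm' layer")
    x = adata.layers["lognorm"]
    x = np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x, float)
    n_components = int(min(n_components, *x.shape))
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)  # constant genes scale to zero
    z = np.clip((x - mean) / sd_safe, -clip, clip)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(z)
    sds = coords.std(axis=0, ddof=1)
    return Embedding(coordinates=coords, component_sds=sds, n_components=n_components)


def elbow_point(component_sds: np.ndarray) -> int:
    """Kneedle elbow: the component count maximizing the perpendicular
    distance from (index, sd) to the chord joining the first and last points.

    Returns a 1-based count.  A strictly linear decay has zero distance
    everywhere; the convention is to return 1.
    """
    sds = np.asarray(component_sds, dtype=float)
    if sds.size < 3:
        raise ValueError("need at least 3 component standard deviations")
    n = sds.size
    x = np.arange(n, dtype=float)
    dx, dy = x[-1] - x[0], sds[-1] - sds[0]
    # |cross((dx, dy), (x_i - x_0, y_i - y_0))| / chord length
    dist = np.abs(dx * (sds - sds[0]) - dy * (x - x[0])) / np.hypot(dx, dy)
    if np.all(dist < 1e-12):
        return 1
    return int(np.argmax(dist)) + 1


def snn_graph(coordinates: np.ndarray, k_neighbors: int = 20) -> sparse.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbor graph over an embedding.

    Edge weight between two nuclei = |shared kNN| / |union of kNN| over
    their k-neighborhoods (each including the nucleus itself); edges with
    zero shared neighbors are dropped.
    """
    n = coordinates.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors={k_neighbors} must be < number of nuclei ({n})")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coordinates)
    indices = nn.kneighbors(return_distance=False)  # excludes self
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    cols = np.concatenate([indices, np.arange(n)[:, None]], axis=1)
    # membership matrix M (n x n): M[i, j] = 1 if j is in i's neighborhood (incl. self)
    m = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols.ravel())), shape=(n, n)
    )
    shared = (m @ m.T).tocoo()  # counts of shared neighbors
    size = k_neighbors + 1
    jac = shared.data / (2 * size - shared.data)
    keep = (shared.row != shared.col) & (jac > 0)
    g = sparse.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return g


def cluster_nuclei(
    embedding: Embedding,
    resolution: float,
    k_neighbors: int = 20,
    seed: int = 0,
    nucleus_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Leiden communities on the SNN graph at the given resolution.

    Deterministic for a fixed seed; cluster ids are relabeled contiguously
    from 0 in decreasing cluster-size order.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    g = snn_graph(embedding.coordinates, k_neighbors)
    coo = sparse.triu(g, k=1).tocoo()
    graph = igraph.Graph(
        n=g.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # contiguous ids, largest cluster first (stable for equal sizes)
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels], dtype=int)
    return ClusterAssignment(
        labels=labels,
        resolution=resolution,
        seed=seed,
        nucleus_ids=list(nucleus_ids) if nucleus_ids is not None else [],
    )


def occupancy(
    assignment: ClusterAssignment,
    conditions: pd.Series | np.ndarray,
    control: str,
    treated: str,
) -> pd.DataFrame:
    """Per-cluster occupancy in each condition and the treated/control fold.

    Occupancy of cluster k in condition c = (nuclei of c in k) / (nuclei of
    c).  Clusters absent from one condition keep their row with
    ``fold_change`` = NaN and ``fold_defined`` = False rather than being
    dropped.
    """
    conditions = np.asarray(conditions)
    for name in (control, treated):
        if name not in conditions:
            raise ValueError(f"condition {name!r} not present in the labels")
    labels = assignment.labels
    rows = []
    for k in range(assignment.n_clusters):
        in_k = labels == k
        n_ctrl = int(np.sum(in_k & (conditions == control)))
        n_trt = int(np.sum(in_k & (conditions == treated)))
        p_ctrl = n_ctrl / np.sum(conditions == control)
        p_trt = n_trt / np.sum(conditions == treated)
        defined = p_ctrl > 0 and p_trt > 0
        rows.append(
            {
                "cluster": k,
                "n_control": n_ctrl,
                "n_treated": n_trt,
                "prop_control": p_ctrl,
                "prop_treated": p_trt,
                "fold_change": p_trt / p_ctrl if defined else np.nan,
                "fold_defined": defined,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def transfer_composition(
    assignment: ClusterAssignment, reference_labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Cell-type percentage breakdown of each metabolic cluster.

    ``reference_labels`` are whole-transcriptome annotations transferred
    onto the metabolically clustered nuclei.  Percentages per cluster sum to
    100; the dominant label is flagged.
    """
    labels = pd.Series(np.asarray(reference_labels))
    if labels.isna().any():
        missing = list(np.where(labels.isna())[0][:5])
        raise ValueError(f"missing reference labels for nuclei at positions {missing}")
    if labels.size != assignment.labels.size:
        raise ValueError("reference labels must cover every clustered nucleus")
    df = pd.DataFrame({"cluster": assignment.labels, "cell_type": labels.values})
    counts = df.groupby(["cluster", "cell_type"], observed=True).size().rename("count").reset_index()
    counts["percent"] = counts.groupby("cluster")["count"].transform(lambda c: 100.0 * c / c.sum())
    dominant = counts.loc[counts.groupby("cluster")["percent"].idxmax(), ["cluster", "cell_type"]]
    dominant_map = dict(zip(dominant["cluster"], dominant["cell_type"]))
    counts["dominant"] = [
        ct == dominant_map[k] for k, ct in zip(counts["cluster"], counts["cell_type"])
    ]
    return counts.set_index(["cluster", "cell_type"])
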