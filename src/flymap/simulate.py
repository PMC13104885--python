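"""Synthetic inputs with machine-readable ground truth.

Every downstream stage of the pipeline (metabolic profiling, pathway
scoring, coordination analysis, ligand-receptor crosstalk, spectral
quantification) is exercised here against data whose generating process is
known exactly:

* pathway catalogs emulating a KEGG-style metabolic collection,
* single-nucleus count matrices drawn from a negative-binomial model with
  planted cell types, condition effects, pathway programs, ligand-receptor
  up-regulations and latent-factor correlation blocks,
* curated ligand-receptor pair tables,
* Raman spectra built from Gaussian/Lorentzian peaks over a polynomial
  baseline with additive Gaussian noise.

All generators take explicit integer seeds and are byte-identical across
runs for a fixed seed; there is no global random state.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pathway",
    "PathwayCatalog",
    "PathwayProgram",
    "LRPlanting",
    "CorrelationBlock",
    "PopulationDesign",
    "GroundTruth",
    "SpectrumDesign",
    "generate_pathway_catalog",
    "generate_cell_population",
    "generate_lr_table",
    "generate_spectrum",
]


def stable_seed(seed: int, *tokens) -> int:
    """Derive a child seed (< 2**31) from a base seed and string tokens.

    Hash-based so the result depends on the tokens' values, never on the
    order in which other children were drawn.
    """
    h = hashlib.sha256(("|".join([str(seed), *map(str, tokens)])).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# Pathway catalog
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    name: str
    category: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError(f"pathway {self.pathway_id} has an empty gene set")


@dataclass
class PathwayCatalog:
    """Named pathways grouped into categories, each a set of gene symbols."""

    pathways: list[Pathway]

    def __post_init__(self):
        ids = [p.pathway_id for p in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("pathway ids must be unique")

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pathways:
            seen.setdefault(p.category, None)
        return list(seen)

    def gene_union(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pathways:
            for g in p.genes:
                seen.setdefault(g, None)
        return list(seen)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.pathway_id == pathway_id:
                return p
        raise KeyError(pathway_id)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)


def generate_pathway_catalog(
    n_categories: int,
    n_pathways: int,
    genes_per_pathway: tuple[int, int],
    gene_universe_size: int,
    overlap_fraction: float = 0.05,
    seed: int = 0,
) -> PathwayCatalog:
    """Sample a synthetic pathway catalog over a gene universe ``g0000...``.

    Pathways are distributed round-robin over ``n_categories`` categories and
    their sizes drawn uniformly from ``genes_per_pathway`` (inclusive).

    ``overlap_fraction`` targets the mean pairwise Jaccard index between
    pathway gene sets.  Each pathway draws a fraction ``sqrt(2 * overlap)``
    of its genes from a small shared pool (pool size = mean pathway size) and
    the remainder from the full universe; for sets of size s sharing an
    expected m1*m2/pool genes this gives mean Jaccard ~ overlap_fraction.
    """
    if not (1 <= n_categories <= n_pathways):
        raise ValueError("need n_pathways >= n_categories >= 1")
    lo, hi = genes_per_pathway
    if not (1 <= lo <= hi):
        raise ValueError("genes_per_pathway bounds must satisfy 1 <= lo <= hi")
    if gene_universe_size < hi:
        raise ValueError(
            f"gene universe of {gene_universe_size} cannot hold pathways of "
            f"up to {hi} genes"
        )
    if not (0.0 <= overlap_fraction < 0.5):
        raise ValueError("overlap_fraction must lie in [0, 0.5)")

    rng = np.random.default_rng(stable_seed(seed, "catalog"))
    universe = np.array([f"g{i:04d}" for i in range(gene_universe_size)])
    mean_size = (lo + hi) / 2
    pool_size = max(2, int(round(mean_size)))
    pool_size = min(pool_size, gene_universe_size)
    pool = rng.choice(gene_universe_size, size=pool_size, replace=False)
    shared_frac = float(np.sqrt(2.0 * overlap_fraction))

    categories = [f"category_{chr(ord('A') + i % 26)}{i // 26 or ''}" for i in range(n_categories)]
    pathways = []
    for j in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_shared = min(int(round(shared_frac * size)), pool_size, size)
        genes_idx = list(rng.choice(pool, size=n_shared, replace=False)) if n_shared else []
        # fill the remainder from the whole universe, avoiding duplicates
        while len(genes_idx) < size:
            extra = rng.choice(gene_universe_size, size=size - len(genes_idx), replace=False)
            genes_idx = list(dict.fromkeys([*genes_idx, *extra]))
        genes = tuple(universe[sorted(genes_idx[:size])])
        pathways.append(
            Pathway(
                pathway_id=f"pw{j:03d}",
                name=f"synthetic pathway {j}",
                category=categories[j % n_categories],
                genes=genes,
            )
        )
    return PathwayCatalog(pathways)


# ---------------------------------------------------------------------------
# Cell population
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayProgram:
    """Multiplicative pathway-level condition effect on the NB mean."""

    cell_type: str
    condition: str  # a condition name or "all"
    pathway_id: str
    log2_effect: float


@dataclass(frozen=True)
class LRPlanting:
    """Ligand/receptor up-regulation restricted to a cell type and condition."""

    condition: str
    source_type: str
    ligand: str
    target_type: str
    receptor: str
    log2_effect: float


@dataclass(frozen=True)
class CorrelationBlock:
    """Pathways coupled through a shared per-nucleus latent factor.

    Gene means of every member pathway are multiplied by
    ``exp(loading * z - loading**2 / 2)`` with z ~ N(0, 1) drawn once per
    nucleus, inducing positive correlation between the member pathways'
    activity scores while leaving expected counts unchanged.
    """

    pathway_ids: tuple[str, ...]
    loading: float
    condition: str = "all"


@dataclass
class PopulationDesign:
    """Everything the count generator needs, with explicit seeds.

    ``n_nuclei`` is keyed by (cell_type, condition).  Baseline gene means are
    drawn log-normally at construction time if not supplied, then treated as
    relative expression; each nucleus draws its expected library size
    uniformly from ``library_size_range`` (so the NB means scale to it).
    Cell types are separable by ``markers_per_type`` disjoint marker genes
    per type, up-regulated by ``marker_log2fc`` and drawn from the catalog
    gene union (``marker_pool="catalog"``) so that metabolic-matrix
    clustering can recover the types, or from all genes (``"all"``).
    """

    cell_types: list[str]
    conditions: list[str]
    n_nuclei: dict[tuple[str, str], int]
    n_genes: int = 1000
    dispersion: float = 2.0
    library_size_range: tuple[int, int] = (1000, 3000)
    pathway_programs: list[PathwayProgram] = field(default_factory=list)
    lr_plantings: list[LRPlanting] = field(default_factory=list)
    correlation_blocks: list[CorrelationBlock] = field(default_factory=list)
    markers_per_type: int = 40
    marker_log2fc: float = 2.0
    marker_pool: str = "catalog"
    baseline_means: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        for (ct, cond), n in self.n_nuclei.items():
            if n <= 0:
                raise ValueError(f"n_nuclei must be positive, got {n} for ({ct}, {cond})")
            if ct not in self.cell_types or cond not in self.conditions:
                raise ValueError(f"undeclared (cell_type, condition) pair ({ct}, {cond})")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    cell_type: list[str]
    condition: list[str]
    occupancy: dict[str, dict[str, float]]  # condition -> cell_type -> proportion
    pathway_programs: list[PathwayProgram]
    lr_plantings: list[LRPlanting]
    block_membership: dict[str, int]  # pathway_id -> block index
    marker_genes: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "condition": self.condition,
            "occupancy": self.occupancy,
            "pathway_programs": [vars(p) for p in self.pathway_programs],
            "lr_plantings": [vars(p) for p in self.lr_plantings],
            "block_membership": self.block_membership,
            "marker_genes": self.marker_genes,
        }


def _validate_design(design: PopulationDesign, catalog: PathwayCatalog, genes: list[str]):
    known_pathways = set(catalog.pathway_ids)
    gene_set = set(genes)
    for prog in design.pathway_programs:
        if prog.pathway_id not in known_pathways:
            raise ValueError(f"pathway program references unknown pathway {prog.pathway_id!r}")
        if prog.condition != "all" and prog.condition not in design.conditions:
            raise ValueError(f"pathway program references unknown condition {prog.condition!r}")
    for lr in design.lr_plantings:
        for g in (lr.ligand, lr.receptor):
            if g not in gene_set:
                raise ValueError(f"L-R planting references unknown gene {g!r}")
    for blk in design.correlation_blocks:
        for pid in blk.pathway_ids:
            if pid not in known_pathways:
                raise ValueError(f"correlation block references unknown pathway {pid!r}")
    missing = [g for g in catalog.gene_union() if g not in gene_set]
    if missing:
        raise ValueError(
            f"catalog genes absent from the simulated universe (first: {missing[0]!r}); "
            "increase n_genes or regenerate the catalog"
        )


def generate_cell_population(
    design: PopulationDesign, catalog: PathwayCatalog
) -> tuple[ad.AnnData, GroundTruth]:
    """Draw a single-nucleus count matrix with planted structure.

    Counts for nucleus c and gene g are negative binomial with mean
    ``L_c * rel_g * m_{g,group} * f_{g,c}`` and shared dispersion, where
    ``L_c`` is the nucleus's target library size, ``rel`` the (renormalized)
    relative baseline expression, ``m`` the deterministic group multiplier
    (markers, pathway programs, L-R plantings, all powers of 2) and ``f`` the
    mean-one latent-factor multiplier of the correlation blocks.

    Returns an :class:`anndata.AnnData` (``layers["counts"]``, obs columns
    ``cell_type``/``condition``/``tissue``) and the ground truth.
    """
    genes = [f"g{i:04d}" for i in range(design.n_genes)]
    _validate_design(design, catalog, genes)
    rng = np.random.default_rng(stable_seed(design.seed, "population"))

    if design.baseline_means is None:
        rel = rng.lognormal(mean=0.0, sigma=1.0, size=design.n_genes)
    else:
        rel = np.asarray(design.baseline_means, dtype=float)
        if rel.shape != (design.n_genes,) or np.any(rel <= 0):
            raise ValueError("baseline_means must be positive with one entry per gene")
    rel = rel / rel.sum()
    gene_index = {g: i for i, g in enumerate(genes)}

    # disjoint marker genes per cell type
    if design.marker_pool == "catalog":
        pool = [gene_index[g] for g in catalog.gene_union()]
    elif design.marker_pool == "all":
        pool = list(range(design.n_genes))
    else:
        raise ValueError("marker_pool must be 'catalog' or 'all'")
    n_mark = design.markers_per_type * len(design.cell_types)
    if n_mark > len(pool):
        raise ValueError("marker pool too small for the requested markers per type")
    marker_idx = rng.choice(pool, size=n_mark, replace=False) if n_mark else np.array([], int)
    marker_genes = {
        ct: sorted(genes[i] for i in marker_idx[k * design.markers_per_type:(k + 1) * design.markers_per_type])
        for k, ct in enumerate(design.cell_types)
    }

    # deterministic per-(cell_type, condition) multiplier
    mult: dict[tuple[str, str], np.ndarray] = {}
    for ct in design.cell_types:
        for cond in design.conditions:
            m = np.ones(design.n_genes)
            for g in marker_genes[ct]:
                m[gene_index[g]] *= 2.0 ** design.marker_log2fc
            for prog in design.pathway_programs:
                if prog.cell_type == ct and prog.condition in (cond, "all"):
                    for g in catalog[prog.pathway_id].genes:
                        m[gene_index[g]] *= 2.0 ** prog.log2_effect
            for lr in design.lr_plantings:
                if lr.condition in (cond, "all"):
                    if lr.source_type == ct:
                        m[gene_index[lr.ligand]] *= 2.0 ** lr.log2_effect
                    if lr.target_type == ct:
                        m[gene_index[lr.receptor]] *= 2.0 ** lr.log2_effect
            mult[(ct, cond)] = m

    block_gene_idx = []
    for blk in design.correlation_blocks:
        idx = sorted({gene_index[g] for pid in blk.pathway_ids for g in catalog[pid].genes})
        block_gene_idx.append(np.array(idx, int))

    lib_lo, lib_hi = design.library_size_range
    theta = design.dispersion
    parts, cell_type_col, condition_col, obs_names = [], [], [], []
    nucleus_counter = 0
    for ct in design.cell_types:
        for cond in design.conditions:
            n = design.n_nuclei.get((ct, cond), 0)
            if n == 0:
                continue
            grng = np.random.default_rng(stable_seed(design.seed, "group", ct, cond))
            base = rel * mult[(ct, cond)]
            base = base / base.sum()  # expected library == drawn target exactly
            lib = grng.integers(lib_lo, lib_hi + 1, size=n).astype(float)
            mu = lib[:, None] * base[None, :]
            for b, blk in enumerate(design.correlation_blocks):
                if blk.condition not in (cond, "all") or blk.loading == 0:
                    continue
                z = grng.standard_normal(n)
                fac = np.exp(blk.loading * z - blk.loading**2 / 2.0)
                mu[:, block_gene_idx[b]] *= fac[:, None]
            p = theta / (theta + mu)
            counts = grng.negative_binomial(theta, p).astype(np.int32)
            parts.append(sparse.csr_matrix(counts))
            cell_type_col.extend([ct] * n)
            condition_col.extend([cond] * n)
            obs_names.extend(f"nucleus_{nucleus_counter + i:06d}" for i in range(n))
            nucleus_counter += n

    X = sparse.vstack(parts).tocsr()
    obs = pd.DataFrame(
        {"cell_type": cell_type_col, "condition": condition_col, "tissue": "gut"},
        index=obs_names,
    )
    adata = ad.AnnData(
        X=X.copy(), obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene"))
    )
    adata.layers["counts"] = X

    occupancy: dict[str, dict[str, float]] = {}
    for cond in design.conditions:
        total = sum(design.n_nuclei.get((ct, cond), 0) for ct in design.cell_types)
        occupancy[cond] = {
            ct: design.n_nuclei.get((ct, cond), 0) / total if total else 0.0
            for ct in design.cell_types
        }

    membership = {
        pid: b
        for b, blk in enumerate(design.correlation_blocks)
        for pid in blk.pathway_ids
    }
    truth = GroundTruth(
        cell_type=cell_type_col,
        condition=condition_col,
        occupancy=occupancy,
        pathway_programs=list(design.pathway_programs),
        lr_plantings=list(design.lr_plantings),
        block_membership=membership,
        marker_genes=marker_genes,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# Ligand-receptor table
# ---------------------------------------------------------------------------

def generate_lr_table(
    n_pairs: int,
    pathway_labels: list[str],
    gene_universe: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Sample a curated-style ligand-receptor pair table.

    Returns a DataFrame with columns ``ligand, receptor, pathway``; ligands
    and receptors are distinct genes, drawn without replacement from the
    universe so no gene appears twice, and pathway labels cycle through
    ``pathway_labels``.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be non-negative")
    if n_pairs > 0 and not pathway_labels:
        raise ValueError("need at least one pathway label")
    if 2 * n_pairs > len(gene_universe):
        raise ValueError(
            f"universe of {len(gene_universe)} genes cannot host {n_pairs} disjoint pairs"
        )
    rng = np.random.default_rng(stable_seed(seed, "lr_table"))
    chosen = rng.choice(len(gene_universe), size=2 * n_pairs, replace=False)
    universe = np.asarray(gene_universe)
    return pd.DataFrame(
        {
            "ligand": universe[chosen[:n_pairs]],
            "receptor": universe[chosen[n_pairs:]],
            "pathway": [pathway_labels[i % len(pathway_labels)] for i in range(n_pairs)],
        }
    )


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------

_GAUSS_W = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM of a unit-sigma Gaussian


@dataclass(frozen=True)
class SpectralPeak:
    center: float  # cm^-1
    amplitude: float
    fwhm: float  # cm^-1
    shape: str = "gaussian"  # or "lorentzian"

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    @property
    def sigma(self) -> float:
        return self.fwhm / _GAUSS_W

    @property
    def area(self) -> float:
        """Analytic area under the peak (amplitude * sigma * sqrt(2*pi) for a Gaussian)."""
        if self.shape == "gaussian":
            return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)
        return self.amplitude * np.pi * self.fwhm / 2.0

    def evaluate(self, nu: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-0.5 * ((nu - self.center) / self.sigma) ** 2)
        return self.amplitude / (1.0 + (2.0 * (nu - self.center) / self.fwhm) ** 2)


@dataclass
class SpectrumDesign:
    """Peaks + polynomial baseline + Gaussian noise on a uniform grid."""

    peaks: list[SpectralPeak] = field(default_factory=list)
    baseline_coeffs: tuple[float, ...] = (0.0,)  # ascending powers of nu
    noise_sd: float = 0.0
    grid: tuple[float, float, float] = (600.0, 3200.0, 1.0)  # start, stop, step
    seed: int = 0

    def __post_init__(self):
        start, stop, step = self.grid
        if not (start < stop and step > 0):
            raise ValueError("grid must satisfy start < stop and step > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_spectrum(design: SpectrumDesign):
    """Synthesize a Raman spectrum and its analytic truth.

    Returns ``(spectrum, truth)`` where truth records each peak's analytic
    height, area and FWHM plus the noise level used.
    """
    from .spectral import RamanSpectrum  # local import to avoid a cycle

    start, stop, step = design.grid
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    nu = start + step * np.arange(n)
    intensity = np.polynomial.polynomial.polyval(nu, np.asarray(design.baseline_coeffs, float))
    intensity = np.broadcast_to(intensity, nu.shape).astype(float).copy()
    for peak in design.peaks:
        intensity += peak.evaluate(nu)
    if design.noise_sd > 0:
        rng = np.random.default_rng(stable_seed(design.seed, "spectrum"))
        intensity = intensity + rng.normal(0.0, design.noise_sd, size=n)
    truth = {
        "peaks": [
            {
                "center": p.center,
                "amplitude": p.amplitude,
                "fwhm": p.fwhm,
                "area": p.area,
                "shape": p.shape,
            }
            for p in design.peaks
        ],
        "noise_sd": design.noise_sd,
        "baseline_coeffs": list(design.baseline_coeffs),
    }
    return RamanSpectrum(nu, intensity), truth
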