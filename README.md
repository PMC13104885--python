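# flymap

Single-nucleus **metabolic profiling**, gut→brain **ligand–receptor (L–R)
scoring**, and **Raman/SRS spectral quantification** for *Drosophila*
dietary-lipid studies — with a synthetic-data module that generates every
input with machine-readable ground truth, so each stage is testable without
any sequencing or imaging downloads.

## Who this is for

Groups studying how diet (e.g. yeast-derived lipid extracts) reshapes tissue
metabolism at single-nucleus resolution, and how the gut signals to the
brain. The package reimplements, as a tested library, the bespoke
computations such a study needs beyond the standard single-cell toolkits:

1. **Metabolic profiling** — cluster nuclei on *metabolic genes only*
   (the sub-matrix of a KEGG-style pathway catalog), then compare
   per-cluster **occupancy** between conditions as a fold change
   `prop(treated) / prop(control)`.
2. **Pathway activity scoring** — the binned-control module score
   `s(c, p) = mean(pathway genes) − mean(expression-bin-matched controls)`
   per nucleus `c` and pathway `p`, and the **Expression Power Index**
   `EPI = f · max(m, 0)` (expression frequency × expression level) that
   ranks pathways within a cluster.
3. **Pathway coordination** — Pearson correlation of pathway scores across
   all nuclei of a condition, hierarchical ordering on `1 − r`, significance
   dots at `P < 0.05`, and **correlation modules** (dendrogram groups with
   ≥ 3 members, mean pairwise `r ≥ 0.3`, ≥ 80 % significant pairs), matched
   across conditions by Jaccard overlap.
4. **L–R crosstalk** — interaction score = (mean log-normalized ligand
   expression in the source gut cluster) × (mean receptor expression in the
   target brain cluster); pairs filtered at `P < 0.05` with both genes
   expressed in > 10 % of nuclei; differential level `Δ = score(A) − score(B)`;
   per-cluster aggregation (clusters with < 10 differential pairs omitted).
5. **Spectral quantification** — 1 cm⁻¹ regridding, background subtraction,
   asymmetric-least-squares baseline, vector normalization; band ratios
   2140/2850 (CD/CH, newly synthesized lipids), 2176/2850 (D-lipids),
   3012/2850 (unsaturation), 2850/2935 (lipid/protein); the A2885/A2850
   area ratio from a joint five-Gaussian CH-stretch decomposition (lipid
   acyl-chain ordering); and the half-height bandwidth of the 1295 cm⁻¹
   CH₂-twist band. Ratios are computed on unprocessed (regridded,
   background-subtracted) spectra and are scale invariant.

All counts are simulated from a negative-binomial model with planted cell
types, condition effects, pathway programs, L–R up-regulations and
latent-factor correlation blocks; see `docs/methods.md` for the model and
its limitations.

## Worked example

```python
import numpy as np
import flymap as fm

# 1. Synthetic gut data: 3 cell types x 2 diets, one metabolic program
#    planted in type T1 and a coordinated 5-pathway block under diet "880"
catalog = fm.generate_pathway_catalog(
    n_categories=4, n_pathways=20, genes_per_pathway=(10, 25),
    gene_universe_size=1000, overlap_fraction=0.0, seed=1,
)
design = fm.PopulationDesign(
    cell_types=["T1", "T2", "T3"], conditions=["ctrl", "880"],
    n_nuclei={("T1", "ctrl"): 100, ("T2", "ctrl"): 250, ("T3", "ctrl"): 650,
              ("T1", "880"): 140, ("T2", "880"): 500, ("T3", "880"): 360},
    pathway_programs=[fm.PathwayProgram("T1", "all", "pw005", 1.0)],
    correlation_blocks=[fm.CorrelationBlock(
        ("pw010", "pw011", "pw012", "pw013", "pw014"), 0.6, condition="880")],
    seed=0,
)
adata, truth = fm.generate_cell_population(design, catalog)

# 2. QC, normalization, metabolic matrix, clustering
adata, qc = fm.filter_by_gene_count(adata, fm.GUT_QC)   # 200-3,000 genes
norm = fm.normalize_log1p(adata)                         # ln(1 + CP10K)
metab, _ = fm.select_metabolic_genes(norm, catalog)
emb = fm.scale_and_embed(metab, n_components=10, seed=0)
clusters = fm.cluster_nuclei(emb, resolution=0.2, seed=0)
print(f"QC kept {qc['kept']} nuclei; {clusters.n_clusters} metabolic clusters")

# 3. Occupancy fold changes between diets
occ = fm.occupancy(clusters, norm.obs["condition"].to_numpy(), "ctrl", "880")
print(occ[["prop_control", "prop_treated", "fold_change"]].round(3))

# 4. Pathway activity scores and EPI ranking per cluster
scores = fm.score_all_pathways(norm, catalog, seed=0)
epi = fm.expression_power_index(scores, clusters)
for k in range(clusters.n_clusters):
    top = epi.loc[k].sort_values("rank").head(1)
    print(f"cluster {k}: top pathway {top.index[0]} (EPI {top['epi'].iloc[0]:.3f})")

# 5. Correlation modules within the 880 diet
in_880 = np.where((norm.obs["condition"] == "880").to_numpy())[0]
corr = fm.pathway_correlation(scores, subset=in_880, condition="880")
for m in fm.detect_modules(corr):
    print(f"module: {m.members} (mean r = {m.mean_r:.2f})")
```

prints

```
QC kept 2000 nuclei; 3 metabolic clusters
         prop_control  prop_treated  fold_change
cluster
0                0.65          0.36        0.554
1                0.25          0.50        2.000
2                0.10          0.14        1.400
cluster 0: top pathway pw017 (EPI 0.167)
cluster 1: top pathway pw015 (EPI 0.198)
cluster 2: top pathway pw005 (EPI 0.739)
module: ('pw014', 'pw012', 'pw011', 'pw010', 'pw013') (mean r = 0.69)
```

Reading the output: the planted occupancy shifts are recovered exactly —
cluster 2 (type T1) has 40 % greater occupancy under diet 880 (fold 1.4) and
cluster 1 doubles (fold 2.0). The pathway planted in T1 (`pw005`) ranks #1
by EPI in its cluster, and the planted 5-pathway correlation block is
recovered as a module with mean within-module `r = 0.69`.

A spectral example:

```python
import flymap as fm
from flymap.simulate import SpectralPeak, SpectrumDesign

design = SpectrumDesign(
    peaks=[SpectralPeak(2140, 0.5, 20),   # C-D stretch (new lipids)
           SpectralPeak(2850, 1.0, 16),   # CH2 symmetric stretch
           SpectralPeak(2871, 0.45, 13),
           SpectralPeak(2885, 0.8, 13),   # ordered-lipid Fermi resonance
           SpectralPeak(2927, 0.9, 18),
           SpectralPeak(2958, 0.4, 15),
           SpectralPeak(1295, 0.6, 14)],  # CH2 twist
    noise_sd=0.005, grid=(1100, 3100, 1), seed=4,
)
spectrum, analytic_truth = fm.generate_spectrum(design)
print(f"CD/CH 2140/2850 ratio : {fm.band_ratio(spectrum, 2140, 2850):.3f}")
print(f"A2885/A2850 area ratio: {fm.area_ratio_2885_2850(spectrum):.3f}")
print(f"1295 cm-1 half-height bandwidth: {fm.half_height_bandwidth(spectrum, 1295):.2f} cm-1")
```

prints

```
CD/CH 2140/2850 ratio : 0.503
A2885/A2850 area ratio: 0.642
1295 cm-1 half-height bandwidth: 13.93 cm-1
```

against analytic truths of 0.5 (amplitude ratio of equal-width bands),
0.64 (Gaussian area ratio) and 14 cm⁻¹ (the designed FWHM).

## Layout

```
src/flymap/
  simulate.py      # synthetic catalogs, counts, L-R tables, spectra + truth
  preprocess.py    # QC, log-normalization, metabolic matrix, top-decile rule
  profiling.py     # scaling/PCA, elbow, SNN-Leiden, occupancy, composition
  scoring.py       # module scores, dot-plot stats, EPI, Wilcoxon DE
  coordination.py  # correlation maps, ordering, modules, condition compare
  crosstalk.py     # L-R scoring, filters, differentials, aggregates
  spectral.py      # Raman processing and band quantification
  io.py            # MTX / GMT / CSV / TSV / JSON readers and writers
```

I/O conventions: counts as 10x-style Matrix-Market triplet directories
(`matrix.mtx` + `features.tsv` + `barcodes.tsv` + `meta.tsv`), catalogs as
GMT, L–R tables as `ligand,receptor,pathway` CSV, spectra as two-column TSV,
ground truth as JSON.
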