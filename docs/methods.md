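# Methods

This note documents the models, conventions and numerical choices behind
`flymap`, what the synthetic-data generator does and does not emulate, and
the known limitations a user should weigh before applying the pipeline to
real single-nucleus or spectral data.

## Synthetic count model

Counts for nucleus *c*, gene *g* are negative binomial with shared
dispersion θ (default 2, a typical snRNA-seq overdispersion) and mean

```
mu(c, g) = L_c · rel_g · m(g, type_c, cond_c) · f(c, g)
```

- `L_c` — the nucleus's target library size, drawn uniformly from
  `library_size_range` (default 1,000–3,000 counts).
- `rel_g` — relative baseline expression, drawn log-normally (σ = 1) and
  normalized to sum to 1; a caller may supply explicit baselines instead.
- `m` — a deterministic per-(cell type, condition) multiplier assembled
  from three planting mechanisms, all powers of two so effects are exact on
  the log2 scale: cell-type **marker genes** (default 40 disjoint genes per
  type at log2FC 2, drawn from the catalog union so metabolic clustering
  can separate types), **pathway programs** (all genes of a pathway times
  `2^log2_effect` in one type and condition), and **L–R plantings**
  (single ligand/receptor genes, analogously). After applying `m` the gene
  profile is renormalized within each group, so the expected library equals
  `L_c` exactly; a planted 2× pathway therefore measures slightly below 2×
  in raw counts (≈ 1.96 when the pathway holds ~2 % of the transcriptome) —
  inside the stated recovery tolerances.
- `f` — correlation-block factors: each block has a latent per-nucleus
  `z ~ N(0,1)`; genes of the block's pathways are multiplied by
  `exp(loading · z − loading²/2)` (mean 1, so expected counts are
  unchanged). Averaging over a pathway's genes cancels independent NB noise
  but not the shared factor, so member pathways' activity scores correlate;
  at loading 0.6 and n = 2,000 nuclei the realized score correlation is
  ≈ 0.6–0.7.

Every generator takes an explicit integer seed; per-group seeds are derived
by hashing `(seed, group)` so outputs are byte-identical across runs and
independent of iteration order. What the generator does **not** emulate:
ambient RNA, doublets, batch effects, UMI-level sequencing noise,
gene–gene regulatory correlation beyond the planted blocks, and realistic
pathway size/overlap structure (overlap is a single mean-Jaccard dial).
Passing recovery tests therefore demonstrates correctness of the
*computations*, not robustness to those artifacts.

## Quality control and normalization

Nuclei are kept when their detected-gene count (genes with raw count > 0)
falls in a closed interval: 200–1,600 for brain, 200–3,000 for gut (gut
nuclei carry more RNA; the lower bound is shared). Both bounds inclusive.
Normalization is counts-per-10,000 followed by `log1p`, delegated to
scanpy's `normalize_total` + `log1p`; the unit test checks the closed-form
`ln(1 + 10⁴·count/total)` against an independent recomputation. The
metabolic matrix is the column restriction to the catalog's gene union;
catalog genes absent from the matrix are reported, not fatal. The
"top 10 % of nuclei" selection used for violin-style group comparisons
takes the `ceil(0.1·n)` largest values with stable (input-order) ties.

## Embedding, elbow, clustering

Genes are z-scaled (sd from the data, constant genes map to zero) and
clipped at ±10 — the conventional guard against a single extreme nucleus
dominating a principal component — then projected by exact-SVD PCA. The
elbow diagnostic is the kneedle rule: the component maximizing the
perpendicular distance to the chord from the first to the last (index, sd)
point; a perfectly linear decay returns 1 by convention.

Clustering builds a shared-nearest-neighbor graph (k = 20 Euclidean
neighbors per nucleus, neighborhoods include the nucleus itself, edges
weighted by neighborhood Jaccard overlap, zero-overlap edges dropped) and
runs Leiden with the RB-configuration objective at the caller's resolution
(0.2 is the gut default, 0.1 brain). The Leiden seed is a required
argument; labels are relabeled contiguously from 0 by decreasing cluster
size. Occupancy folds are `prop(treated)/prop(control)` per cluster;
clusters absent from one condition are flagged (`fold_defined = False`)
rather than dropped or given ∞.

## Pathway activity scores and EPI

The module score bins all genes into 24 equal-frequency bins by dataset
average expression; each pathway gene draws 100 control genes from its bin
**excluding the pathway's own genes** (scanpy's convention; without the
exclusion a planted pathway's controls are dominated by the pathway itself
whenever bins are small, and the score collapses toward zero). Sampling is
without replacement when the remaining bin is large enough, with
replacement otherwise; if exclusion empties a bin the full bin is used.
Score = mean(set) − mean(pooled controls). Adding a constant to the
normalized layer cancels exactly; scaling by k scales scores by k.
Per-pathway control sampling is seeded from a hash of (seed, pathway id),
so a pathway's score column is independent of catalog order. Submatrix
means are taken over C-contiguous gathers so results do not depend on
memory layout.

EPI for (cluster, pathway) is `f · max(m, 0)` with `f` = fraction of the
cluster's nuclei with score > 0 and `m` = mean score. The `max(·, 0)` floor
keeps pathways with negative mean activity from ranking positively; "score
> 0" is the recorded convention for "expressing a pathway" in dot-plot
fractions as well. Ties in EPI break alphabetically by pathway id.

Differential expression is a two-sided Wilcoxon rank-sum on the
log-normalized layer over genes detected in ≥ 10 % of either group,
`log2FC = log2((mean expm1 A + 1)/(mean expm1 B + 1))`, Benjamini–Hochberg
across tested genes. Swapping groups negates log2FC and preserves P.

## Pathway coordination

Pearson correlations are computed across all nuclei of one condition (not
per cluster); P-values come from the t-transform with n − 2 degrees of
freedom. Zero-variance pathways give missing correlations: imputed as 0
for dendrogram ordering (with a warning), excluded from module statistics.
Ordering is average-linkage on `d = 1 − r`; modules are the groups from
cutting that dendrogram at `d = 0.7` (i.e. `r = 0.3`) that have ≥ 3
members, mean pairwise `r ≥ 0.3`, and ≥ 80 % of pairs at `P < 0.05`. The
significance dots use raw P < 0.05 (no multiple-testing correction),
matching heatmap-annotation practice; a BH variant is a one-liner away via
the returned P matrix. Cross-condition matching labels a module "shared"
at Jaccard ≥ 0.5 with some counterpart.

**Known limitation — control-sharing correlation.** Module scores of even
disjoint pathways are weakly correlated because their control pools are
drawn from the same expression bins (and, to a lesser degree, because
normalization is compositional). On null populations this adds an extra
±0.01–0.03 of true pairwise correlation on top of the 1/√n sampling noise,
so at n = 1,000 nuclei the P < 0.05 dot rate is ≈ 7 % rather than 5 %, and
the effect does not vanish with transcriptome size. It is far too small to
create spurious modules at the r ≥ 0.3 cut (the null module count is 0 in
20/20 simulations), but dot-level significance on large n should be read
with this floor in mind. The dot-rate calibration test therefore runs on
the correlation map's own null (independent score vectors), where it sits
at 5 % ± 2 %.

## Ligand–receptor crosstalk

The interaction score is the product of mean log-normalized ligand
expression over source nuclei and receptor expression over target nuclei —
zero whenever either side is silent, monotone in both, and simple enough
to invert mentally. (A sum-of-scaled-means alternative was considered and
rejected: it is nonzero when one side is silent.) Pair significance is the
maximum of two one-sided rank-sum enrichment tests (ligand: source cluster
vs the rest of its tissue; receptor: target vs rest); both sides must be
enriched. Filters are strict: P < 0.05 and both expression fractions
> 0.10. Differential level Δ = score(A) − score(B) is exactly
antisymmetric. Aggregation counts significantly differential pairs per
cluster and lists clusters under 10 pairs as omitted; category comparisons
use a two-sided rank-sum over member-pair scores with single-pair
categories flagged `small_n`.

## Spectral processing

Regridding linearly interpolates onto a uniform grid (default step
1 cm⁻¹) anchored at the first input wavenumber. Background spectra must
share the grid exactly. Baseline correction is asymmetric least squares
(λ = 10⁵, p = 0.01, 10 reweighting iterations; second-difference penalty) —
a standard, parameterized choice. Vector normalization divides by the
Euclidean norm (unit-norm output, idempotent).

Band intensities are means over ±2 cm⁻¹ windows (robust to regridding
phase, unlike single-point lookup); all named ratios are computed on
regridded, background-subtracted but otherwise unprocessed spectra — they
are invariant to vector normalization anyway (numerator and denominator
scale together, asserted to 1e-12) but not to baseline correction, so the
order is enforced by convention. For a fwhm-20 Gaussian the ±2 cm⁻¹
windowed mean is 0.9908 of the peak amplitude (the windowing bias the
±2 cm⁻¹ default trades for phase robustness).

Peak decomposition is bounded Gaussian least squares: centers within
±8 cm⁻¹ of their initials, positive amplitudes, fwhm in [1, 120] cm⁻¹.
The A2885/A2850 ordering ratio always fits the five canonical CH-stretch
bands (2850, 2871, 2885, 2927, 2958 cm⁻¹) jointly over 2,800–3,050 cm⁻¹,
because the 2871/2885 bands overlap too heavily for window integration.
The decomposition is statistically well-conditioned for ordered-lipid
spectra (band fwhm ≈ 13–18 cm⁻¹ — the regime where the 2885 cm⁻¹ Fermi
resonance is pronounced and the ratio is informative); for very broad,
heavily blended bands (fwhm ≳ 20 cm⁻¹) the 2871/2885 split is poorly
identified and the ratio's replicate scatter grows several-fold.

The half-height bandwidth searches for the local maximum nearest the
requested center within ±15 cm⁻¹ (ties go to the closest), estimates a
local linear baseline from two flanking-band anchors (mean intensity over
the outer fifth of a ±45 cm⁻¹ baseline window on each side — a band mean
rather than a single minimum, because the minimum of ~45 noisy points is
biased low by about 2σ, which at SNR 50 inflates the measured FWHM by
~2.4 %), and locates the half-height crossings of the baseline-subtracted
signal by linear interpolation between grid points. Noiseless Gaussians
measure exactly; Lorentzians measure ≈ 1.5 % narrow because their fat
tails raise the baseline anchors.

## Problem sizes used in tests and the acceptance script

Recovery simulations use 2,000 nuclei over a 1,000-gene universe with a
20-pathway catalog (catalog union ≈ 350 genes), 8–20 replicate seeds per
check, L–R worlds of 400 genes and 3 clusters per tissue, and spectra on
1 cm⁻¹ grids spanning the fingerprint-to-CH range. These sizes put every
planted effect several standard errors above its detection threshold while
keeping the full suite under a few minutes on one CPU; the DE power
benchmark uses a compact 300-gene equal-baseline panel so that planted
genes sit at typical detected coverage and the measurement reflects the
rank-sum + BH contract rather than per-gene abundance lottery.
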