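# Methods

This note documents the models behind `domemap`: what each stage assumes,
the parameters that matter, what the simulator does and does not emulate,
and the numerical choices made where the design was genuinely open. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Statistical primitives

Intensities are variance-stabilised with `asinh(x / c)`; the cofactor
defaults to `c = 5` (the mass-cytometry convention; suspension and imaging
data use the same value, configurable per panel). Group comparisons are
two-tailed; the unpaired t test defaults to the Welch unequal-variance
convention with a flag for the pooled form, since a robust default costs
nothing when variances happen to be equal. The Wilcoxon rank-sum test uses
exact enumeration of the rank-sum null for tie-free data up to 16 total
observations and a tie-corrected, continuity-corrected normal approximation
above; the two agree within |Δp| ≤ 0.02 for all group sizes ≤ 8 (checked
against a brute-force enumeration oracle). Holm's step-down and Bonferroni
corrections follow the textbook formulas. Spearman's ρ is the Pearson
correlation of midranks; its p value is exact (full permutation) for
n ≤ 7 and otherwise uses the `t = ρ√((n−2)/(1−ρ²))` approximation.
Zero-variance inputs return an explicit degenerate flag rather than
raising, so batch reports over hundreds of markers/genes can proceed.

## Synthetic tissue generator

The generator is the package's ground-truth source; its defaults define
the study conditions for every recovery test.

**Geometry.** One stylised follicle section in µm (origin top-left, y
down): a lumen strip (y < 60), the follicle-associated epithelium (FAE)
band beneath it, the subepithelial dome (SED) directly below, a germinal
centre (GC) disc nested in a mantle disc deeper in the tissue, a T-cell
zone at one edge, lamina propria elsewhere. Nesting is by containment
only; points are sampled from each zone's polygon minus any smaller
overlapping zone, so a cell's generated zone always equals its geometric
assignment under the smallest-containing-polygon rule.

**Cell placement.** Counts and zone weights per type put DN2 B cells just
beneath the FAE (their depth below the epithelium decays exponentially,
scale 40 µm), IEDN inside the FAE, naive/MZ cells in the mantle, GC
subsets in the GC and plasma cells in the lamina propria — so the expected
distance-to-epithelium ordering across B subsets holds by construction.
IEDN cells are excluded from the distance-ordering report by default:
sitting among the epithelial cells themselves, their near-zero distances
say nothing about positioning within the stroma.

**Marker model.** Raw intensities are two-component lognormal: a dim
negative population (`meanlog 0, sdlog 0.5`) and a positive population
`separation = 3` natural-log units brighter (`sdlog 0.35`). Positive
fractions of subset-defining markers are 1.0 — they are definitional (an
IgD-negative "naive" B cell *is* a DN cell); partially expressed markers
(IgG, FcRL4, plasma-cell CD20) keep intermediate fractions, and every
marker has a 0.5% spurious-positive background. DN2's CD11c and IEDN's
E-cadherin carry a `dim` grade (55% of the separation): bright relative to
other B cells but well below the myeloid/epithelial level, which is what
lets these cells pass the CD20 lineage gate while reading as marker-high
within the B compartment. Observed intensities are the inverse transform
of (true transformed + per-ROI batch shift, s.d. 0.25) mixed through a
banded spillover matrix (4% leak into the next channel, 2% into the one
after). 5% of cells draw areas below the 11-px QC threshold and 2% carry
no DNA signal; 1.5% of follicular B cells carry adjacency-contaminated
CD3 (B–T doublets).

**Spot counts.** Spots sit on an odd-row-offset hex lattice (28 × 32 over
the geometry). Gene programs are graded per spot: a program's activity is
its neighbourhood-smoothed zone-membership indicator (boundary spots carry
partial tissue) times a shared lognormal jitter whose location is solved
numerically so the zone-mean multiplier equals the configured fold change.
Each program also carries a shared per-spot cell-content factor
(lognormal, sdlog 0.4, mean 1): the same myeloid cells express DNASE1L3,
C1QB and C1QA, so their transcripts covary beyond the zone signal. Counts
are gamma-Poisson with the overdispersion decomposed accordingly — program
genes keep only a residual independent dispersion of 0.05 on top of the
shared factors, null genes carry the full 0.2 independently. The SED
program is anchored on DNASE1L3 (fold change 4, baseline 8 counts) with
complement genes at fold change 3 and abundant baselines (6), which
reproduces simultaneously: DNASE1L3 ranked first among SED-enriched genes,
realized SED/follicle mean ratios within ±20% of the configured fold
change, pairwise Spearman ρ ≥ 0.6 among the co-programmed trio over the
lymphoid spots, and family-wise error control over the null genes.

**Rasters.** Reference discs (radius 14 px) and signal discs (radius 4 px)
placed either entirely inside or entirely clear of the reference mask, so
the ground-truth overlap fraction equals the request up to blob
granularity; foreground sits ~70 counts above a noisy background so Otsu
thresholding recovers the masks.

**Determinism.** Every output object draws from its own RNG stream derived
from the master seed and a CRC32 hash of the object's label, so adding an
output never perturbs the others and runs are identical across platforms.

**What the simulator does not emulate.** Cell shapes and segmentation
errors beyond size/DNA outliers; ablation artefacts; spatial marker
gradients within a zone; spot-swapping/bleed between adjacent spots;
realistic transcriptome-wide gene panels (the spot panel is ~216 genes, so
the 2000-HVG cut keeps everything — see the gene-scaling note below).
Passing tests therefore demonstrate correctness of the algorithms under a
clean generative model, not robustness to every real-data artefact.

## Suspension stage

Equal-event subsampling (default 9214 per sample, capped with a warning at
the smallest sample) precedes density-dependent downsampling: local
density is the number of points within 5× the median 15-NN distance
(counted against a ≤ 3000-point reference subsample for speed), and each
point survives with probability `min(1, target/density)` with the target
at the 3rd density percentile — abundant populations are flattened,
rare ones retained. Retained events are clustered with k-means (default
100 nodes; the classical agglomerative step is quadratic and adds nothing
at this scale), a Euclidean minimum spanning tree joins node medians, and
every event is assigned to its nearest node. Clustering uses the 12-marker
reduction panel; node medians cover all markers so bubble rules may use
markers outside the reduction panel (CD11c). A 2-D embedding is a
visualisation-only contract — recovery is asserted on the clustering, not
on any embedding.

Bubbles are first-match ordered rules on node medians. Positivity
thresholds per marker come from the first gap ≥ 0.25 transformed units in
the sorted node medians (`gap_thresholds`): node medians denoise
single-cell variation, and the first sufficient gap sits just above the
negative cloud so dim and bright populations both count positive. Pooled
two-component mixture fits (kept for per-image gate thresholds, where
populations are bright) are unreliable here: for a marker carried by a few
percent of cells the mixture splits the negative cloud instead.

## Imaging stage

QC removes cells with area < 11 px or DNA below max(per-ROI 1st
percentile, absolute floor 1). Spillover compensation solves
`observed = x·S, x ≥ 0` per cell — an unconstrained solve with NNLS
fallback for rows driven negative by noise; compensation is exact to
1e−8 noise-free and adds little beyond shot noise (shot noise acts on the
integrated counts over a cell's ~40 px, not on the stored means).
Gating is per image with thresholds from two-component mixture fits per
channel; mutual exclusion (zero or ≥ 2 gate matches, or the CD20⁺CD3⁺
profile → unassigned) makes the result independent of gate order.

Label propagation trains on the gated cells (70/30 split; accuracy
reported on the held-out 30%) and labels only the unassigned cells —
gated labels are never overwritten. The default classifier is
distance-weighted k-NN (k = 25): the cells that mutual exclusion leaves
unassigned are precisely mixed-marker profiles absent from training
(CD20⁺CD11c-dim DN2, CD20-dim plasma cells), and nearest-neighbour
geometry extrapolates to them far better than axis-aligned tree ensembles
(97.8–98.2% vs ~94.5–95.1% end-to-end lineage recovery on the default
simulator). A 500-tree random forest remains available via
`classifier="random_forest"`.

Batch integration standardises the B-cell marker matrix (E-cadherin
included, for intraepithelial B cells), takes PCs, and iterates soft
k-means with per-batch linear corrections. Clusters straddling batches
receive per-cluster centroid shifts (diversity-weighted clustering keeps
them straddling); if no cluster straddles at all, mutually nearest
batch-pure cluster pairs vote a single rigid shift. A do-no-harm guard
reverts any iteration that widens the batch-centroid gap. Constant offsets
are removed essentially exactly while batches overlap in embedding space
(up to ~2 within-population s.d.); a fully separated offset is not
identifiable without assuming equal composition — a limitation shared by
reference integration tools — and is left uncorrected rather than risking
collapse of batch-unique populations.

B-subset naming clusters the corrected embedding with k-means (default
k = 20: with ten subsets plus background-bright artifact clusters, smaller
k forces merges such as MZB+MZP) and labels each cluster by the first rule
matching its median transformed profile, thresholds again from the
cluster-median gap rule.

## Spatial statistics

Distances are centroid-to-centroid, per ROI, computed with a KD-tree that
is exact (verified against the O(n²) minimum on random ROIs); epithelial
cells report the distance to the nearest *other* epithelial cell. Zone
assignment is boundary-inclusive with nested polygons resolved to the
smallest container. Expression contrasts default to the ROI as the unit of
analysis (per-ROI group means, paired t across ROIs), matching analyses
whose n is the number of imaged regions; pooled per-cell Welch tests are
available. Raster quantification thresholds with Otsu by default;
colocalization is (signal ∧ reference) / signal pixels, NaN (with a
warning) when no pixel is signal-positive.

## Spot stage

Normalisation is log1p of counts scaled to 10⁴ per spot — one code path
for both clustering and differential expression; rank-based DE is
insensitive to the monotone difference from variance-stabilising
transforms. HVG selection standardises dispersion within 20 mean-bins;
genes are standardised before PCA because on a targeted panel the HVG cut
retains everything and sparse low-count genes otherwise dominate the
log-scale variance and bury the coordinated programs.

The Potts sampler uses a shared spherical covariance (stabler than full
covariances at hundreds of spots), k-means initialisation, colour-class
parallel Gibbs updates (valid because same-colour spots are mutually
non-adjacent), per-sweep conjugate-style parameter refreshes, and the
per-spot marginal mode over post-burn-in samples as the final labelling.
Defaults: γ = 4, 1000 sweeps, 200 burn-in. With the degree-normalised
prior term `γ·n_i(k)/deg_i`, γ = 4 corresponds to a per-neighbour weight
of ~0.67 on a hex lattice, comparable to reference smoothing levels;
smaller γ under-smooths at 2σ cluster separation. γ = 0 reduces the
sampler to a plain Gaussian-mixture Gibbs sampler (ARI ≥ 0.95 against an
independent Gaussian-mixture fit on well-separated data).

The q-tuning curve records the negative pseudo-log-likelihood of short
chains per q. A curve that ends no lower than it starts carries no
evidence of structure beyond the smallest q (extra components only pay the
spatial prior's penalty) and suggests the smallest q; otherwise the
suggestion is the maximum-curvature point of the min–max-normalised curve.
The suggestion is advisory — the cluster count in the original analyses
was an inspection decision, and the pipeline accepts an explicit q.

Region DE: genes pass if |logFC| ≥ 0.25 (difference of mean log-normalised
expression, natural log) and ≥ 10% expression in either region; passing
genes are tested by Wilcoxon on the log-normalised values. Bonferroni
divides by the **total** number of genes in the table, the convention of
spot-level marker-detection tools: correcting only over filter-passing
genes is anti-conservative because the log-FC filter selects for small p.
Failing genes are flagged, never dropped. The gene–gene matrix computes
pairwise Spearman ρ over the selected spots with Holm over the unique
pairs.

Lymphoid-cluster selection scores clusters by mean expression of
MS4A1/IGHD/IGHM/CD19 and refuses ties (runner-up within 0.05) rather than
guessing. Subclustering merges samples, integrates with the batch
procedure above, and k-means-partitions the corrected embedding (default
5 subclusters).

## Problem sizes

Tests and the benchmark script run deliberately scaled-down problems
chosen to keep the whole suite in a few minutes while leaving the methods
unchanged: 5 donors × 2500 events (1500 after equal subsampling) over 100
replicates for the paired-enrichment rates; 16 ROIs of ~3700 cells for the
distance ordering; 40 × 40 lattices for spatial clustering; 30 × 30
lattices × 20 seeds for q-tuning; 200 null replicates of 17 × 18-spot
samples for family-wise error. The full-scale defaults (9214 events per
sample, 100 tree nodes, 1000 Gibbs sweeps) remain the library defaults.

## Known limitations

* The simulator's marker separations are generous; recovery percentages
  say little about antibody panels with genuinely overlapping populations.
* Batch integration cannot distinguish a batch offset from biology once
  batches no longer overlap in embedding space (see above).
* The Potts model's spherical shared covariance misfits elongated
  expression clusters; full covariance is available but less stable at
  small spot counts.
* Distance statistics are centroid-based; membrane-to-membrane distances
  require cell masks, which the segmented-table interface does not carry.
* The spot panel is targeted (~216 genes); transcriptome-scale HVG
  behaviour (2000 of ~18,000) is not exercised by the synthetic data.
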