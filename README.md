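# domemap

Multi-platform spatial analysis of gut-associated lymphoid tissue (GALT),
built as a tested, reusable pipeline with a ground-truth tissue simulator.

GALT — the organised lymphoid follicles beneath the intestinal epithelium —
is studied with several single-cell platforms at once: suspension mass
cytometry of paired tissue and blood B cells, imaging mass cytometry (IMC)
of segmented tissue sections, spot-level spatial transcriptomics, and
in-situ transcript imaging. `domemap` implements the full analysis chain
for each platform and, crucially, a synthetic GALT generator with known
ground truth (cell types, zones, gene programs, overlap fractions), so
every stage can be verified end to end without access to patient data.

The package is aimed at computational immunologists who want either the
individual building blocks (spillover compensation, SPADE-style clustering
trees, Potts-prior spot clustering, distance statistics) or the whole
pipeline as a benchmarked reference.

## What it computes

**Suspension cytometry** (`domemap.cytof`). Equal numbers of events per
sample (default *n* = 9214), density-dependent downsampling, k-means
clustering into tree nodes joined by a minimum spanning tree, rule-based
subset "bubbles" on node median profiles (DN2/3: CD27⁻IgD⁻CD21^lo CD11c^hi;
GC: CD38⁺⁺CD10⁺⁺; MZB: CD27⁺CD45RB⁺IgM⁺IgD⁺; …), and paired two-tailed
t tests of per-donor subset proportions between tissue and blood.

**Imaging mass cytometry** (`domemap.imc`). Per-cell mean intensities are
arcsinh-transformed (x ↦ asinh(x/5)), spillover-compensated by nonnegative
least squares against the mixing matrix S (observed = x·S, x ≥ 0), QC'd
(area < 11 px or low DNA removed), gated per image with mutually exclusive
lineage gates (B: CD20⁺; T: CD3⁺; Mac/DC: CD11c⁺∨CD11b⁺∨CD68⁺; endothelial:
CD31⁺; epithelial: E-cadherin⁺; CD20⁺CD3⁺ and multi-gate cells left
unassigned), propagated to unassigned cells with a supervised classifier
(70/30 train/test split), batch-integrated across ROIs, and clustered into
named B-cell subsets including intraepithelial DN (IEDN) and DN2.

**Spatial statistics** (`domemap.spatial`). Exact nearest-epithelial-cell
distances per ROI, polygon zone assignment, per-ROI positivity thresholds,
ROI-level paired expression contrasts, blob segmentation and pixel
colocalization fractions (signal∧reference / signal).

**Spot transcriptomics** (`domemap.spots`). Log-normalisation
(log1p(10⁴·count/total)), highly-variable genes, PCA (default 2000 HVGs,
15 PCs), and spatially regularised clustering by Gibbs sampling under a
Potts prior: the full conditional for spot *i* is

    P(z_i = k | …) ∝ N(x_i; μ_k, σ²I) · exp(γ · n_i(k) / deg_i)

where n_i(k) counts neighbours of *i* currently labelled *k* on the hex
lattice. A pseudo-likelihood curve over the cluster count q gives an
advisory elbow; region differential expression uses the Wilcoxon rank-sum
test with |logFC| ≥ 0.25 and ≥ 10% expression filters and Bonferroni
correction; gene–gene association uses Spearman's ρ with Holm-adjusted
pairwise p values.

**Simulator** (`domemap.synth`). A stylised follicle geometry (lumen, FAE,
SED, GC, mantle, T zone, lamina propria), two-component lognormal marker
models per cell type, a spillover forward model, per-ROI batch shifts,
hex-lattice spot counts with graded zone programs (DNASE1L3-anchored SED
program, MS4A1/IGHD follicle program, BCL6 GC program, ≥ 200 null genes),
and two-channel rasters at requested overlap fractions — all with recorded
ground truth and fully deterministic per-seed output.

## Worked example

Simulate five donors with paired tissue/blood samples and run the
suspension stage:

```python
import numpy as np
from domemap.synth import SimConfig, simulate_suspension_pair
from domemap.cytof import run_cytof_stage

config = SimConfig(seed=1)
events, truth = simulate_suspension_pair(config, n_donors=5)
result = run_cytof_stage(events.reset_index(), n_per_sample=9214, seed=1)
print(result.tests[["subset", "galt_mean", "pbmc_mean", "p_value"]]
      .round(4).to_string(index=False))
recovered = (result.event_labels
             == truth.loc[result.events["event_id"], "true_subset"].to_numpy())
print(f"\nevents assigned to their true subset: {recovered.mean():.1%}")
```

```
      subset  galt_mean  pbmc_mean  p_value
         DN1     0.0612     0.0604   0.9002
       DN2/3     0.0940     0.0489   0.0004
          GC     0.1840     0.0190   0.0000
         MZB     0.1032     0.1069   0.2304
         MZP     0.0481     0.0755   0.0002
         Mem     0.1800     0.2204   0.0073
       Naive     0.1688     0.4161   0.0000
       PB/PC     0.1600     0.0507   0.0000
unclassified     0.0007     0.0020   0.0098

events assigned to their true subset: 99.0%
```

The generator configures DN2/3 at twice its blood fraction in tissue and
leaves DN1 equal in both compartments: the stage detects the enrichment
(paired p = 0.0004, tissue mean 9.4% vs blood 4.9%) while the built-in
null subset stays non-significant (p = 0.90), and 99% of events land in a
tree node whose bubble matches their true subset.

The same pattern is available from the shell:

```bash
domemap run --seed 1 --out demo_out      # all stages, report.json + CSVs
domemap simulate --seed 1 --out sim_out  # write simulated inputs to disk
```

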