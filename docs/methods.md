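# Methods

This note documents the models and procedures implemented in `epidriver`,
the assumptions behind them, the defaults that matter, and what the
synthetic benchmarks do and do not demonstrate.

## Scope and design

`epidriver` re-implements, as a tested library, the bespoke computational
steps of a pan-cancer single-nucleus multiome (snATAC-seq + snRNA-seq)
analysis: unified peak catalogs, TF-IDF/LSI embeddings, closest-normal-cell
inference, differential accessibility with copy-number-aware filters,
correlation-based enhancer-to-gene linking with a diffuse-correlation
correction, regulon consolidation and AUC activity scoring, a supervised
between-cluster embedding with pseudotime for primary-to-metastatic
progression, and read-level variant / copy-number utilities.  Upstream
steps with mature standalone tools (read alignment, peak calling itself,
doublet detection, label transfer, GRN inference, CNV inference from
expression) are input boundaries: the package consumes their outputs as
plain-text tables.

Because the motivating analyses were performed on controlled-access
patient data, all quantitative checks here run on synthetic data with
planted ground truth.  The generator (`epidriver.simulate`) is first-class,
tested code; its defaults define the study conditions for every
recoverability claim below.

## Peak catalogs

Peaks carry a MACS2-style significance score (−log10 q).  They are resized
to 501 bp centred on the summit (`[summit−250, summit+251)` under 0-based
half-open arithmetic); a resized peak crossing a contig start is an error,
never a silent clip.  To compare significance across samples, scores are
converted to score-per-million (SPM): `score × 1e6 / Σ score` within each
sample, so SPM sums to 1e6 per sample.  Overlap resolution is iterative
removal — keep the most significant peak, delete everything sharing ≥1 bp
with it, repeat — implemented as a single descending-score sweep, which is
provably equivalent to the literal re-scan and is checked against a
brute-force oracle.  Score ties break by (chrom, start) so results are
platform-stable.  Cohort catalogs renormalize SPM within each sample and
merge across samples; the pan-cancer catalog renormalizes within each
cohort and merges cohort sets.  Whatever score column enters a merge stage
is the one renormalized.

Cell QC applies the fixed accessibility gates (all strict): 1,000 <
fragments in peaks < 20,000; % reads in peaks > 15; blacklist fraction
< 0.05; nucleosome signal < 5; TSS enrichment > 2.  Promoters are the
strand-aware (−1000, +100) window around the TSS.  Regulatory-element
labels require ≥400 bp of overlap.

## Embeddings

TF-IDF: `ln(1 + 1e4 · TF · IDF)` with TF the within-cell frequency and
IDF = n_cells / row sum — the convention of the standard single-cell ATAC
toolkits (the scale factor and log1p are documented choices, since
"TF-IDF" alone underdetermines them).  LSI is truncated SVD of the
normalized matrix; the cell embedding is `V·S`, signs fixed by making the
largest-magnitude feature loading of each component positive.  Component 1
tracks depth and is dropped by downstream consumers (components 2..30 or
2..50).  Components are not standardized afterwards.

Between-cluster analysis (BCA) is the supervised reduction used for
trajectory input.  With cluster centroids μ_k and sizes |C_k|, the
between-cluster scatter is S_B = Σ_k |C_k| μ_kᵀ μ_k — deliberately
*without* grand-mean centring, matching the definition used in the
source analyses rather than the classical LDA scatter; a `center` flag
restores the conventional behaviour.  W maximizing tr(WᵀS_B W) over
orthonormal W is the top r = K−1 eigenvectors of S_B, and the embedding is
Y = XW.  The achieved trace is verified against a dense eigensolver and
against random orthonormal projections.  With K = 2 the embedding is
one-dimensional and flagged; 2-D consumers need K ≥ 3.

## Differential testing

Marker tests are two-sided Wilcoxon rank-sum with the tie-corrected normal
approximation, after detection-fraction pre-filters (`min.pct`-style).
DACRs use a logistic-regression likelihood-ratio test with the per-cell
fraction of fragments in peaks as a latent covariate; p-values come from
χ²(1) on the deviance difference.  The per-feature logistic fits use a
small batched Newton/IRLS routine (bounded iterations, so quasi-separated
features return a converged deviance with a flag); it is cross-checked
against statsmodels on reference fits and calibrated on simulated nulls.
Bonferroni is the default adjustment for DEG/DACR families, BH for
regulon/motif/correlation families.  Log2 fold changes use a pseudocount
of 1e-4 on group means (configurable; the upstream tool's exact formula is
unpublished).

CNV-aware filtering removes DACRs whose direction matches a frequent
copy-number event at the nearest gene (log2FC > 0 with AMP > 0.25, or
log2FC < 0 with DEL > 0.25, both strict).  Metastasis DACRs are ranked by
the fraction of metastatic samples with positive fold change, then mean
fold change, keeping the top 200.  Metastasis-associated TFs must be
FDR < 0.05 with concordant direction in both motif-score and
regulon-activity tests; the expression score is |log2FC| on per-sample
average expression, zeroed when its sign disagrees with the motif shift.

## Closest normal cell (CNC)

For each cohort, pseudobulk profiles (feature means) are computed for each
tumour sample and for each candidate normal type (cells pooled across
samples).  Pearson correlation per (sample, type) over an explicit marker
feature set, median across samples per type, argmax wins.  The feature set
is always supplied by the caller (in the pipeline: unions of differential
features); ties select the lexicographically smallest type with a warning.

## Enhancer-to-gene linking

Candidates are (peak, gene) pairs with the peak midpoint within 500 kb of
the TSS, over cells with joint measurements.  For each pair, Pearson r of
accessibility versus expression is compared with a null of the 200 peaks
nearest the focal peak in mean accessibility (matching on accessibility
only — synthetic peaks have no sequence, so no GC matching; the hook is
extensible): z = (r − μ_null)/σ_null, one-sided normal p.  Links require
r > 0.05 and p < 0.05, applied before the corrections below (gate first,
then correct).

*Diffuse-correlation correction.*  Broad regional accessibility can drive
apparent peak–gene correlation without a specific element.  Chromosomes
are tiled with 100-kb windows anchored at 0; window accessibility is the
summed counts of member peaks; window–gene correlations are computed for
genes with TSS within 500 kb.  Link r values are z-scored across all
links, window r values across all window–gene pairs (global scope for
both; the scope is this package's choice), and a link survives only if its
z exceeds that of (its window, same gene).  The correction is strict by
construction when a window contains a single dominant peak, so it is
evaluated on a designed simulation in which diffuse windows (all member
peaks following a shared latent factor, gene driven by the window sum) and
specific windows (one causal peak among background peaks) coexist: the
correction removes ≥80% of the diffuse per-peak links and keeps every
specific one.

Genes amplified in >25% of cancer cells *and* >2,000 cells are excluded.
Transition-associated links additionally require the peak to gain
accessibility (log2FC > 0.5, FDR < 0.05) and the gene to be upregulated
(log2FC > 0.25, FDR < 0.05) in primary cells versus the CNC.
Enhancer-level z is the mean of member-link z values.

## Regulons

Stochastic GRN inference is consolidated across n = 10 runs: a TF–target
pair must appear in ≥ ⌈0.8·n⌉ runs, and regulons keep ≥20 surviving
targets.  Activity is the AUCell statistic: per cell, genes are ranked by
descending expression (ties broken by gene index for determinism); with
T = ⌈0.05·n_genes⌉ (the cited tool's default threshold, configurable) and
recovery curve H(k), the score is ΣH(k)/ΣH_max(k) over k ≤ T, in [0, 1]
and invariant to monotone transforms within a cell.

Group-specific regulons require BH FDR < 0.05 against all other cells, a
mean ratio > 1.5 and a focal mean above the median of per-group means; the
top 10 by fold change are reported per group.  Cancer-cell-specific
annotation versus the CNC requires FDR < 0.05, mean difference > 0.01 and
log2 ratio > 0.1.

*TF-link enrichment.*  For a regulon with N targets, the observed count M
of targets linked to motif-containing peaks is tested against 500
samplings of N genes drawn without replacement from the expressed-gene
pool: z = (M − μ)/σ from the sample moments, one-sided normal p, fold =
M/μ.  σ = 0 degenerates to p = 0.5 when M = μ (and a flagged floor when
M > μ).  The z statistic is validated against exact hypergeometric moments
and an oversampled Monte-Carlo draw; the test is calibrated under random
regulons.

Pathway scoring of target sets uses the Jaccard index plus hypergeometric
over-representation within an expressed-gene universe, BH-adjusted.

## Trajectories

A case needs primary and metastatic cells.  X is LSI components 2..50.
With normal cells present, the condition annotation (K = 3) is the
clustering and BCA supplies a 2-D embedding; with two clusters the LSI
components are used directly (BCA would be 1-D).  The start cluster is
normal, else primary.

Lineage fitting is a deliberate simplification of curve-based trajectory
tools, which are not re-implemented here: the cluster path is the
minimum-spanning-tree path over cluster centroids from the start, and
pseudotime is the arc length of each cell's orthogonal projection onto the
piecewise-linear centroid path.  This is deterministic, invariant to rigid
rotations, and validated by recovery tests against planted pseudotime.

TF motif scores are Pearson-correlated with pseudotime over all cells on
the trajectory (BH over the full panel, FDR ≤ 0.05; constant scores are
excluded).  Peaks associated with pseudotime or a TF score are selected by
lasso with λ at the 10-fold cross-validation minimum (seeded folds,
descending data-derived λ path of 100 values, coordinate-descent tolerance
1e-4).  Genes of selected peaks feed a hypergeometric ORA, optionally
capped by fold change (top 1,000 / 5,000 in the motivating analyses).

## Variants and copy number

Read tables (barcode, chrom, 1-based pos, allele, read id) replace BAM
parsing.  Per-cell allele counting reports ref/alt/other reads per group
and rates normalized by group cell counts (counts conserve: ref + alt +
other = covering reads).  Adjacent SNVs (pairwise distance ≤ 2 bp,
transitive closure) merge into DNPs when the fraction of reads spanning
all sites that carry all alternate alleles is r_c = n_c/n_t ≥ 0.8; sets
without spanning reads stay unmerged with a flag.  Somatic filters:
tumour/normal depth ≥ 14×/8×, tumour VAF ≥ 0.05, normal VAF ≤ 0.02, no SNV
within 10 bp of a same-sample indel, with driver-gene rescue for tumour
VAF in [0.015, 0.05).  Gene-level CNV calls use the overlap-weighted mean
copy ratio across segments, with fixed default bounds (0.9, 1.1) — the
upstream caller's data-driven z-threshold is simplified to these printed
defaults, configurable — and genes overlapping no segment are "unknown".

## The synthetic generator

No generative model exists in the motivating study (it uses real data), so
all distributional choices are this package's own:

- **Accessibility** is Bernoulli per (cell, peak): background probability
  0.05, foreground 0.5.  Each normal cell type has a marker-peak program;
  tumour cells are a perturbed copy of normal type 0 (the planted CNC),
  retaining 80% of its markers plus a shared tumour signature.
- **Links**: planted peaks sit within 500 kb of their gene's TSS (decoys
  inside and outside the window; peak summits on a 1-kb grid 3 Mb gene
  territories, so 501-bp peaks never overlap); the linked gene's negative
  binomial mean is `base + link_effect × accessibility` (identity link;
  dispersion parameter 10).  Default effect 2.0 yields planted Pearson
  r ≈ 0.5 at 2,000 cells.
- **Trajectory**: cells on the normal → primary → metastatic continuum get
  pseudotime uniform in thirds of [0, 1]; a metastatic program (20% of
  non-link peaks — sized comparably to the union of marker programs so
  progression is a leading axis of variation, as in epithelial-mesenchymal
  transition data) ramps its accessibility linearly with pseudotime.
- **Regulons**: each TF and its targets are boosted 3× in a focal cell
  group; repeated GRN "runs" report true targets at 90% and TF-specific
  spurious targets at 20%.
- **Reads/segments**: DNP pairs at configured co-occurrence rates with
  binomial read-level sampling (1-based positions); copy-ratio segments
  tile each chromosome with forced breakpoints inside some gene bodies.

Defaults: 3 normal cell types × 200 cells plus 200 primary and 200
metastatic cells (1,000 cells), 2,000 peaks, 500 genes, 30 planted links,
4 regulons × 30 targets, seed 0.  One global seed fans out to named
per-stage child seeds, so stages re-run independently and byte-identically.

What the generator does **not** emulate: sequence content and GC bias (so
background matching uses accessibility only), doublets, batch effects,
fragment-level counts (accessibility is binary), branching trajectories,
and realistic LD/cohort structure in variants.  Passing recovery tests
therefore demonstrates the correctness and calibration of the procedures
under their stated assumptions, not their performance on real tissue data.

## Problem sizes used in the checks

Link recovery runs at 2,000 cells × 5,000 peaks × 1,000 genes with 50
planted links; CNC recovery uses 100 seeded compact simulations (300
cells each); pseudotime recovery uses 10 seeds at the default
configuration; lasso power/null use 100 seeded runs at 100 cells × 500
peaks; enrichment calibration uses 500 replicates of 500 samplings; DNP
thresholds use 20 seeds.  These sizes are the package's documented study
conditions and are reproduced end to end by `scripts/acceptance.py`.

## Known limitations

- The diffuse-correlation correction with global z-scoring is conservative
  for windows dominated by a single peak (see above); in sparse synthetic
  catalogs it removes most single-peak links, which is why link-recovery
  claims refer to the significance-gated linking stage and the correction
  is validated on its designed simulation.
- The MST-path pseudotime assumes a single unbranched lineage.
- The sampling enrichment test's normal tail is approximate for very small
  target sets; the hypergeometric moments check bounds the error.
- The logistic LRT assumes independent cells (no pseudo-replicate or
  mixed-model correction).
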