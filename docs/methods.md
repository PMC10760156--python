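# Methods

This note documents the models, defaults and design decisions behind
`incitekit`: what each stage computes, why the open choices were made the
way they were, and what the synthetic cohorts do and do not emulate.

## Data model

Three aligned containers: a nuclei × genes sparse integer RNA count
matrix, a nuclei × antibodies integer capture matrix whose panel carries
roles (`target` proteins, exactly one `normalizer` — histone H3 — and
donor `hashtag`s), and a per-nucleus metadata table (donor, disease group
∈ {young_ctrl, old_ctrl, AD, ALS, FTD}, age, 10x well batch; synthetic
cohorts add `true_*` ground-truth columns).

## Demultiplexing and QC

The hashtag demultiplexer is a transparent ratio rule: assign the top
hashtag when its counts reach an absolute floor (default 50) and dominate
the runner-up by a ratio (default 3); otherwise `negative` or `ambiguous`.
It deliberately does not model ambient hashtag background the way
model-based deconvolution tools do — the generator's ground-truth hashes
exist precisely so its accuracy is measured, not assumed (≥95% correct at
the default signal-to-noise of 20, monotone in that parameter).

Nucleus filters, with boundary semantics read literally from their stated
rules: keep a nucleus iff detected genes ≥ 50, mitochondrial count
fraction ≤ 0.05 (strictly more is removed), summed hashtag counts ≤ 4000
and raw TDP-43 antibody counts ≤ 3000 (both strict). The hashtag ceiling
is applied to the *summed* hashtag counts (the rule's purpose is to remove
hash-aggregate artifacts, which inflate the total). The TDP-43 ceiling
applies to raw counts before any normalization, since it sits among the
raw-count QC rules; when the panel lacks a TDP-43 antibody the rule is
skipped with a warning. Gene filtering (detected in ≥ 5 nuclei) runs after
nucleus filtering. Removal counts are reported per rule; a nucleus may
count toward several. Filtering is idempotent. Synthetic doublets carry
ground-truth flags which the pipeline honours; a heuristic
(ambiguous hashtag AND total counts above the 99th percentile) is provided
as clearly-labelled plumbing, not a substitute for transcriptome-based
doublet detection.

## Expression pipeline

Counts are scaled per nucleus to a common target sum (default 10,000 —
the conventional choice; it cancels in fold-change comparisons) and
transformed by ln(x+1). Variable genes use the binned-dispersion
procedure (mean band 0.0015–0.18, normalized dispersion > 0.30, 20 mean
bins), delegated to scanpy's implementation of exactly that recipe. Those
band defaults presuppose a transcriptome-scale gene universe; the
synthetic cohorts have a few hundred genes with correspondingly higher
per-gene means, so the end-to-end driver keeps all genes instead of
applying the band. Log counts are then residualized per gene against
total UMI (OLS with intercept; residuals with numerically-zero variance
are left at 0) and z-scored with clipping at ±10. Order — regress, then
scale — is the one that makes the clip threshold meaningful in units of
residual standard deviations.

Embedding: PCA (arpack solver, 40 components, clipped with a warning when
the data are smaller), pluggable batch correction whose default is
per-batch mean-centering in PC space (model-based integration like
Harmony is an external backend by design; on synthetic cohorts centering
suffices and keeps the stage exactly reproducible), kNN graph (k=10,
UMAP connectivities), Leiden at resolution 0.8, optional UMAP for
visualization only. The two-pass strategy separates cell-type discovery
(first pass: center out well batch *and* donor, so disease structure is
removed) from disease-state discovery (second pass on one cell type,
batch-only correction).

A property of community detection worth knowing when interpreting
subclusters: at a fixed resolution, an *isolated* structureless population
is typically split into several communities (modularity finds partitions
even in near-random kNN graphs), while the same population embedded in a
larger graph is protected by the resolution limit. Subclusters of a
homogeneous cell type are therefore expected to be exchangeable —
indistinguishable in composition — rather than absent; the tests assert
exactly that.

Differential expression is a per-gene Welch two-sample t-test on the
log-normalized matrix with Benjamini–Hochberg adjustment (the correction
procedure is configurable; BH is the default in the absence of a stated
choice). Genes with zero variance in both groups and equal means get
t=0, p=1. Cluster composition: per-donor cluster proportions (rows sum
to 1) and Spearman rank correlation against donor covariates
(average-rank ties).

## Nuclear protein quantification

`h3_ratio = counts / H3 counts` per nucleus; nuclei with zero H3 cannot
be normalized and are dropped from protein analyses (retained for RNA),
with a warning carrying the count. The centered log-ratio

    nCLR_ij = ln((x_ij + ε) / gmean_j(x_ij + ε))

is taken over the *target* panel only — H3 is the normalizer, hashtags are
identity tags, neither is a measurement. The printed form of the ratio
without a logarithm would not be centered (its panel sum is not
constrained); the log form is what "centered log ratio" names, and its
zero-sum identity is asserted to 1e-9 in the tests. The pseudocount ε
(default 1e-6 on the ratio scale) guards zeros and may be set to 0 when
all ratios are positive. Both h3_ratio and nCLR are invariant to scaling
a nucleus's whole antibody vector (capture depth).

**Scale choice for stoichiometry.** nCLR components sum to zero, so
regressing one component on another necessarily mixes in the remaining
panel members through the shared geometric mean — the classic spurious
correlation of compositional data. A shift δ confined to one protein
appears in its own nCLR attenuated by (1 − 1/n_panel) and leaks into every
other component by −δ/n_panel; for the 3-target panel the net attenuation
of the decoupling estimate was measured at ~0.75. Pairwise analyses
(`stoich_curve`, `decoupling_statistic`) therefore default to the additive
log-ratio ln(target/H3), which isolates the pair under study and is
equally capture-depth invariant. nCLR remains the scale for
stratification, quintiles and density maps (rank-based, so the distinction
is immaterial there), and the stoichiometry functions accept any value
matrix if the CLR variant is wanted.

Strata are percentile bins over a chosen protein, computed on the supplied
population — pool the nuclei of the cell type under analysis (the
default reading), or pass per-donor slices for donor-wise referencing.
Bins are (lo, hi] with the bottom bin closed at zero; ties are resolved by
stable ordinal ranks with a warning (this keeps occupancies at their
nominal widths; for distinct values it coincides with average ranks).
Embedding density is a Gaussian kernel sum over stratum members evaluated
at every nucleus, normalized to [0,1] by its maximum; bandwidth defaults
to Scott's rule on the members, with a fixed-bandwidth override for exact
reproducibility. Whether such maps should instead be normalized to the
overall embedding density is a presentation choice; both modes are
provided (`embedding_density`, `embedding_density_ratio`).

## Pathway activity and GSEA

mlm activities: each nucleus's expression vector is regressed jointly on
all pathway weight columns plus an intercept; the activity is the
coefficient t-value (not the raw coefficient — t-values put pathways with
different weight norms on one scale). Collinear weight tables fall back to
a ridge-regularized fit with a logged penalty; exact fits floor the
residual variance at numerical precision so genuinely-zero coefficients
report zero activity. Weight tables are user-supplied (PROGENy-style
top-N footprints); the synthetic cohorts ship ground-truth gene programs
that serve the same role in tests.

Pre-ranked GSEA: genes ranked by a signed score (default: the DE
t-statistic; logFC is configurable), hits increment the running sum by
|score|^p normalized by the set total (p=1 default), misses decrement by
1/(N − n_set); ES is the signed extremum. Because the input is a ranking
rather than per-sample expression, the null is gene-label permutation:
random same-size sets (default 1,000 permutations, seeded). NES divides
ES by the mean |ES| of same-sign permutations; p is the same-sign
permutation tail; FDR follows the permutation-pool procedure over
pooled null NES values (BH over permutation p-values is available as an
alternative). The implementation is checked against brute-force
running-sum enumeration on every random instance up to N=50, and its null
p-values against uniformity. Heatmap filtering retains pathways at FDR
below threshold (default 0.01) in at least two contrasts. The pathway
network weights edges by Jaccard overlap of member genes with greedy
modularity communities.

## Stoichiometry and the decoupling statistic

`stoich_curve` bins the pooled x (NF-kB) into equal-frequency bins
(default 20) and reports each group's mean ± SE of y (TDP-43) per bin —
binned means rather than a smoother, for determinism and testability
(LOESS is a plotting nicety, not part of the statistic).

`decoupling_statistic` formalizes "TDP-43 drops relative to NF-kB at the
top of the NF-kB range":

1. Mark top-stratum nuclei: x above the 75th percentile, computed within
   each donor by default. Per-donor cutoffs make the stratum invariant to
   donor-level shifts in capture or staining and match how the breakdown
   is defined per donor; pooled cutoffs are available.
2. Fit OLS of y on x over pooled control nuclei *below* the cut — the
   region where the coupled relationship is assumed intact.
3. Δ_g = mean over group g's top-stratum nuclei of (observed − predicted
   y), **minus the same quantity over the pooled-control top stratum**.
   Referencing to controls cancels any bias shared by all groups from
   extrapolating the linear fit into the stratum (under heteroscedastic
   counting noise E[y|x] is only approximately linear, and the groups'
   x-distributions match, so the residual bias is common-mode).
4. A guard band (default 5 percentiles) just above the cut is excluded
   from the *evaluation* (not the fit): measurement noise makes stratum
   membership ambiguous near the threshold, so boundary nuclei are a
   mixture of truly-above and truly-below populations and dilute any
   shift confined to the stratum (measured ~7% multiplicative dilution
   without the band). Set `guard_pct=0` to recover the plain top-25% mean.
5. Confidence intervals: bootstrap resampling donors, then nuclei within
   donor (respecting the clustering of nuclei in donors). With a handful
   of donors the cluster-bootstrap percentile interval is anti-
   conservative, so the interval is point ± t(d−1, 0.975) × bootstrap SE
   with donor-level degrees of freedom; a flat nucleus bootstrap with
   percentile intervals is available and used where speed matters.
6. One-way ANOVA with Tukey HSD compares top-stratum residuals across
   groups (stars: *** P<0.001, ** P<0.01, * P<0.05, two-sided).

Validation is by parameter recovery: on cohorts where the decoupling
shift is the *only* disease effect on TDP-43
(`stoichiometry_cohort_config`), Δ̂ recovers injected shifts of 0, −0.25,
−0.5 and −1.0 with bias ≤ 0.05 and control intervals covering zero in
≥95% of runs (4 donors/group × 150–300 nuclei, i.e. 3,000–6,000 nuclei —
sizes chosen so the donor bootstrap has ≥4 clusters per group and the
whole grid runs in seconds). The default cohort deliberately adds a second
TDP-43-lowering mechanism (the disease endothelial state, below); with
both active the statistic measures their sum, which is why recovery is
validated on the isolating configuration.

## The synthetic cohort generator

What it emulates, per nucleus:

* **Design**: five donor groups, configurable donors per group (default 3)
  and nuclei per donor (default 300); donors interleaved across 10x wells
  so each well mixes control and disease donors; ages uniform within
  group ranges (15–29 young controls, 67–95 aged controls and AD, 55–85
  ALS/FTD). Cell types drawn at the sorted composition (EC 0.50,
  microglia 0.25, neuron 0.15, other 0.10).
* **RNA**: gamma-Poisson (negative binomial, dispersion 10) around
  cell-type signatures with exclusive marker blocks; per-nucleus library
  sizes log-normal around 2,000 UMI; mitochondrial genes (3% of the
  panel) at a mean 2% of counts with a log-normal per-nucleus spread so a
  small tail crosses the 5% QC ceiling.
* **Proteins** (natural-log latents): NF-kB normal per cell type
  (microglia run higher), TDP-43 = 0.8 × NF-kB + noise (sd 0.3),
  β-Catenin independent. Disease nuclei above their donor's 75th NF-kB
  percentile get `decoupling_delta` (default −0.5) added to TDP-43 — the
  stoichiometric breakdown. Antibody counts are Poisson around
  depth × scale × exp(latent) with a shared log-normal capture depth;
  H3 scale 1,000 and target scale 300 put counts where relative Poisson
  noise is a few percent. The magnitude of the TDP-43 drop is not an
  estimate of any real effect — it is a calibration knob for validating
  the estimator.
* **Disease endothelial state**: 60% of disease-donor EC nuclei enter a
  state with Wnt targets down (log-fold −1), NF-kB targets up (+1), and
  nuclear β-Catenin and TDP-43 each 0.5 lower — the disease-enriched
  capillary subcluster with its protein signature. Disease-donor
  microglia enter a DAM-like state (60%; aged controls 20%, young 5%)
  with DAM markers up and homeostatic markers down.
* **Hashtags**: one dominant hashtag per singlet at signal-to-noise 20
  over Poisson ambient counts (mean 10). Doublets merge random nucleus
  pairs (counts summed, so cross-donor doublets carry two strong
  hashtags), at a default rate of 5%.

What it does not emulate: ambient RNA, sequencing-read structure,
batch-specific antibody efficiencies, cell-type proportions varying by
donor, spliced/unspliced structure, spatial organization, or any real
gene identity (programs are synthetic gene lists emitted as ground
truth). Passing tests therefore demonstrate that the *statistics* recover
engineered effects under realistic count noise and multiplexing
structure — not that any biological conclusion transfers to real tissue.

## Numerical choices and degenerate inputs

Fixed seeds make every stage bit-reproducible (generator, Leiden, UMAP,
permutations, bootstraps); seeds derived inside the acceptance script stay
below 2^31. Zero-total nuclei are rejected by normalization (impossible
post-QC). Residuals and exact fits are floored at numerical precision
rather than amplified (regress-out scaling, mlm t-values). CLR requires
≥2 targets; empty or universe-spanning gene sets are rejected; a stratum
of size one yields a single-kernel density with a warning. Tie handling:
ordinal (stable) ranks in strata with a warning; average ranks in
Spearman. n_pcs is clipped to the data dimension with a warning.

## Known limitations

The demultiplexer ignores ambient-hash structure; the default batch
correction is mean-centering, not a mixture/harmony-style integration;
GSEA uses gene-label permutation, which treats genes as exchangeable and
ignores inter-gene correlation; the decoupling statistic assumes the
control relationship is linear on the log scale below the stratum and
only corrects shared departures; the generator's disease effects are
piecewise (threshold) rather than smooth. HVG defaults target
transcriptome-scale data and are not meaningful on few-hundred-gene
cohorts.
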