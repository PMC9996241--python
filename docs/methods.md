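# Methods

## Activity inference

### Kinase z-test

The activity of kinase *k* in sample *s* is scored from the residualised
log2 fold-changes of its substrate phosphosites.  With x̄ the mean over the
*N* substrates measured in the sample, and μ, σ the mean and standard
deviation of **all** phosphosites measured in that sample, the statistic is

    z = (x̄ − μ) / (σ / √N),

two-tailed p from the standard normal, reported as the signed score
AS = sign(z)·(−log10 p).  Design points:

* **Background definition.**  The background includes the kinase's own
  targets.  The alternative (leave the targets out of μ and σ) is exposed
  as `exclude_targets_from_background`; for realistic substrate counts
  (tens) against site totals (thousands) the two are numerically
  indistinguishable, but the switch matters for small constructed inputs
  and for exactness tests.
* **Filters.**  A cell is reported only when at least `min_targets`
  (default 3) substrates are measured.  Samples whose background SD is 0
  are skipped with a warning — a degenerate sample carries no usable
  contrast.
* **Numerical floor.**  p is floored at 1e-300 before the log so scores
  stay finite.
* **Self-site mode.**  `mode="self_sites"` scores a kinase on phosphosites
  residing on the kinase itself, restricted to sites annotated as
  regulatory or with a functional score above 0.4; sites without a score do
  not pass the gate.  This is a validation mode, not the default
  inference.

### TF regulon enrichment

Per sample, measured gene statistics are rank-transformed to quantiles
q = rank/(n+1) (average ranks on ties) and mapped through Φ⁻¹; the score is
NES = Σ mode·Φ⁻¹(q) / √m over the m measured regulon targets, reported when
m ≥ `min_regulon` (default 5).  This is a deliberately transparent signed
enrichment statistic with an analytic null (≈ N(0,1) under random ranks,
verified by permutation calibration): it follows the same
regulon-with-modes input contract as the established two-tailed regulon
enrichment tools, but does not replicate their pleiotropy correction or
three-tail variants.  Correctness is therefore claimed via
null calibration and planted-signal recovery, not via equality with any
external implementation.

## Preprocessing

* **Fold-changes.**  Abundances become log2(v + pseudocount) centred on the
  per-feature median (pseudocount 1).
* **Outlier samples.**  A sample is dropped when |median log2FC| over
  features strictly exceeds 1 (a two-fold global shift indicates a
  normalisation failure, not biology).
* **Quantile normalisation.**  The reference distribution is the mean of
  the column quantile functions on a common grid — for complete columns
  exactly the per-rank mean of sorted values.  Ranks are computed on
  observed values only; the reference is interpolated to each column's
  observed count; ties take average ranks, hence the mean of the reference
  values they span.  Missing cells stay missing.  The transform is exactly
  idempotent on complete matrices; with missing data idempotence is only
  approximate because the reference is re-estimated from interpolated
  columns.
* **Residualisation.**  Per-row OLS on complete cases: phosphosites on
  their host protein plus age/gender, or covariate-only for batch removal
  (study as one-hot).  Rows with fewer than 3 usable samples (or no matched
  predictor) pass through unchanged and are flagged; single-level
  covariates are dropped with a warning.  Fitted residuals are orthogonal
  to their predictors to better than 1e-8.
* **Phosphosite deduplication.**  Multiply-phosphorylated peptides are
  excluded; duplicate site keys collapse only when their value vectors are
  identical (missing-aware), otherwise all copies are dropped.
* **Sequence validation.**  Sites and mutations are kept only when the
  declared residue matches the FASTA sequence at the 1-based position;
  splice-site records carry no residue and pass unchecked; proteins absent
  from the FASTA reject the item with reason `no_sequence`.
* **Mutation matrix.**  Binary gene × sample; silent and splice-site calls
  never set a cell.
* **Imputation.**  Where clustering needs complete input, missing
  correlation cells are imputed with the column median — a deterministic
  choice, logged, in place of model-based imputation.

## Association models

OLS throughout, fitted per pair on complete cases via the normal equations,
with the experimental study one-hot encoded against a reference level
(singleton studies merge into the reference with a warning).  p-values are
coefficient t-tests; BH adjustment runs within each response family
(kinase responses and TF responses separately; per-hotspot families for the
joint recurrent-mutation model).  Filters for the mutation model: genes
mutated in more than 20 samples, activities measured in at least 10, and at
least 5 carriers among the pair's complete cases.  Association sets are
validated by one-sided Fisher exact enrichment among protein-interaction
edges with combined score ≥ 850, along a grid of −log10 FDR cutoffs.

Differential expression between activity-defined groups uses the log2
ratio of group means on the linear scale and a Wilcoxon rank-sum test;
samples inside the noise gate (|AS| ≤ 0.15) are excluded from the group
split.

## Landscape analyses

* **Activity-vs-layer correlations.**  Pearson r per regulator against its
  own CNV/mRNA/protein levels; the phosphorylation summary is the mean of
  the regulator's own measured site residuals (the per-protein summary is
  otherwise underdetermined).  Pairs with fewer than 10 overlapping samples
  are labelled `unknown`; the rest are BH-adjusted per layer and called
  significant below 0.05.
* **Kinase-pair correlations.**  Spearman over shared samples, annotated
  pairs stratified by source support against an unannotated background,
  compared by one-sided rank-sum tests.
* **Redundancy reduction.**  Complete-linkage clustering on 1 − Jaccard
  index of substrate sets, cut at height 0.85 (0.8 for the pair-correlation
  control); one kinase per cluster survives — most substrates, ties
  lexicographic.  Variable-kinase selection (SD strictly above the median
  SD) runs on the post-reduction set.
* **Tumour vs perturbation specificity.**  Per-kinase regulation
  percentages (|AS| > 1.75) in the two sample sets; kinases regulated in
  neither are excluded; a linear fit relates the two percentages and
  standardised residuals beyond ±2 flag specificity.  The regression
  orientation is ambiguous in principle; the default takes the tumour
  percentage as the response, under which residual z > 2 means
  tumour-specific, and `response="perturbation"` swaps the orientation
  (and with it the sign convention of the calls).

## Survival

Samples are stratified per regulator at |AS| = 1.75 with strict
inequalities (boundary scores are neutral).  Log-rank tests span all
populated strata, gated per protein class: TFs need more than 10 deaths
and more than 10 samples active **and** inactive; kinases, with rarer
extreme scores, need more than 5 deaths and more than 5 active **or**
inactive.  The Cox model treats the activity score as a continuous
predictor adjusted for age, gender and binary genotypes of recurrently
mutated genes; the genotype panel is defined as genes with at least
`min_mut_for_genotype` mutated samples in the input cohort (default 100,
reduced in synthetic runs to match cohort size), which makes panel
membership data-dependent rather than a fixed list.  Ties use the Efron
approximation; non-convergent fits are flagged and excluded from the BH
family.  Hazard ratios are exp(coefficient) with Wald 95% intervals.

## Sample clustering

The sample × sample Spearman correlation of combined kinase + TF activity
profiles (pairwise-complete, ≥ 3 shared features) feeds Euclidean distances
between correlation rows and a complete-linkage tree cut into k groups
(default 8; a k-groups cut implements "minimum height yielding k groups").
Cluster ids are reassigned by decreasing size for stable reporting.
Cluster-level regulator scores are median/SD of member activities
(degenerate below 2 members or at zero spread); |score| ≥ 2 marks
deregulation.  Clinical levels (BMI binarised at 37, age at 50, levels with
under 5 patients excluded) are tested per cluster with the hypergeometric
upper tail, BH-adjusted across all tests.

## Benchmarking substrate priors

Absolute activity scores classify gold-standard (kinase, condition) pairs
against pairs of unknown regulation.  Because unknowns dominate, AUROC
(rank formulation, ties ½) is averaged over 100 balanced resamples of
negatives drawn without replacement, matched in size to the positives; an
optional equal-subsample mode also subsamples positives to a fixed size so
priors with different coverage are comparable.

## Synthetic cohort

The generator emulates the statistical structure the analyses assume, not
tumour biology:

* **Layers.**  mRNA/protein/phosphosite values are Gaussian log2
  fold-changes with per-(study, feature) additive batch offsets
  (SD 0.3) and missingness completely at random (rate 0.1).  Copy-number
  calls are discrete −2..2, mostly 0.
* **Activity.**  Each regulator belongs to one of 3 latent sample blocks,
  with a random sign, and is active only in a thinned subset of its block:
  the overall active fraction defaults to 0.1, reflecting that strong
  regulation is a minority event per regulator in tumour cohorts.  Active
  kinases shift their substrate sites by δ = 1 log2 unit against
  phosphosite noise SD 1; active TFs shift target transcripts by
  mode · δ.  Phosphosites additionally carry 0.8 × host-protein abundance,
  the confounding the residualisation step must remove; two
  autoregulatory-like sites per kinase carry the kinase's own signal
  without being part of the substrate prior.
* **Genetics.**  Five planted (mutated gene → kinase) effects (carrier
  fraction 0.15, shift 1.0 on the substrate scale) over a background
  mutation rate of 1%; loss-of-function carriers lose 0.5 log2 units of
  protein abundance.  Planted pairs enter the edge list at score ≥ 850
  with sub-threshold decoys.  FASTA sequences satisfy every declared site
  and mutation residue.
* **Survival.**  Exponential event times with per-sample hazard
  baseline · exp(Σ log-HR · activity) (default log-HR = ln 2 for one kinase
  and one TF) and uniform censoring — the simplest model with an
  interpretable planted hazard ratio.
* **Effect-scale helpers.**  Mutation-effect and hazard recovery at exact
  planted magnitudes is checked with direct activity-scale simulators
  (`simulate_activity_given_mutations`, `simulate_survival_from_activity`),
  because through the full pipeline the activity readout is a nonlinear
  (signed −log10 p) transform of the planted substrate shift and the
  coefficient units would differ from the planted ones.

What the generator does **not** model: informative missingness, tumour
purity, copy-number segmentation, realistic genomic coordinates,
inter-regulator signalling feedback, or heavy-tailed measurement error.
Passing tests on this cohort demonstrate that the statistics recover what
they are designed to recover under their own assumptions — they do not
certify performance on real consortium-scale tumour data, where prior
incompleteness and structured artefacts dominate.

## Problem sizes and determinism

The bundled end-to-end run uses 300 samples × 1000 genes (50 kinases, 40
TFs, 10 substrates each) across 3 studies — large enough that all planted
signals are comfortably detectable, small enough to iterate quickly.  The
tumour-vs-perturbation comparison uses a second, smaller generated cohort
(a quarter of the samples, offset seed) as the stand-in perturbation
panel.  All randomness flows from a single integer seed through
`numpy.random.default_rng`; outputs are written with a fixed float format,
so identically seeded runs are byte-identical.

## Known limitations

* The NES implementation is a simplified signed enrichment; regulons
  dominated by repressive targets with few measured genes have reduced
  power compared with dedicated two-tailed machinery.
* Quantile normalisation with heavy missingness shifts the reference
  toward well-observed columns.
* The Cox stage fits one model per protein × tissue; no shared frailty or
  multi-protein models.
* `select_regulated_proteins` pools absolute activities across regulators
  by default (per-protein thresholds are a switch); pooling mixes the two
  score kinds if kinase and TF matrices are concatenated upstream, so it
  is applied per score kind in the pipeline.
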