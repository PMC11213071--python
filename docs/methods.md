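# Methods

This note documents the statistical models behind each analysis stage, the
conventions that had to be fixed where the field leaves them open, the
generative model of the synthetic-cohort module, and the limits of what the
test suite can and cannot demonstrate about real data.

## Statistical primitives

All hypothesis tests are two-sided — the package reports both enrichment
and depletion, and two-sided is the conservative convention when
directionality is not pre-registered.

**Fisher's exact test** (`stats.fisher_exact`) returns the two-sided
p-value obtained by summing hypergeometric probabilities of all tables
with the observed margins that are no more probable than the observed
table. The effect is the sample odds ratio `ad/bc`; whenever any cell is
zero, 0.5 is added to every cell (Haldane–Anscombe) so screens with empty
cells still report a finite, plottable effect size.

**Benjamini–Hochberg** (`stats.benjamini_hochberg`) implements the step-up
rule `q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1 and returned in input
order; NaN entries are excluded from the family and propagated. The
significance convention throughout the package is q < 0.1 (10% FDR).

**Rank tests.** Mann–Whitney U uses exact enumeration when
`n_x·n_y ≤ 400` and the pooled sample is tie-free, otherwise the normal
approximation with tie and continuity corrections. The paired Wilcoxon
signed-rank test drops zero differences (the common convention; the
degenerate all-zero case returns p = 1 with a flag), uses exact
enumeration of sign assignments when n ≤ 25 with untied |differences|,
and midranks + normal approximation otherwise. Effect sizes are median
differences: for unpaired comparisons the difference of group medians, for
paired comparisons the median of paired differences (the two conventions
are distinct; outputs record which applies).

**Quantiles and outliers.** All quantiles use linear interpolation
(index = p·(n−1)), fixed once so the extreme-outlier rule is reproducible.
An extreme outlier is a value strictly beyond Q1 − 3·IQR or Q3 + 3·IQR;
"strictly" means a value exactly at a fence is retained. Fewer than 4
finite values yields no exclusions. The mask is invariant under
positive-scale affine transforms.

## Autoantibody pipeline

Reactivities are normalized per sample: score = (MFI − median_s)/MAD_s,
using the **raw** MAD with no 1.4826 consistency constant, so scores are
literally in per-sample MAD units and the per-sample identities
median = 0, MAD = 1 hold exactly. Samples with zero MAD (constant
reactivity) cannot be normalized and are excluded with a record.
Positivity per antigen is a score strictly above the 90th percentile
(linear interpolation) of the euploid control samples; controls are scored
against their own threshold, so ≈10% of controls are positive per antigen
by construction. The over-representation screen excludes antigens with
positive calls in fewer than 18 samples — "detected" is interpreted as
"called positive", the only sample-level detection notion the pipeline
defines; the threshold is a parameter. Phenotype associations require ≥5
cases and are BH-corrected within phenotype across antigens (family choice
recorded in output metadata). QC thresholds for bead counts and missing
fractions are unstandardized in this assay class and are exposed as
parameters (defaults: 20 beads, 50% missing) with an exclusion log.

## Inflammatory markers

Out-of-range wells arrive with a missing concentration and a below/above
flag; they are imputed with the per-plate per-analyte minimum (below) or
maximum (above) of the in-range concentrations, then duplicate wells are
averaged per sample. Analytes with more than 10% of wells out of range are
flagged but retained (removal is a config option). Preprocessing is
idempotent: imputation is keyed on missingness, flags are sticky, and a
collapsed panel passes through unchanged.

Differential abundance fits, per analyte,
`log2(concentration) ~ group + age + sex` with a random intercept for
sample source, estimated by REML (statsmodels MixedLM). The group
coefficient is the log2 fold-change. When only one source level is present
the model collapses to OLS and the fallback is recorded per analyte. The
acceptance contract is coefficient recovery and error calibration, not a
specific estimation algorithm.

Covariate adjustment for visualization and scoring residualizes the
nuisance covariates evaluated at their means (the `removeBatchEffect`
idiom), preserving the intercept and the kept group contrast;
zero-variance covariates are dropped (their centered contribution is
identically zero), and genuinely collinear covariate pairs raise an error.

The cytokine score is the sum of z-scores for TNF-α, IL-6, CRP and IP-10
computed on log2, covariate-adjusted values. The reference is either the
euploid cohort (cohort-context mode) or the pooled provided samples
("self" mode, used for trial across-visit comparisons — pooling over
visits rather than standardizing per visit, recorded in output metadata).
The reference-population mean score is 0 by construction, and scores are
invariant to per-component affine rescaling applied consistently to
samples and reference.

## IFN transcriptome

The ISG set is a pure filter over a differential-expression result table
(supplied as an input contract — DE estimation itself is upstream of this
package): keep candidates with q < 0.1, linear fold-change ≥ 1.5, and not
on chr21. Chromosome-21 ISGs (IFNAR2, MX1, MX2) are excluded because their
elevation in T21 is a copy-number effect rather than a signaling readout.
Order is deterministic (fold-change descending, name tiebreak), and the
gene set is data, never hard-coded.

The IFN score standardizes log2(FPKM + pseudocount) per gene against the
reference population and sums across the set. The pseudocount defaults to
1 for scoring (FPKM-like inputs can contain zeros). The treatment-response
analysis computes, per gene, the mean over participants of paired
log2(visit/baseline) ratios — here the default pseudocount is 0 so a pure
halving yields exactly −1; a pseudocount is available when zeros occur.
Mean aggregation across participants is the default (median available).
Each visit's distribution of gene-level fold-changes is tested against
zero with the one-sample Wilcoxon signed-rank test — the one-sample
analogue of the Mann–Whitney U location test — and BH-corrected across
visits.

## Beta regression on cluster frequencies

Cluster proportions are modelled marginally (no sum-to-one constraint),
one beta regression per cluster: logit mean link,
`logit E[p] = β₀ + β₁·group + β₂·age + β₃·sex`, single constant precision
φ per cluster with a log link. Estimation is maximum likelihood
(statsmodels BetaModel) started from logit-scale OLS coefficients and a
method-of-moments precision, with up to 5 jittered restarts on
non-convergence. Wald p-values per coefficient; exp(β₁) is reported as the
"fold-change" following the field's convention for this analysis, with the
caveat that it is strictly an odds ratio of proportions. Boundary values
(0 or 1) are handled by the standard squeeze transform
`y' = (y(n−1) + 0.5)/n`, toggleable; with the squeeze disabled, boundary
data raise. Extreme outliers are excluded per karyotype and cluster by the
3×IQR rule before fitting; clusters with fewer than 10 usable samples per
group are skipped. BH correction runs across clusters within one analysis
level (clusters defined against different parent gates should be analyzed
as separate families).

## Trial endpoints

Visits are fixed to {B, W2, W8, W16}. Each endpoint is tested by paired
Wilcoxon against baseline at each post-baseline visit, with the median
paired difference as effect size and BH across the three visits within the
endpoint. Cohort-context comparisons require the trial scores and the
cohort scores to share a standardization reference (checked by label).
Titer trajectories flag baselines strictly above the upper limit of normal
(anti-TPO default 60 U/mL, a parameter), per-visit changes,
monotone decreases and ULN crossings. Visit-level exclusion annotations
(immune-trigger excursions, e.g. a vaccination days before a blood draw)
never delete data: analyses are run and reported both including and
excluding flagged visits. All computed q-values are always reported;
masking designated cells (e.g. per an interim-analysis plan) is a
reporting flag, not a computation change.

## Synthetic cohort generator

The generator is the package's test bed, emulating the statistical
structure each analysis assumes with the simplest consistent models:

- **Noise:** Gaussian on the log2 scale for concentrations and expression
  (matching the log2 analysis scale); beta draws for proportions;
  Bernoulli reactivity spikes (2³-fold, on a lognormal background) for
  autoantigen positivity with a baseline rate of 0.1 and odds multipliers
  for enriched antigens in T21.
- **Structure:** per-source batch offsets (SD 0.25 log2 units), small
  random age slopes and sex effects, duplicate wells (two per sample,
  independent noise) to exercise the averaging rule, plates of 40 samples,
  and a configurable fraction of out-of-range wells to exercise
  imputation.
- **Cohort defaults** (300 T21 / 150 D21, ages 0.5–57, three sources)
  follow the shape of a large DS cohort study in which cases outnumber
  controls roughly 2:1; all sizes are parameters.
- **Trial:** 10 participants, visits B/W2/W8/W16, a multiplicative
  treatment effect at treated visits, and immune-trigger excursions that
  reverse the effect with a configurable probability.

Effect sizes have no empirical basis — the real study publishes estimates,
not a generative model — so every default is a configurable stand-in
chosen to be plausible for the modality. The generator deliberately omits
realistic cross-modality covariance (a participant's IFN score and
cytokine score are independent given karyotype), longitudinal
autocorrelation beyond a per-participant baseline, and heavy-tailed
assay artifacts. Passing tests therefore demonstrate that the analysis
machinery is correct and calibrated under its own assumptions, not that
those assumptions hold in any particular real cohort.

## Verification design and problem sizes

Exact components are tested against implementation-independent oracles:
full hypergeometric enumeration for every 2×2 table with margins ≤ 15,
the definitional BH formula on 1,000 random p-vectors, and complete
enumeration of rank-test null distributions for n ≤ 10. Stochastic
components are tested by simulation at fixed seeds: beta-regression
recovery of a 0.8 logit-scale group coefficient (precision 50, n = 300,
20 replicates; MAE ≤ 0.1, decreasing over n ∈ {50, 200, 800}); marker
differential abundance on a 54-analyte panel with 10 analytes elevated by
0.5–1.5 log2 units at n = 200/100 (sensitivity ≥ 0.9, observed FDR ≤ 0.15
at q < 0.1 over 20 replicates) plus a global-null calibration over 60
simulated cohorts (3,240 fits — fits within one cohort share participants
and are correlated, so calibration precision is governed by the number of
cohorts, not fits); the autoantibody screen with one 9×-odds antigen among
100 nulls at n = 300/150 (top-ranked and q < 0.1 in ≥ 90% of 20 seeds);
and trial endpoint recovery under a 30% reduction in 10 participants.
The bundled end-to-end CLI run (`configs/example_cohort.yaml`) is checked
for bit-identical outputs across repeated runs at the same seed.

## Known limitations

- MixedLM Wald p-values use the normal approximation, not
  Satterthwaite-adjusted t-tests; with a handful of source levels the
  group-effect calibration is adequate (measured ≈0.053 at nominal 0.05)
  but precision-variance of the random intercept is not propagated.
- Beta regression implements constant precision only; variable-precision
  models are out of scope.
- The DE result table consumed by ISG selection is an input contract; the
  generator emits one consistent with its injected fold-changes rather
  than estimating DE from simulated counts.
- The exact/asymptotic branch boundaries of the rank tests are
  conventions (products ≤ 400; n ≤ 25); both branches agree to within
  0.02 near the boundaries on tie-free data, which the suite checks.
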