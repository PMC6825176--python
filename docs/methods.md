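# Methods

This note records the statistical models, the generative assumptions of the
synthetic cohort, and the numerical decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The analysis chain

The pipeline mirrors a prospective birth-cohort design: one airway sample
per child in early infancy, clinical follow-up for asthma through age 6,
and a concurrent panel of 20 mucosal immune mediators. The stages are
fixed in order: depth exclusion → relative abundance → prevalence/abundance
filter → log transform → z-scale → (diversity, differential abundance,
sparse-PLS score) → immune profile → mediation.

### Abundance preparation

* Depth exclusion keeps samples with ≥ `min_reads` (default 2000) reads;
  the boundary is inclusive.
* Genus filtering requires prevalence ≥ 10% *and* mean relative abundance
  ≥ 0.01%, both inclusive.
* The log pseudocount is half the smallest nonzero relative abundance,
  computed **globally** over the filtered matrix. A single global value
  keeps the transform monotone across genera; a per-genus variant exists
  behind a flag for sensitivity analyses.
* Natural logarithms throughout. After z-scaling, hazard ratios per SD are
  base-invariant, and Shannon diversity is conventionally reported in nats.
* z-scaling divides by the population SD (divisor *n*). At cohort sizes of
  several hundred the distinction from the sample SD is far below the
  precision of any reported hazard ratio; the divisor is configurable.

### Diversity

* Bootstrap richness draws `depth` reads **with replacement** from the
  multinomial defined by a sample's counts and reports the median number of
  distinct OTUs over 100 resamples; samples shallower than the target depth
  are skipped with a warning.
* Weighted UniFrac defaults to the normalized variant (bounded in [0, 1],
  easing cross-cohort comparison); the raw variant is available. The
  backend is scikit-bio; the test suite verifies it against a naive
  per-branch oracle to 1e-10.
* PERMANOVA uses the Anderson pseudo-F on squared distances with the
  add-one permutation estimator p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is
  never exactly zero. One-sided by construction.
* Wilcoxon rank-sum tests use the exact null distribution when both groups
  have ≤ 25 untied observations, otherwise the normal approximation with
  continuity correction.

### Survival machinery

* Cox models maximize the Efron-tied partial likelihood (lifelines).
  Monotone likelihoods (complete separation) are detected and raised as an
  explicit error rather than returning a diverged estimate.
* Confidence intervals and p-values are Wald-based, symmetric on the
  log-hazard scale.
* Season of birth enters as three dummies against a winter reference.
* Children without asthma are censored administratively at age 6
  (configurable).
* The late-onset phenotype boundary is closed on the late side: diagnosis
  at exactly 3.0 years is late-onset. "Current asthma at 6" overlays the
  three onset phenotypes rather than partitioning them.
* Tertiles are formed by a stable sort, so ties break by sample order and
  group sizes differ by at most one (573 children → 191/191/191).

### The bacterial asthma score

One sparse-PLS component of the log genus matrix against asthma-ever
(binary, centered 0/1 coding). Given z-scaled columns, the weight vector is
the covariance vector soft-thresholded at the (k+1)-th largest absolute
entry and normalized to unit Euclidean norm; k = p applies no shrinkage.
Exact ties at the threshold break toward the lexicographically first genus
name, making selection deterministic.

Model selection is repeated stratified 10-fold cross-validation over the
candidate grid {1, 2, 3, 5, 7, 10, 15, 20, 30, all}; the chosen k maximizes
the median held-out AUC over all folds × repeats, with ties preferring the
sparser model. Stratification matters because events are roughly a quarter
of children; plain folds risk event-free test folds. Centering/scaling
parameters and the threshold come from training folds only — an anti-leakage
property the test suite checks by contrasting with a deliberately leaky
variant on pure noise.

The per-child score averages the held-out component scores across repeats,
is oriented to correlate positively with the outcome, and z-scaled.
Averaging across repeats (rather than using a single partition) reduces the
partition noise of the score; single-partition behavior is available by
setting one repeat. Importance is the median absolute loading across
folds × repeats normalized to sum to 1 over selected genera; absolute values
are used because genera of both effect signs carry positive importance.

With many weakly informative genera the CV criterion is flat in k above the
true support size, so the chosen k often exceeds the number of planted taxa
while still ranking the planted taxa at the top of the importance list; the
acceptance checks therefore score selection recovery (planted taxa inside
the selected set) rather than the chosen k itself.

### Immune profile

* kNN imputation: k = 10, nan-Euclidean distance over mediators observed in
  both samples, unweighted neighbor mean (scikit-learn `KNNImputer`),
  applied to raw log concentrations **before** any normalization.
* Normalization order: per-mediator standardization (division by the
  mediator median — a robust reference scale; skippable), per-sample
  total-sum normalization, log transform, per-mediator z-score.
* Concentration-ratio models regress the post-normalization log
  concentration on the score plus four principal components of the
  "other bacteria" — all retained genera not selected into the score. When
  every genus is selected there are no other bacteria and the adjustment is
  skipped.
* The immune mediator score reuses the sparse-PLS machinery with the
  continuous bacterial score as target and held-out Spearman correlation as
  the CV criterion.

### Mediation

Primary estimator: the difference method on the log-hazard scale,
PM = (ln HR_total − ln HR_direct)/ln HR_total, from Cox fits without and
with the mediator. PM is invariant to affine transforms of the mediator. A
total effect near zero leaves PM undefined and raises an explicit error.

Intervals come from a nonparametric child-level bootstrap (default 1000
resamples, percentile 2.5/97.5) with a two-sided add-one sign p-value —
assumption-light and appropriate when the interval engine of a published
estimate is unspecified. The alternative "simulation" method draws
counterfactual mediator values from the linear exposure→mediator model and
pushes them through the combined Cox model's log hazard; with linear
models it targets the product-of-coefficients decomposition and agrees
with the difference method in the rare-event regime.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
the biology of any real cohort:

* **Counts.** Dirichlet-multinomial: genus base proportions are a sorted
  log-normal (σ = 2.0), giving a few dominant genera over a sparse tail, as
  in infant airway 16S data; the Dirichlet concentration (default 50)
  controls between-child overdispersion. Read depths are uniform on
  `read_depth_range`. Base proportions are assigned in decreasing order of
  taxon index so that planted indices map to genera that survive the
  prevalence filter and planted effects remain identifiable.
* **Outcome.** The per-child log hazard is the sum of planted effects times
  z-scaled log relative abundances plus covariate effects (paternal asthma,
  older siblings, season with winter reference). Event times are
  exponential with rate `baseline × exp(η)` and administrative censoring at
  6 years; the default baseline (0.045/year) yields the ~23% cumulative
  asthma risk typical of high-risk birth cohorts. No competing risks.
* **Mediators.** Log concentrations are `loading × taxa-signal` plus
  equicorrelated Gaussian noise (ρ = 0.3), exponentiated to raw
  concentrations; missingness is MCAR at 1.2%, and ~7% of children are
  flagged excluded (emulating exclusions for excessive nasal secretions).
  The mediators have **no independent causal path to asthma**: they are
  downstream markers of the planted taxa. A correctly working mediation
  stage therefore reports near-zero proportion mediated on these cohorts;
  mediation recovery is tested on dedicated exposure→mediator→outcome
  simulations with explicit path coefficients.
* **Phylogeny.** A random rooted binary tree over OTUs (exponential branch
  lengths), sufficient for exercising weighted UniFrac; it encodes no
  taxonomic signal.
* One NumPy generator per cohort, seeded once; identical (config, seed)
  reproduces every container byte-for-byte.

What passing tests on these cohorts do **not** show: robustness to batch
effects, taxonomic misassignment, longitudinal dynamics, non-multinomial
overdispersion, informative censoring, or non-MCAR missingness — none of
which the generator emulates.

## Problem sizes

Simulation-based checks run at desk scale, chosen to keep the full suite in
minutes while leaving the statistical claims testable: calibration and
recovery use 600 children × 60 genera with 10–20 replicates and 2–3 CV
repeats; the mediation oracle uses a single 50,000-child run against
medians of 1500-child estimates; bootstraps in tests use 200 resamples
(the library default is 1000).

## Known limitations

* The sparse-PLS penalty is a hard top-k via soft-thresholding, the
  standard one-component sPLS variable-selection behavior; an L1-path
  variant is not implemented.
* Only one PLS component; multi-component models are out of scope.
* The mediation machinery handles a single continuous mediator without
  exposure–mediator interaction.
* The difference-method PM assumes a rare-ish outcome for its collapsible
  interpretation of Cox coefficients; at very high event rates the two
  mediation estimators can drift apart.
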