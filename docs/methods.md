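# Methods

## Scope and data model

`ionsig` analyzes log2-normalized bulk expression matrices (genes × samples)
with per-sample clinical tables. Upstream array processing (GCRMA-style
normalization, probe-to-gene collapsing, repository retrieval) is out of
scope: inputs are assumed already normalized and gene-collapsed, and the
package rejects anything that does not declare itself as log2 to avoid
silent double-logging. Two preprocessing filters operate on user-provided
tables: retention of genes detected (present-called) in at least a given
fraction of samples — the threshold is inclusive and defaults to 2/3, and is
applied per cohort — and exclusion of chromosome X/Y genes to avoid gender
confounding. Genes without chromosome annotation are kept with a warning
rather than silently dropped, so annotation gaps stay visible. Survival
times may be recorded in days or months (declared in the clinical file
header) and are normalized to days using the mean Gregorian month
(30.44 days).

## Differential expression

Paired designs (tumor vs matched normal from the same patients) use the
paired t-test on per-pair differences; two-group designs (adenocarcinoma vs
squamous-cell carcinoma) use Welch's unequal-variance t-test — the safer
default when only "two-tailed t-test" is specified, since it does not
assume equal group variances. P-values are adjusted by Benjamini–Hochberg
step-up FDR control within the family of genes actually tested: when the
screen is restricted to a gene panel (e.g. a curated ion-channel list), the
adjustment runs over the panel only, matching a per-analysis adjusted P.
Significance thresholds are strict inequalities (adjusted P < 0.001 for the
normal/tumor screen, < 0.05 for the subtype screen, both configurable).

Fold changes are computed on the linear scale from log2 group means,
`2**(mean_log2(num) - mean_log2(den))`, i.e. ratios of geometric means.
Whether published microarray fold changes are arithmetic- or geometric-mean
ratios is usually unstated; the geometric form is the natural one for data
modeled on the log scale and is what this package implements throughout.
Genes with zero variance (degenerate tests) are skipped with a warning and
excluded from the BH family.

## Sign-weighted risk score

A signature freezes an ordered gene list with the discovery-cohort fold
changes. Each gene's weight is `sgn(log2 fc)`: +1 if up-regulated in the
adverse direction of the discovery contrast, −1 if down-regulated. A fold
change of exactly 1 yields weight 0; the gene is flagged and excluded from
scoring. The packaged 37-gene normal-vs-tumor signature has 10 positive and
27 negative weights; the packaged 30-gene subtype contrast has 21 and 9.

The risk score is the weighted sum of per-gene z-scores,
`s = Σ w_i (e_i − μ_i)/τ_i`, with μ and τ the mean and **sample** (n−1) SD
of the gene across all samples of the cohort being scored. Standardization
statistics are always recomputed inside the scored cohort and never carried
over from the discovery cohort: this is what makes the score well-defined
across platforms with different dynamic ranges. Two consequences follow
directly: the cohort mean score is exactly zero (each standardized gene
sums to zero), and the median is near zero, so the median split produces
two nearly equal halves. Dichotomization is deterministic: positive iff
strictly greater than the cohort median, ties negative.

Signature genes absent from a platform are dropped with a logged count and
**no rescaling** of the remaining sum. A reduced-gene score therefore has a
smaller dynamic range and is comparable only within, not across, cohorts;
the dropped count is carried in the result so cross-platform comparisons
can be flagged.

## Survival analysis

Kaplan–Meier curves, log-rank tests and Cox proportional-hazards models are
fitted with lifelines. Tied event times use the Efron approximation (more
accurate than Breslow and the lifelines default); confidence intervals and
p-values are Wald-based, matching the usual printed (HR, 95% CI, P)
triplets. The Newton stopping tolerance is tightened to 1e−12 so that
coefficients agree with direct partial-likelihood maximization to ~1e−8
even on tiny, flat-likelihood inputs. Stage enters multivariate models as a
single numeric ordinal term (one hazard ratio per unit stage increase)
rather than as dummy-coded levels. Rank-deficient designs are rejected with
the collinear columns named. For the continuous score, the per-point hazard
increase is reported as `exp(β) − 1`.

A dedicated single-covariate Newton solver for the Efron partial likelihood
(`cox_coef_fast`) backs the resampling inner loop, where thousands of
coefficient evaluations per test make the full fitting machinery the
bottleneck; it is damped-Newton from β = 0, converges to |step| < 1e−12,
raises when |β| exceeds 50 (complete separation), and is tested to agree
with lifelines to 1e−6 on tied and untied data.

## Resampling null (non-randomicity)

Random gene signatures are often as prognostic as published ones, so the
signature's association is referenced against its own construction
procedure: B (default 1000) signatures of identical size are sampled
uniformly without replacement from a gene universe (default: all genes with
a discovery fold change, configurable), each weighted by the sign of its
genes' discovery fold changes — the same rule that built the real
signature, so the null preserves the procedure and not just the gene count.
The test statistic Z is the sum over cohorts of the univariate Cox
coefficient for dichotomized status; the empirical p uses the permutation
pseudo-count `(1 + #{Z_null ≥ Z_obs})/(B + 1)`, one-sided in the
poor-survival direction (the weight convention makes larger Z mean stronger
adverse association) and bounded below by 1/(B+1). Sampling is fully
deterministic under the seed. The original description specifies neither
the random-signature weighting nor the universe; both choices here are
configurable and recorded in the result metadata.

## Validation toolbox

Cross-cohort agreement between two DE tables is summarized over their
common genes by the Pearson correlation of log10 **raw** p-values (the
figure convention for such comparisons; the column is configurable), the
correlation of log2 fold changes, and the fraction of genes with matching
fold-change direction. PCA projects samples onto the first two components
of the per-gene centered and unit-variance-scaled expression restricted to
a gene panel; a fixed sign convention (largest-magnitude loading positive)
makes projections reproducible. Hierarchical clustering uses Ward linkage
on Manhattan distances via scipy's Lance–Williams update on the precomputed
distance matrix (the `hclust`-style generalization of Ward's criterion to a
non-Euclidean metric), returning leaf orders for heatmap layout. Stage (or
any categorical) distributions are compared with the classical contingency
chi-square without continuity correction.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
microarray physics. Paired cohorts: per-gene baselines uniform on log2
4–12 (a typical normalized-array range), i.i.d. Gaussian noise with SD 0.5
on the log2 scale, and planted per-gene log2 fold changes with alternating
signs and magnitudes uniform on a configurable range (default 0.5–2.5,
roughly the published discovery range) on the first `n_de` genes; defaults
are 56 pairs and 37 planted effects on a 1000-gene background. Two-subtype
cohorts follow the same scheme with independent groups (default 50 + 28).
Survival: exponential event times (constant baseline hazard, the simplest
model satisfying proportional hazards) with rate
`h0 · exp(β_s · score + Σ β_c x_c)`, default `h0 = 3e−4`/day (~6-year
median survival), uniform censoring on a 10-year window, and clinical
covariates drawn from declared marginals (age ~ N(65, 8), gender and
smoking Bernoulli(0.5), stage uniform on {1,2,3}, Myc-high Bernoulli(0.3),
mutation Bernoulli(0.4)). Every generator draws from its own child stream
of the config seed, so output is reproducible and adding one generator call
never perturbs another's draws.

What the generator does **not** emulate — probe-level effects, background
correction artifacts, batch effects, gene–gene correlation, non-proportional
hazards — bounds what passing tests show: they demonstrate that the
estimators recover what they model under the model's own assumptions, not
that real cohorts satisfy those assumptions.

## Numerical and design choices

- Expression TSV parsing uses numpy's correctly-rounded float parser, so a
  write→read round trip is bit-exact.
- The presence-call threshold comparison allows a 1e−12 float slack so that
  a detected fraction of exactly 2/3 passes an inclusive ≥ 2/3 rule.
- Monte-Carlo problem sizes in the test suite are chosen so estimator
  precision matches the asserted band: e.g. hazard-ratio recovery within
  ±0.2 of a true HR 2 pools the log-HR over five replicates of n = 2000,
  since a single replicate's sampling SE already spans the band.
- The resampling uniformity check averages over independent cohorts:
  conditional on a single cohort's outcome realization, random-signature Z
  values share cohort-level noise and are not centered at zero.
- The exhaustive Ward-bipartition cross-check runs on well-separated
  fixtures, where greedy agglomeration provably attains the global optimum;
  the bipartition cost generalizes Ward's within-cluster sum of squares to
  Manhattan distance.
- Pipeline orchestration (`ionsig run-all`) persists every stage as TSV,
  aborts with the failing stage's name while keeping partial outputs, and
  is a pure function of (inputs, config, seed) — `summary.json` reproduces
  byte-identically under a fixed seed.

## Known limitations

- Exponential event times mean the generator cannot probe robustness to
  non-proportional hazards or time-varying effects.
- Scores over reduced gene sets are not rescaled by gene count; comparing
  score magnitudes across platforms with different coverage is unsupported.
- The smoking-stratified multivariate model's exact covariate set is
  exposed in the pipeline config rather than fixed, since published
  descriptions of such models are frequently ambiguous.
- No moderated-variance (limma-style) tests: with ≥ 50 samples per group in
  the intended designs, per-gene variance estimates are stable enough for
  plain t-tests.
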