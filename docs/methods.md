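# Methods

This note documents the statistical models, the defaults and why they
were chosen, what the synthetic cohort generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Weighted genetic risk score

The score is the weighted count of exposure-increasing alleles,
S_i = Σ_j β_j g_ij, in the exposure's units per allele (mg/dL for the
urate-like default).  It is deliberately not standardized: downstream
log-odds are per unit of genetically proxied exposure, which is the scale
on which association tables are usually printed.

Harmonization rules, applied per variant before scoring:

- exact allele match → keep; effect/other swapped → count 2−d (flip);
- strand difference → resolve by complementing, then as above;
- palindromic pairs (A/T, C/G) → align by allele frequency, but only when
  both sides are more than **0.08** from 0.5 (a common two-sample
  harmonization default); otherwise drop as `palindromic-ambiguous`;
- anything else → drop as `allele-mismatch`, never silently.

Missing dosages are imputed by the expected dosage 2·EAF of the counted
allele, which preserves the score's expectation; the alternative
(excluding the person or variant) changes denominators per phenotype and
complicates the leave-one-out algebra in the sensitivity stage.

Covariate screening tests each candidate against the score — Pearson
correlation for continuous candidates, one-way ANOVA across levels for
categorical ones — and keeps those with p < 0.05.  On the packaged
generator this recovers exactly the two confounded candidates (assessment
center and the first PC-like score).

## Phenome construction

Diagnosis codes are normalized (uppercase, dots stripped) and matched to
phecodes by longest normalized prefix, the standard semantics of the
public phecode maps.  An assigned phecode also assigns all its dotted
ancestors (411.2 → 411), since disease-group rows and their
sub-phenotypes are both reported in this kind of analysis.  Controls for
a phecode are all persons not assigned any phecode inside its exclusion
range, so clinically overlapping states never contaminate control pools;
one shared control pool per phecode, no matching.  Phecodes with fewer
than 20 cases are excluded from testing.  Case status requires a single
episode; requiring repeat codes would trade sensitivity for specificity
and the generator emits one record per prevalent case anyway.

The ICD-10 tree is built over the observed codes plus their ancestors
(chapter → block → 3-character stem → 4-character code, the most specific
level modelled), and a person is a case at a node iff they carry any code
at or below it.

## PheWAS

Each phecode is fit by maximum-likelihood logistic regression
(iteratively reweighted least squares; convergence when the deviance
changes by <1e-8, at most 25 iterations; Wald SEs from the observed
information; two-sided normal p).  The IRLS loop is written directly in
numpy — it is the inner loop of the permutation and replicate studies, and
an independent GLM implementation serves as its oracle in the test suite.
Separation is detected by fitted log-odds at the stability clip (|η| ≥ 29)
or perfect prediction; such fits report `converged=False` with estimates
withheld, and are excluded from the FDR family since they carry no valid
p-value.

Multiple testing uses the Benjamini–Hochberg step-up at q = 0.05, with the
reported significance threshold equal to the largest discovered p.  BH is
chosen over Bonferroni because rollup makes the tests strongly positively
dependent (parent and child phecodes can share identical case sets), a
setting where BH still controls FDR and Bonferroni is needlessly harsh.
The rollup duplication does mean that a single chance null hit usually
appears as a small family of discoveries; the permutation-null calibration
below accounts for this.

ORs and 95% CIs are exp(β) and exp(β ± 1.96·SE), rounded to 2 decimals
only for display; full precision is retained internally (printed tables
rounded from unrounded betas can therefore differ in the last digit from
exp(rounded β), which is expected).

## Tree-structured Bayesian scan

The genetic coefficient lives on a discrete grid containing 0; the root
state is 0 with probability 1−π, otherwise uniform over the nonzero
points; each child copies its parent with probability 1−θ, else redraws
from the root prior.  That redraw choice makes the prior stationary along
every path — with flat likelihoods each node's prior probability of a
nonzero state is exactly π, a property the tests exploit.

Evidence enters only at leaves, as the Gaussian working likelihood
N(b̂ | b, sê²) of each leaf's logistic summary.  Internal nodes' case sets
are unions of their descendants', so attaching likelihoods there would
count the same persons repeatedly; internal nodes are instead inferred
through the Markov prior.  Nodes with fewer than 20 cases (or
non-converged fits) get a flat likelihood.

Marginal posteriors are exact, via upward/downward sum-product passes in
log space with max-subtraction; the implementation is validated to 1e-10
against exhaustive enumeration on random trees.  Defaults: π = 0.001,
θ = 1/3, grid = 0 plus 20 points spanning ±4·(median leaf SE·√n_leaves) —
all configurable, since the underlying model family does not prescribe
them.  The default grid width is set by typical leaf noise, so a very
large effect (the gout-like leaf) can sit at the grid edge: its PP is
unaffected but its MAP estimate saturates; widen the grid when effect
sizes of interest exceed it.

Reported per node: PP = 1 − P(state = 0 | data); the MAP effect size,
defined as the mode of the nonzero-conditional posterior (the zero state's
evidence is already summarized by PP, and this definition keeps the MAP
inside the credible interval by construction); and the central 95% of the
renormalized nonzero mass.  Nodes with PP ≥ 0.95 are reported, in
depth-first tree order.

## Two-sample MR

Per-variant: Wald ratio β_Y/β_X with first-order SE se_Y/|β_X|.
Estimators over the harmonized, exposure-increasing-allele-oriented set:

- **IVW (fixed-effect)**: β = Σ(β_Xβ_Y/se_Y²)/Σ(β_X²/se_Y²),
  SE = (Σβ_X²/se_Y²)^−1/2 — identical to the inverse-variance
  meta-analysis of Wald ratios and to WLS through the origin (both
  identities are tested).  Cochran's Q against the pooled estimate
  supplies the heterogeneity diagnostic.  A multiplicative
  random-effects SE is deliberately not the default: the crude analysis
  is meant to be the simplest estimator, with robustness delegated to
  the selection ladder.
- **MR-Egger**: WLS of β_Y on β_X with free intercept, weights 1/se_Y²;
  the intercept's t-test (estimated dispersion, the usual Egger
  convention) is the directional-pleiotropy test.  Orientation to the
  exposure-increasing allele makes the fit invariant to per-variant sign
  flips.  Identification requires spread in β_X and ≥3 variants.
- **Weighted median**: interpolated weighted empirical CDF of the ratios
  at 0.5, weights 1/se_ratio²; 50% breakdown point.
- **Kernel mode**: Gaussian-kernel density of the ratios (Silverman-style
  bandwidth × a configurable factor, default 1), weights 1/se_ratio².
- Median and mode SEs come from a seeded parametric bootstrap
  (default 1,000 draws) of both effect vectors.

Estimator selection is a deterministic, auditable rule ladder standing in
for trained model-selection machinery: one variant → Wald ratio;
Egger intercept p < 0.05 (directional pleiotropy) → kernel mode;
else Q p < 0.05 (heterogeneity) → weighted median; else IVW.  The
triggering rule is recorded in the output.

## Pleiotropy dissection

A locus is flagged for a category (obesity, BP, lipid, glucose) iff any
trait in the category's group has cross-trait p below α/m (0.05/31 =
1.61×10⁻³); flags may overlap, and a locus with no flags is
exposure-specific.  The cross-trait p-values are an input table — the
classification rule stays pure and offline.  Stratified scores are built
for: all loci, exposure-specific loci, each category, leave-category-out
(a locus is removed if it carries the removed flag, regardless of other
flags), and the renal-handling subset plus its complement (renal
membership is an annotation supplied as a flag list, not computed).
Disjoint subsets satisfy exact score additivity, which the leave-one-out
tests verify to floating tolerance.

## Synthetic biobank generator

What it emulates (the packaged defaults, fixed a priori):

- 31 independent biallelic variants, EAFs spread over 0.12–0.85, two
  large-effect loci (0.373, 0.217 mg/dL per allele, transporter-like) and
  29 small ones; dosages Binomial(2, EAF).
- Exposure = Σβ_j g_j + ε, with ε scaled so the score explains exactly
  the target fraction of variance (default R² = 0.07).
- Four mediator traits; 17 pleiotropic loci with category sizes
  10/10/6/3 (obesity/BP/lipid/glucose, overlapping as those counts
  force), per-allele pleiotropic effect 0.2, unit noise.
- Liability-threshold diseases: liability = w·z(traits) + N(0,1), case
  above the normal quantile of the configured prevalence.  The gout-like
  disease (M10.0, prevalence 0.015 ≈ adult gout prevalence in the UK)
  loads only on the exposure (w = 1.2); cardiometabolic diseases load
  only on mediators (w = 0.2–0.5; hypertension I10 at prevalence 0.15,
  myocardial infarction I21.0, chronic ischemic disease I25.1, heart
  failure I50.1, hypercholesterolemia E78.0, diabetes-like E11.9,
  obesity E66.0); three null diseases (J45.9, K21.9, N39.0) carry no
  genetic signal.  There is deliberately no direct exposure→CVD path, so
  the dissection's ground truth is "pleiotropy, not causality".
- Covariates: assessment center and the first PC-like score are weakly
  confounded with the true score (latent shift 0.05 and correlation 0.03
  respectively — enough for screening to find them at the default cohort
  size); sex, age, BMI and PC2–PC5 are independent noise.
- Two-sample summary statistics: per-variant exposure/outcome estimates
  drawn around their truth with SEs ∝ 1/√(2p(1−p)·n); the outcome truth
  is τ·β_j plus configured mediator loadings, giving clean or
  pleiotropic replication sets on demand.
- Cross-trait p-value tables for the classifier: flagged pairs draw
  log-uniform from 1e-12–1e-4, unflagged pairs uniform on (0.05, 1) —
  nulls kept clear of any sensible threshold so the configured truth
  table is exactly recoverable.

What it does not emulate: linkage disequilibrium (the instrument is
treated as independent loci), relatedness, population structure beyond
linear covariates, age-dependent incidence, repeat episodes,
miscoded/unmapped diagnoses, and winner's-curse in the weights.  Passing
tests therefore demonstrate correctness of the pipeline's logic under its
own assumptions, not robustness to those real-data complications.

Determinism: one global seed fans out to named per-stage substreams
(SeedSequence), so any stage can be rerun in isolation and full pipeline
reruns are byte-identical.

## Problem sizes used by the validation suite

The calibration experiments run at the packaged study conditions:
cohorts of 50,000 individuals for the parameter-recovery, permutation
(500 replicates on one cohort) and dissection (50 replicate cohorts)
studies; 1,000 replicates for the Egger type-I rate (at τ = 0, where the
weighted t-test is exactly calibrated); 200 fuzzed trees (≤6 nodes,
≤7 states) for the enumeration oracle.  Unit tests use smaller cohorts
(hundreds to a few thousand) where only logic, not power, is at stake.

## Known limitations

- The per-replicate "exposure-specific GRS associates only with the
  gout-like family" property holds with probability ≈ 1 − q by
  construction (BH leaves ~5% of replicates with a chance extra family),
  so its replicate-level recovery rate sits near 0.94, not 1.
- Internal tree nodes that merely contain an affected branch inherit
  elevated PP through the Markov prior (a union of case sets genuinely
  associates with the score); interpretation should focus on the most
  specific reported nodes.
- Non-converged logistic fits are reported but carry no p; with very rare
  phenotypes prefer raising `min_cases` over interpreting near-separated
  fits.
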