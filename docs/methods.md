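# Methods

`prsubtype` implements a genetics-first subtyping analysis for a
heterogeneous disease (the motivating case is schizophrenia): patients are
described by a vector of polygenic risk scores (PRSs) — one for the focal
disease and one per comorbid trait that shares genetic liability with it —
and subtypes are defined as clusters of patients in that score space.
Subtypes obtained this way are then validated against clinical endpoints:
pre/post treatment symptom counts, cognitive domain scores and laboratory
panels from a trial cohort.

## Polygenic scoring

For each trait *t* with GWAS summary statistics, the score of individual
*i* is

    PRS_t(i) = sum_j  w_tj * d_ij

over the markers *j* selected for that trait, where `d_ij` is the dosage
(0–2 copies) of the effect allele and `w_tj = ln(OR_tj)` for binary traits
or the regression beta for quantitative traits.  Markers enter a trait's
score only when their association p-value is at or below 0.05 in **both**
the focal disease and the trait (the joint-threshold rule); the focal
disease's own score uses the single-trait p ≤ 0.05 filter.  No LD clumping
is applied: the joint filter is the selection rule, and clumping is left
as an optional pre-filter for callers who need it.

Allele harmonization between summary statistics and genotype coding
resolves each shared variant to one action: `keep` when the coding
matches, `flip_weight` when the alleles are swapped (the scorer counts
the complementary dosage `2 − d`, keeping the published weight, so the
constant offset `2w` is absorbed by standardization), and `drop` for
strand-ambiguous A/T and C/G variants or allele mismatches.  Dropping
palindromic variants is conservative and deterministic; frequency-based
strand resolution is deliberately not attempted.

Missing dosages are imputed at scoring time with the variant's cohort
mean (`mean_impute`, the default) or handled by rescaling the observed
weighted sum by total/observed marker count (`omit_rescale`).

Scores are standardized to z-scores per cohort (sample SD, `ddof=1`)
before any downstream use.  Raw PRSs across traits differ by orders of
magnitude because marker counts and effect scales differ; Euclidean
clustering on raw scores would be dominated by a single trait.  A
zero-variance score column is a hard error naming the trait.

## Trait screening

Each candidate trait's standardized PRS is regressed on case/control
status by logistic regression (maximum likelihood via IRLS, as provided
by statsmodels) separately in each discovery cohort, without covariates
by default (an optional covariate matrix is supported and recorded).  A
trait is retained when its two-sided Wald p-value is ≤ 0.15 in **every**
discovery cohort and the coefficient sign is identical across cohorts.
Ties at exactly 0.15 are retained.  Quasi-complete separation is detected
as a coefficient magnitude above 15 on standardized scores; such fits are
flagged non-converged, their p-value is set to missing, and the trait is
excluded.  A constant predictor returns estimate 0 with p = 1 by
convention.

At large cohort sizes the screen is permissive: a trait with no shared
causal variants still acquires, by chance, a handful of jointly
significant markers that genuinely carry focal-disease signal, so its
score picks up a small but real case/control difference whose sign is
shared across cohorts (both cohorts use the same weights).  This
contamination is a property of joint-threshold scores, not an artifact of
the simulation; the screen is therefore evaluated on recovering the truly
comorbid traits, not on rejecting every null trait.

## Subtype clustering

Cases (patients only) are re-standardized within the case set and
clustered on Euclidean distances with Ward linkage by default (average
and complete linkage are available and recorded).  The number of clusters
is chosen by majority rule over a fixed, versioned panel of sixteen
cluster-validity indices (Calinski–Harabasz, silhouette, C-index, Dunn,
Davies–Bouldin, Hartigan, Ball, Krzanowski–Lai, McClain–Rao,
point-biserial, Ratkowsky–Lance, TraceW, TrCovW, Rubin, Duda–Hart and
pseudo-t²); each index nominates one best k by its published optimality
rule (value maxima/minima, first or second differences across hierarchy
levels, or the Duda–Hart critical-value test at z = 1.645).  The exact
definitions and rules are documented in `prsubtype/indices.py`; every
index is verified against a from-definition reimplementation in the test
suite, with scikit-learn as an additional cross-check where it implements
the same statistic.  An index abstains wherever its value is undefined
(degenerate cuts); abstentions are recorded.  Ties in the vote break to
the smallest k (parsimony).  The cut at the chosen k is labeled by
decreasing class size with Roman numerals; the largest class (Class I) is
the reference in all regressions.

Two cohorts' votes are compared by chosen-k agreement and per-index
agreement.  A dendrogram-guided sub-split of one class
(`refine_split`) re-cuts the subtree spanning that class into a requested
number of groups, leaving other classes untouched; it is an explicit,
logged analyst action, mirroring the situation where a trial cohort's
dendrogram shows one discovery-level cluster dividing further, and never
an automatic heuristic.

## Outcome association

Treatment outcomes are tested per outcome and class with paired Student
t-tests on complete pairs.  Sign conventions follow the reporting
tradition of trial tables: symptom counts are reported as `pre − post`
(positive difference = reduction = improvement), cognitive and laboratory
measures as `post − pre`.  Every reported row carries n, mean difference,
SE, t, df = n − 1, the 95% CI (`mean ± t_{0.975,df}·SE`) and the
two-sided p.  Zero-variance differences with nonzero mean are flagged and
reported with infinite t and p = 0.  Raw p-values are never adjusted in
place; Bonferroni correction appears only as flags, with the family size
recorded per outcome family (3 symptom categories, 4 cognitive domains,
5 laboratory panels).

Baseline features are modeled as `outcome ~ class dummies + sex + age +
assigned drug` by OLS (or logistic regression for binary outcomes) with
Class I omitted as the reference; per-dummy Wald p-values are reported.
Classes with fewer than two modeled samples are flagged unstable; exactly
collinear design columns are a hard error naming the columns.

## Synthetic cohorts

The generator produces the full data layout the pipeline consumes — two
case/control discovery cohorts (defaults 2,681/2,653 and 2,895/2,895) and
one all-case trial cohort (435), M = 5,000 variants, 25 candidate traits
of which 10 genuinely comorbid, 4 latent subtypes — plus a truth bundle
recording every planted quantity.

**Genetic model.**  Allele frequencies are Uniform(0.05, 0.95); each trait
has additive effects (SD 0.12) on a 40-variant causal block, with
comorbid-trait blocks lying inside the focal-disease block so that shared
variants carry effects for both (this is what makes the joint p ≤ 0.05
filter find them).  Seven comorbid traits correlate positively with the
disease, three negatively.  Liability is additive genotype burden plus
Gaussian noise and case status means liability above the threshold set by
a 1% prevalence.  Rather than simulating and thresholding a population
pool (which would need ~10⁵–10⁶ individuals per cohort at realistic
prevalences), case genotypes are drawn from the *exponentially tilted*
genotype law — the asymptotic conditional distribution of genotypes given
liability above the threshold: each causal variant's allele frequency is
shifted on the logit scale in proportion to its effect.  The focal tilt
magnitude is the inverse Mills ratio of the prevalence; each case
additionally receives a subtype-specific tilt on the blocks of its
subtype's traits.

**Subtype separability.**  The subtype tilt magnitude
(`subtype_separation`, default 6.0) is expressed in SD units of the true
trait burden.  PRS estimation — noisy weights on the jointly selected
marker subset — attenuates it by roughly 15%, so the default realizes a
minimum pairwise centroid separation of about 5–6× the within-subtype SD
in observed score space, the separability regime in which hierarchical
clustering reliably recovers planted structure.  The recorded subtype
label is the argmax over subtypes of the case's realized shared genetic
contribution, making the planted classes exactly the structure PRS
clustering can recover.

**Summary statistics** come from an independent reference GWAS per trait,
simulated at the sufficient-statistic level: `beta_hat ~ N(beta, se²)`
with the standard per-variant score-test SE `1/sqrt(2f(1−f)·n_eff)`
(n_eff = 20,000 for quantitative traits, its balanced case/control
equivalent n/4 on the log-odds information scale for binary ones).  Null
variants therefore have exactly Uniform(0,1) p-values, reference and
study cohorts share no individuals by construction, and 5% of rows are
reported on the opposite allele (2% of variants are strand-ambiguous) to
exercise harmonization.

**Outcomes.**  Twelve outcomes with class-specific treatment effects
emulate an antipsychotic-trial panel: a treatment-responsive class (total
symptom reduction 5.47 counts, positive 1.26, negative 1.36; improvement
in all four cognitive domains; HDL −2.25 mg/dL), a partial responder
(total/positive symptoms, processing speed, lower baseline symptoms), a
treatment-resistant class with a metabolic signature (phosphorus
+0.19 mg/dL, HDL +2.22, calcium +0.14), and a negative-symptom responder
with an inflammation signature (lymphocytes −3.12%, neutrophils +3.04%).
Change SDs are on the scale of published trial tables (total symptom
change SD 18, cognitive z-score change SD 0.55), so per-class t statistics
land in the realistic 2–4 range at trial-size classes.  Cognitive
follow-up is observed for 52% of patients and laboratory follow-up for
96%, reproducing the df spread such tables show.

**What the generator does not emulate:** linkage disequilibrium and
clumping, population stratification and ancestry PCs, imputation
uncertainty (INFO filtering happens upstream of this package),
genotyping batch effects, informative dropout (follow-up is missing
completely at random) and treatment-arm differences.  Passing the
recovery suite therefore demonstrates that the pipeline's statistics and
bookkeeping are correct and that the method recovers separable planted
structure; it does not certify performance on real cohorts, where
separability is unknown and confounding is present.

## Numerical and design choices

- Natural logarithm for OR weights; sum-of-(weight × dosage) scoring
  rather than PLINK's per-allele average (equivalent up to the scale
  removed by standardization).
- z-scores use the sample SD (ddof = 1); standardization is idempotent to
  1e-12 and verified to 1e-8 in tests.
- scipy's nearest-neighbor-chain agglomeration is deterministic; merge
  ties resolve by cluster index.  Identical inputs give identical votes,
  labels and report bytes.
- Majority-vote ties break to the smallest k.  Class labels order by
  decreasing size, ties by first appearance.
- Degenerate inputs have defined behavior throughout: empty marker sets
  warn and score zero, constant predictors return estimate 0/p 1,
  zero-variance paired differences flag an infinite-t result, indices
  abstain rather than vote on undefined values.
- All randomness flows from one top-level seed through named
  `SeedSequence` streams per component, so every artifact is reproducible
  byte-for-byte from (config, seed).

## Problem sizes used by the test and acceptance suites

Unit and property tests run on deliberately small instances (tens of
samples, hundreds of variants).  The end-to-end recovery suite runs the
full pipeline on runtime-scaled cohorts — discovery cohorts at one
quarter of the default case/control counts (~670/663 and ~723/723), the
trial cohort at its full 435 cases, and M = 2,000 variants — over 50
seeds in the acceptance script and 12 seeds in the test suite; one run at
the full default sizes (M = 5,000, ~11,600 genotyped individuals) is also
exercised per acceptance run.  These sizes are the package's chosen
desk-scale defaults for its validation experiments; every structural
parameter (trait counts, prevalence, separability, effect sizes) is
identical to the full-scale configuration.

## Known limitations

- The screen's false-positive behavior at large n (shared-marker
  contamination) means selected-trait counts are not comparable across
  cohort sizes; only recovery of truly comorbid traits is guaranteed.
- The Duda–Hart/pseudo-t² critical-value rules assume roughly spherical
  Gaussian clusters; on elongated clusters they abstain or vote low.
- `refine_split` requires the analyst to name the class and sub-k; the
  package deliberately provides no automatic rule for when a class
  "looks divisible".
- Binary-trait reference GWAS are approximated on the log-odds
  information scale with a balanced design; unbalanced reference designs
  would need a different n_eff.
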