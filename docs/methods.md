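# Methods

## The statistical problem

In a carrier-ascertained FMF referral cohort, every subject carries at least
one *MEFV* founder variant, and ancestry is mixed: the four grandparents may
come from up to four countries. The quantity of interest is the association
between each country of origin and each common variant. Because origins are
fractional, per-country contingency tables are ill-defined; instead, the
pipeline asks how well origin *predicts* the variant, and reads the fitted
model's coefficients as association strengths.

## Origin-score encoding

Ancestry is a vector of grandparent fractions: entry *x_c* is the number of
grandparents from country *c* divided by 4, so entries lie in
{0, 0.25, 0.5, 0.75, 1} (exact in binary floating point — equality
comparisons are safe) and each row sums to 1.

Missing-data rules:

* If a parental side has exactly one known grandparent, the unknown one is
  assumed to share its country (endogamy within a side is the norm in this
  population). Known slots are never altered, and supplying more
  information can never make an eligible subject ineligible.
* If a side has no known grandparent, half the pedigree is unknown and the
  subject is excluded from origin analysis (but kept in genotype
  summaries). Ineligibility is a returned value, not an exception.

Countries supported by fewer than `min_referrals` referrals (default 15,
counting any positive fraction, not weighted mass) are dropped from the
feature matrix. Rows are **not** renormalized after column dropping: a
retained entry must keep meaning "this fraction of grandparents", both for
coefficient interpretation and for the dose analysis. The threshold is
applied to the full eligible cohort before the modeling subset is taken;
both orders are possible in principle and the choice is configurable by
calling `filter_countries` on whichever matrix is wanted.

## Genotype classes and the modeling subset

Allele pairs are stored unordered and canonicalized. Classes: negative
(WT/WT), heterozygous, homozygous, compound heterozygous (two distinct
variants; V726A + E148Q is labelled *apparent* compound heterozygous since
phase is unverified, and is treated as compound for all filters). The
modeling subset keeps single-variant-type carriers (HTZ or HMZ) of M694V,
V726A or E148Q only: compound heterozygotes are too heterogeneous to label
cleanly and the two rare variants (M680I, M694I) have too few carriers.
Records with missing sex are kept in summaries (an extra column) but leave
the modeling subset, since sex is a model feature.

## Logistic model

One binary model per target: carriage of a variant, or homozygosity for it
(the homozygosity model is fitted on the whole modeling subset with
HMZ-for-the-variant as the positive class; restricting the comparison set
to carriers of that variant is possible by filtering the cohort first).
Features: retained country fractions + sex (female = 1). Fitting is
Newton/IRLS with step halving on the penalized Bernoulli log-likelihood,
written in-package (the estimator is the point of the package, not a
wrapper). Numerical choices:

* gradient max-norm tolerance 1e-8, `max_iter` 100;
* ridge penalty λ = 1.0 by default on unstandardized features, never on
  the intercept. λ = 1 mirrors the long-standing default strength of
  mainstream logistic-regression software and keeps near-separated country
  indicators finite; `penalty="none"` gives the MLE;
* features are deliberately not standardized (fractions are already on
  [0, 1], sex is binary), so the penalty acts on the natural per-unit-
  ancestry scale — documented because penalty and scale interact;
* constant columns are fitted, not dropped, with a warning (under ridge
  they shrink to ~0; without a penalty they are unidentifiable);
* perfect separation under `penalty="none"` is detected via saturated
  fitted probabilities and flagged `converged=False` with a warning,
  because the gradient can numerically vanish at a divergent optimum;
* step halving guarantees the penalized log-likelihood never decreases,
  so the fit is deterministic and order-invariant.

Coefficient magnitudes depend on the penalty configuration; only signs and
rankings are comparable across software, which is all the downstream
analysis uses.

## Evaluation, ranking, groups

AUC is the tie-adjusted Mann–Whitney statistic (midranks); the ROC curve
sweeps distinct score thresholds and its trapezoidal area equals the AUC
exactly, ties contributing diagonal segments.

Resampling schemes:

* **tenfold cross-validation** — unstratified random folds (sizes differing
  by at most one), matching the plain "random 90/10" design; a stratified
  option exists behind a flag;
* **out-of-bag bootstrap** — B replicates (default 1000) of n draws with
  replacement, tested on the left-out rows (mean out-of-bag size
  n(1−1/n)ⁿ ≈ 0.368 n).

Resamples whose training or test part is single-class, or whose test part
is empty, are skipped and counted — with many bootstrap replicates on small
data some out-of-bag sets are degenerate, and aborting would bias the
remainder. Coefficient vectors of successful fits are averaged; countries
(never sex or the intercept) are ranked by mean coefficient, ties broken
lexicographically so rankings are deterministic. The k-fold ranking is the
default report; the bootstrap ranking is computed the same way and, on
strong signal, the two agree on the top-4 set (checked in the acceptance
suite). The pooled ROC concatenates held-out scores across resamples.

Group analysis takes the 4 highest- and 4 lowest-ranked countries, computes
each referral's grandparent dose for a group from the **unfiltered** origin
matrix (dose is a pedigree property; dropped columns must not deflate it),
and tabulates carriers/non-carriers by exact dose level. Empty dose bins
are reported with zero counts and undefined (NaN) prevalence. By default
dose tables cover all eligible genotype-positive referrals; a flag restricts
them to the modeling subset.

## Synthetic cohorts

The generator emulates the study's data-generating structure, not FMF
genetics: no drift, linkage or penetrance. Per subject:

1. grandparent origins: with probability `endogamy` (default 0.5) all four
   share one weighted-sampled country; otherwise each side shares a country
   with probability `side_coherence` (default 0.8), else two independent
   draws — qualitatively matching a population where single-origin families
   are common but admixture is substantial;
2. genotype: each parental allele is drawn from the equal mixture of that
   side's two grandparent frequency vectors, alleles independent. This is a
   modeling simplification — parental genotypes are never instantiated —
   but it is equivalent in expectation for the allele-frequency signal the
   inference uses;
3. ascertainment: variant-negative subjects are discarded (the retained
   count is random; `simulate_retained` resamples to a fixed count);
4. missingness: after ascertainment, each grandparent slot is blanked
   independently (default 0.1). Subjects who thereby lose a side stay in
   the cohort and are excluded later by the encoder, as in the real flow.

Presets (26 countries, equal sampling weights, female fraction 0.52):

* `null_config` — identical frequencies everywhere (M694V 0.06, V726A 0.03,
  E148Q 0.05, M680I 0.004, M694I 0.002): any downstream signal is noise.
* `paper_like_config` — three disjoint planted clusters over low shared
  backgrounds: M694V at allele frequency 0.25 in four North-African-like
  countries (founder carrier rates approaching 1 in 4 are documented for
  such populations), V726A at 0.10 in four European-like countries, E148Q
  at 0.12 in four West-Asian-like countries. These frequencies are invented
  qualitative stand-ins — the real cohort's composition is unpublished —
  chosen to represent a strong founder effect.

`planted_countries` recovers the ground-truth cluster from a config
(frequency > 2× the across-country median), so recovery tests never
hard-code the planted sets.

What passing tests show — and what they do not: the null and recovery
checks demonstrate that the pipeline is calibrated (no spurious
associations from ascertainment, admixture or missingness at these levels)
and that it recovers strong planted founder signals at realistic cohort
size (n ≈ 1800, as in the study). They do not validate the presets'
frequencies against any real population, and real cohorts add features the
generator omits: uneven country weights, correlated missingness,
genotype-dependent referral bias, family clustering.

## Problem sizes and determinism

The test and acceptance runs use n = 500 (null calibration, 10 seeds),
n = 1800 (recovery, 10 seeds, B reduced to 200 for the bootstrap arm), and
20 000 pre-ascertainment draws for the simulator analytics — sizes at which
the binomial/Monte-Carlo tolerances used (3 SE bands, AUC ∈ [0.40, 0.60]
under the null, ≥ 9/10 seed recovery) are meaningful. Every stochastic
component takes an explicit seed; identical seeds reproduce cohorts,
resampling splits and output bundles byte for byte.

## Known limitations

* The origin encoding weights all grandparents equally and cannot express
  great-grandparent or unequal-weight pedigrees.
* The per-variant models are binary, fitted independently; no multinomial
  model and no feature selection.
* Dose-response tables are reported as counts; no plotting layer is
  included, and no confidence intervals beyond resample dispersion.
* Published real-cohort performance cannot be reproduced here: the patient
  data are not deposited. The packaged fixture carries the published
  genotype-by-sex table only, which supports prevalence statistics but not
  origin analysis.
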