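# Methods

This note documents the models, parameters and numerical choices behind
`mtphen`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one defensible option existed.

## Ontology and information content

Phenotypes are sets of terms from an `is_a`-structured DAG (HPO-like).
Only `is_a` edges are used; other relation types carry no similarity
semantics in this setting.  Alternative ids are resolved silently and
obsolete terms are dropped from inputs with a warning rather than erroring,
because real ontology releases retire and merge ids between versions.

Information content is estimated two ways:

* **Corpus IC (default).**  Each reference case's terms are propagated to
  all ancestors; `p(t) = n(t)/N` over the `N` cases and `IC(t) = −ln p(t)`.
  Terms never observed in the corpus receive the smoothed probability
  `1/(N+1)`, so queries carrying reference-absent terms keep finite IC.
  The smoothing preserves edge-monotonicity (`IC(parent) ≤ IC(child)`),
  but note its side effect: two *distinct* unobserved terms share the
  maximal IC value, so unobserved sibling leaves can attain Lin similarity
  1.0 through an unobserved shared parent.  With a reasonably sized
  ontology relative to the corpus this is rare; it is the main reason the
  default synthetic ontology is built with a large leaf pool (see below).
* **Structural IC (fallback).**  Without a corpus,
  `IC(t) = −ln(|reflexive descendants of t| / |terms|)`.

IC is in nats by default; the log base is configurable (`log_base=2` gives
bits).  Both estimators are exposed because published workflows differ in
which they use and the choice shifts the absolute similarity scale; all
thresholds in this package were calibrated under corpus IC.

## Similarity score

Term similarity is Lin's measure, `2·IC(MICA)/(IC(t1)+IC(t2))`, with the
MICA found over the intersection of reflexive ancestor sets; Resnik
(`IC(MICA)`) is available for sensitivity analysis.  When both terms have
zero IC the similarity is defined as 1 for identical terms and 0 otherwise.

Set similarity is the **symmetric best-match-average**: average each term's
best cross-set match in both directions and average the two directional
means.  An asymmetric variant (query→reference direction only) sits behind
a config flag.  Query term sets are used as given — no ancestor expansion
before matching — because the MICA search already accounts for shared
ancestry.

The **mean phenotype similarity score** of a patient is

* *gene-matched mode*: the mean set similarity to **all** reference cases of
  the candidate gene, or
* *top-k fallback* (k = 5 by default): the mean over the k most similar
  reference cases across the whole database, used when no candidate gene is
  present in the reference.  Ties at the k-th value are resolved by case id
  so the score is deterministic.

A query that is itself a reference case is excluded from its own pool
(leave-one-out); without this, within-reference score distributions are
inflated by the guaranteed self-match.  If leave-one-out removes the gene's
only case, the score falls back to top-k mode rather than erroring — a
one-case gene simply has no within-gene cohort to compare against.

`SimilarityEngine` precomputes the full term-by-term similarity matrix for
a given term universe so cohort-scale scoring is vectorised; it produces
values identical to the scalar functions (asserted in tests) and costs
O(T²) memory, so callers pass the union of terms actually in play rather
than a full 17k-term ontology.

## Candidate filtering

The cascade retains affected, unsolved individuals with either a qualifying
homozygous variant or ≥ 2 qualifying heterozygous variants in one gene:
gnomAD AF < 0.01 (strict), gnomAD homozygote count exactly 0, internal
cohort AF < 0.02 (strict), HIGH or MODERATE impact, passing QC, gene not in
the excluded bifunctional set (KARS, GARS).  ClinVar Benign/Likely-Benign
annotations exclude variants on the heterozygous branch only (a config
switch extends this to homozygotes).  Absent gnomAD annotations count as
"not observed" (0) by default — the standard rare-disease convention — with
a stricter "exclude if missing" mode available.

Heterozygous pairs closer than 150 bp (a typical short read) are flagged
`needs_phase_review` but never auto-excluded: true phase can only be
resolved by alignment inspection, which is outside this package.  Finally,
individuals without phenotype terms and genotypes with inconsistent
segregation are removed; unknown segregation is retained.

Every non-survivor carries ledger rows with one reason each, ordered by a
fixed rule precedence, and the ledger partitions the cohort: at every stage
`inputs = survivors + exclusions`.  The cascade is idempotent on its own
output and monotone under threshold tightening (both property-tested).

## ACMG combining and PP4

Evidence codes are combined with the Richards-style table (operationalised
in `acmg.combine_evidence`; the docstring spells out every pattern).
Strength modulation is supported — in particular PP4 at moderate — and
benign evidence at the table-less "moderate" level is counted as
supporting.  Meeting classifying patterns on both sides yields VUS
(conflict), as does insufficient evidence.

PP4 is assigned from the similarity score as a step function: ≥ 0.4 →
moderate, ≥ 0.3 → supporting, below → none; no PP4 without phenotype terms,
and PP4 is capped at moderate.  PP4 may coexist with BP4: phenotype
specificity and computational impact predictions measure different things.
Revision appends PP4 to each allele's evidence list once (both alleles of a
genotype receive the same PP4) and re-combines; the revised class never
drops below the initial one, which also lets a curated initial
classification act as a floor when its evidence is not fully itemised.

Case status per genotype: both alleles LP/P → likely diagnosis; exactly one
LP/P with the other at least VUS → candidate for further investigation; all
VUS → VUS finding; anything below VUS → not prioritised.  An individual
with several candidate genotypes receives their most advanced status.

## Classifier validation

The modelling dataset labels reference cases (scored leave-one-out,
gene-matched) and any diagnosed individuals whose causal gene is in the
reference as positive; all other diagnosed individuals (scored top-5
fallback) as negative.  Balancing subsamples the larger class to the
smaller without replacement (seeded).  The 80/20 split is stratified with
per-class rounding to the nearest integer.

Two models are fitted, statsmodels-style (`DiagnosticModel.fit()` returns a
`DiagnosticResults` with `summary()`, `evaluate()`, `roc()`, `youden()`):

* **Logistic (GLM)** on the similarity score alone, by unpenalised maximum
  likelihood (statsmodels `Logit`).  Under complete separation the MLE
  diverges; a guard falls back to a weakly penalised fit (ridge-like,
  C = 10⁴) with a warning and `separation_guard=True`, leaving standard
  errors unreported.
* **Random forest** on similarity + term count + average IC, 500 trees,
  seeded; variable importance is mean decrease in impurity and only the
  *ranking* is treated as meaningful (importance scales are
  implementation-specific).

Cross-validation is seeded stratified 5-fold, used purely as a performance
summary (no tuning; fold models for the GLM use the same weakly penalised
approximation for speed and robustness).

ROC points are evaluated at midpoints between consecutive distinct scores
plus ±∞ endpoints, predicting positive at `score ≥ threshold`.  AUC is the
normalised Mann-Whitney statistic with half-credit for ties; its 95% CI is
`AUC ± 1.96·√var` with the DeLong placement-value variance (sample
covariances, ddof = 1), clipped to [0, 1].  Constant scores yield AUC 0.5
with a degeneracy warning.  The implementation was checked once against an
independent reference implementation of the DeLong interval and the
expected values frozen into the test suite (the 1.96 convention differs
from the Gaussian-quantile convention by < 5 × 10⁻⁵ here).

The Youden-optimal threshold maximises `J = sens + spec − 1` over the
cutpoints, ties broken toward the lowest threshold.  Mapping the
model-space threshold back to the similarity scale is model-dependent:

* logistic: closed form, `sim* = (logit(p*) − β₀)/β₁` for positive slope;
* random forest (scores not monotone in similarity): quantile matching —
  the similarity value whose exceedance fraction in the evaluation set
  equals the fraction of model scores at or above the threshold.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis relies on:

* a single-rooted layered DAG (default 5 top branches × 4 levels ×
  branching 4 → 425 terms, 320 leaves) with a seeded 10% fraction of
  diamond cross-edges.  The leaf pool is deliberately large relative to the
  term profiles so that unobserved-term collisions (see the IC smoothing
  note) stay rare, as they are in a full-size ontology;
* a reference cohort of ten genes with the per-gene case counts of the
  curated published cohort (total 234).  Each gene has a fixed 8-leaf term
  profile (profiles disjoint across genes); a case expresses each profile
  term with probability `p_express` (default 0.8) plus Poisson(1) noise
  terms, truncated to 1–13 terms.  High `p_express` produces tight
  DARS2-like clusters, low values heterogeneous IARS2-like ones;
* labelled query cohorts (default 200 + 200).  Every individual draws an
  assigned reference-gene profile and an assigned background-disease
  profile and mixes them: each term comes from the gene profile with
  probability θ and from the background profile otherwise
  (θ_pos = 0.9, θ_neg = 0.1 by default).  Positives record their gene as
  causal; negatives do not.  Because both classes share one generating
  mechanism, θ_pos = θ_neg makes them exchangeable by construction — the
  null design.  Term counts are `1 + Poisson(3)` clipped to 1–13, matching
  the observed range (1–13), mean (~4) and median (3) of structured
  phenotype data in the platform cohort;
* variant fixtures whose deterministic core exercises every filter rule
  exactly once (including the boundary values 0.01/0.02 and homozygote
  count 1) plus seeded random individuals; ground truth is computed at
  generation time with an independent restatement of the rules.

One global seed fans out into fixed per-component substreams, so adding a
generator does not perturb the others and every artefact is bit-reproducible
given `(seed, spec)`.

**Operating characteristic worth knowing:** the scoring mode follows the
candidate gene — positives are scored gene-matched (a mean over the gene's
cases) while gene-less individuals get the top-5 fallback (a best-case
mean).  The fallback is upward-biased relative to the gene-matched mean, so
even exchangeable phenotype classes separate slightly once scored
mode-asymmetrically.  Null checks in the test suite therefore score
label-blind (everyone through the fallback).  In real use the asymmetry is
conservative: it inflates the scores of the *negative* class.

What the generator does **not** emulate: real HPO depth and annotation
density; term co-occurrence structure within organ systems; realistic
HGVS/genome coordinates or mutation-rate models; inter-curator variability
in phenotype coding; missingness patterns of clinical records.  Passing
tests therefore demonstrate correctness of the machinery and recovery of
known generative structure, not clinical performance on real cohorts.

## Problem sizes

Default sizes (234 reference cases, 200+200 queries, ~38-individual variant
cohort) keep a full pipeline run below ten seconds and the complete test
suite below a minute on one CPU, while matching the published cohort's
reference size exactly and its modelling design in miniature.

## Known limitations

* PP4 calibration thresholds (0.3/0.4) are taken as given, not re-derived
  per cohort; the Youden analysis reports where they fall on synthetic data
  but does not update them.
* The ACMG combiner covers the classifying patterns; it does not implement
  point-based scoring variants or per-code applicability rules (evidence
  other than PP4 is an input, not derived from annotations).
* The similarity score has no p-value calibration; it is validated
  empirically through the classifier analysis instead.
* HGVS strings are compared as opaque identifiers; no normalisation.
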