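# mtphen

Phenotype-similarity driven interpretation of rare recessive variants in
mitochondrial aminoacyl-tRNA synthetase (mt-aaRS) genes.

## The problem

Mt-aaRS deficiencies are rare recessive mitochondrial diseases with highly
heterogeneous, mostly neurological presentations, which makes variant
interpretation from sequencing data alone unreliable: most candidate
genotypes end up as variants of uncertain significance (VUS).  When
individual-level phenotype data for published cases are curated as HPO
terms, the *quantified* similarity between an undiagnosed patient and the
published cases of a candidate gene becomes usable evidence.  `mtphen`
implements that workflow end to end for anyone analysing a rare-disease
cohort with structured HPO phenotypes and annotated variant tables:

1. **Candidate selection** — homozygous and presumed compound-heterozygous
   genotypes filtered on gnomAD allele frequency (< 0.01), gnomAD homozygote
   count (= 0), internal cohort frequency (< 0.02), HIGH/MODERATE impact,
   ClinVar B/LB exclusion (het branch), QC flags, with cis-artefact flagging
   and an exclusion ledger that always conserves the cohort.
2. **Phenotype similarity** — per-term information content
   IC(t) = −ln p(t) from the curated reference corpus (ancestor-propagated
   counts), Lin term similarity 2·IC(MICA)/(IC(t₁)+IC(t₂)), symmetric
   best-match-average over term sets, and the **mean phenotype similarity
   score**: the mean similarity to all reference cases of the candidate gene
   (or to the five most similar cases when no gene matches).
3. **Calibrated PP4** — score ≥ 0.4 → PP4 moderate, ≥ 0.3 → PP4 supporting,
   fed into a Richards-style ACMG evidence combiner to revise per-allele
   classifications and derive a per-individual case status
   (likely diagnosis / candidate / VUS finding / not prioritised).
4. **Validation** — logistic (similarity only) and 500-tree random-forest
   (similarity + HPO count + average IC) classifiers with stratified 80/20
   splits, optional class balancing, 5-fold cross-validation, confusion
   metrics, DeLong AUC confidence intervals and Youden-optimal thresholds
   mapped back to the similarity scale.

A seeded synthetic-data module generates HPO-like ontologies, clustered
per-gene reference cohorts (234 cases over ten genes by default), labelled
query cohorts with tunable profile overlap, and variant tables with known
filter outcomes, so the whole pipeline is testable offline.

## Worked example

```python
import pandas as pd
from mtphen import (GeneratorSpec, generate_toy_ontology, generate_reference_cohort,
                    generate_query_cohorts, AnnotationCorpus, information_content,
                    SimilarityEngine, average_ic, build_modelling_dataset,
                    DiagnosticModel, pp4_from_score)

spec = GeneratorSpec(seed=7, n_positive=60, n_negative=60)
graph = generate_toy_ontology(spec)
reference, profiles = generate_reference_cohort(spec, graph)
corpus = AnnotationCorpus({c.case_id: c.terms for c in reference.cases}, graph)
ic = information_content(graph, corpus)
engine = SimilarityEngine(graph, ic)

case = reference.cases[0]
score = engine.mean_phenotype_similarity(case.terms, case.gene, reference,
                                         exclude_case_id=case.case_id)
print(case.case_id, case.gene, round(score.value, 3), score.mode)
print(pp4_from_score(score.value))
```

prints

```
REF0001 AARS2 0.693 gene_matched
Evidence(code='PP4', strength=<Strength.MODERATE: 'moderate'>)
```

i.e. this published AARS2 case scores 0.693 against the other 43 AARS2
cases (leave-one-out), comfortably above the 0.4 threshold for
moderate-strength PP4 evidence.  Fitting the similarity-only logistic model
on the scored cohorts:

```python
cohort = generate_query_cohorts(spec, graph, profiles)
rows = {"positive": [], "negative": []}
for row in cohort.to_dict(orient="records"):
    gene = row["causal_gene"] or None
    s = engine.mean_phenotype_similarity(row["hpo_terms"], gene, reference)
    rows[row["label"]].append({"individual_id": row["individual_id"],
                               "mean_similarity": s.value,
                               "term_count": len(row["hpo_terms"]),
                               "average_ic": average_ic(row["hpo_terms"], ic)})
train, test = build_modelling_dataset(pd.DataFrame(rows["positive"]),
                                      pd.DataFrame(rows["negative"]),
                                      balance=True, seed=7)
results = DiagnosticModel(train, kind="logistic", seed=7).fit()
print(results.summary())
roc = results.roc(test)
print(f"test AUC {roc.auc:.3f} (95% CI {roc.ci_lower:.3f}-{roc.ci_upper:.3f})")
```

```
Diagnostic model results
================================================
kind:           logistic
predictors:     mean_similarity
n train:        96
CV accuracy:    0.896 (+/- 0.065, 5 folds)
------------------------------------------------
term                      coef     std err
intercept             -14.3270      3.2017
mean_similarity        34.8160      8.1268
test AUC 0.882 (95% CI 0.733-1.000)
```

The positive slope says the probability of an mt-aaRS diagnosis rises
steeply with the similarity score; `results.youden(test)` places the optimal
operating point at a similarity of about 0.43 (sensitivity 0.92,
specificity 0.83 on this small demo cohort).

## Command line

```sh
mtphen simulate --seed 0 demo_ws        # write a complete simulated workspace
mtphen run demo_ws/config.yaml          # filter -> score -> PP4 -> classify -> evaluate
mtphen report demo_ws/config.yaml      # human-readable run summary
```

A run directory contains `scores.tsv`, `classifications.tsv`,
`exclusions.tsv`, `model_report.json`, ROC point tables, a manifest and a
plain-text report; reruns with the same seed are byte-identical.

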