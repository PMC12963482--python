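"""Seeded generators for ontologies, cohorts and variant tables.

Every stage of the pipeline is testable offline against data produced here.
The generators emulate the statistical structure the analysis assumes:

* a single-rooted HPO-like DAG with a tunable fraction of diamond edges;
* a curated reference cohort with per-gene phenotype profiles whose
  within-gene homogeneity is controlled by ``p_express`` (tight DARS2-like
  clusters at high values, heterogeneous IARS2-like ones at low values) and
  Poisson noise terms;
* labelled query cohorts whose overlap with the reference profiles is set
  by ``theta_pos`` / ``theta_neg``, so downstream classifier performance is
  a known function of the generator;
* variant tables engineered to exercise every filter rule, with the
  ground-truth survivor list computed during generation.

Per-individual term counts are drawn as ``1 + Poisson(3)`` clipped to the
configured bounds (default 1-13), matching the observed range, mean (~4)
and median (~3) of structured phenotype data in rare-disease platforms.
All generators are bit-reproducible given ``(seed, spec)``; one global seed
fans out to fixed per-component substreams so adding a generator does not
perturb the others.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyGraph
from .reference import DEFAULT_GENES, CuratedCase, ReferenceDatabase
from .variants import (
    CandidateGenotype,
    FilterConfig,
    IndividualRecord,
    VariantCall,
)

__all__ = [
    "GeneratorSpec",
    "PUBLISHED_CASE_COUNTS",
    "generate_toy_ontology",
    "generate_reference_cohort",
    "generate_query_cohorts",
    "generate_variant_fixture",
    "VariantFixtureTruth",
    "materialise_workspace",
]

#: Published-individual counts per gene in the curated reference cohort.
PUBLISHED_CASE_COUNTS: dict[str, int] = {
    "AARS2": 44,
    "CARS2": 6,
    "DARS2": 35,
    "EARS2": 28,
    "IARS2": 13,
    "LARS2": 19,
    "NARS2": 25,
    "RARS2": 25,
    "VARS2": 18,
    "WARS2": 21,
}

#: Publication counts per gene (used to synthesise source ids).
_PUBLICATION_COUNTS: dict[str, int] = {
    "AARS2": 21,
    "CARS2": 5,
    "DARS2": 10,
    "EARS2": 12,
    "IARS2": 5,
    "LARS2": 6,
    "NARS2": 12,
    "RARS2": 11,
    "VARS2": 5,
    "WARS2": 8,
}

# fixed substream tags: adding a generator must not perturb the others
_STREAM_ONTOLOGY = 11
_STREAM_REFERENCE = 12
_STREAM_QUERIES = 13
_STREAM_VARIANTS = 14


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic study, with study-condition defaults."""

    seed: int = 0
    # ontology shape
    n_branches: int = 5
    depth: int = 4
    branching: int = 4
    cross_edge_fraction: float = 0.1
    # reference cohort
    genes: tuple[str, ...] = DEFAULT_GENES
    cases_per_gene: Mapping[str, int] = field(
        default_factory=lambda: dict(PUBLISHED_CASE_COUNTS)
    )
    profile_size: int = 8
    p_express: float = 0.8
    noise_rate: float = 1.0
    term_bounds: tuple[int, int] = (1, 13)
    # query cohorts
    n_positive: int = 200
    n_negative: int = 200
    theta_pos: float = 0.9
    theta_neg: float = 0.1
    n_background_profiles: int = 20
    query_term_rate: float = 3.0
    # variant fixture
    n_random_individuals: int = 20

    def __post_init__(self) -> None:
        for name in ("cross_edge_fraction", "p_express", "theta_pos", "theta_neg"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        for name in ("n_branches", "depth", "branching", "profile_size",
                     "n_positive", "n_negative", "n_background_profiles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.term_bounds
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid term bounds {self.term_bounds}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def _term_id(i: int) -> str:
    return f"PT:{i:07d}"


def generate_toy_ontology(spec: GeneratorSpec) -> OntologyGraph:
    """Single-rooted layered DAG: ``n_branches`` top branches, ``depth``
    levels, ``branching`` children per node, plus a seeded fraction of
    cross-edges to one-level-shallower terms (diamonds)."""
    rng = spec.rng(_STREAM_ONTOLOGY)
    root = _term_id(1)
    parents: dict[str, set[str]] = {root: set()}
    labels = {root: "synthetic phenotype root"}
    counter = 2
    levels: list[list[str]] = [[root]]
    for level in range(1, spec.depth + 1):
        new_level: list[str] = []
        if level == 1:
            for _ in range(spec.n_branches):
                tid = _term_id(counter)
                counter += 1
                parents[tid] = {root}
                labels[tid] = f"synthetic term {tid[-7:].lstrip('0')}"
                new_level.append(tid)
        else:
            for parent in levels[-1]:
                for _ in range(spec.branching):
                    tid = _term_id(counter)
                    counter += 1
                    parents[tid] = {parent}
                    labels[tid] = f"synthetic term {tid[-7:].lstrip('0')}"
                    new_level.append(tid)
        levels.append(new_level)

    # cross edges: second parent drawn from the previous level
    for level_idx in range(2, len(levels)):
        pool = levels[level_idx - 1]
        if len(pool) < 2:
            continue
        for tid in levels[level_idx]:
            if rng.random() < spec.cross_edge_fraction:
                current = next(iter(parents[tid]))
                choices = [t for t in pool if t != current]
                extra = choices[int(rng.integers(len(choices)))]
                parents[tid].add(extra)
    return OntologyGraph(parents, labels=labels)


def _leaves(graph: OntologyGraph) -> list[str]:
    return sorted(t for t in graph.active_terms if not graph.children(t))


def _truncate_terms(
    profile_terms: list[str], noise_terms: list[str], bounds: tuple[int, int]
) -> list[str]:
    lo, hi = bounds
    merged: list[str] = []
    for t in profile_terms + noise_terms:
        if t not in merged:
            merged.append(t)
    return merged[:hi]


def generate_reference_cohort(
    spec: GeneratorSpec, graph: OntologyGraph
) -> tuple[ReferenceDatabase, dict[str, tuple[str, ...]]]:
    """Reference cases clustered per gene around fixed disjoint term profiles.

    Returns the database and the per-gene profiles (needed by the query
    generator and by the per-gene annotation export).
    """
    rng = spec.rng(_STREAM_REFERENCE)
    leaves = _leaves(graph)
    n_needed = spec.profile_size * len(spec.genes)
    if n_needed > len(leaves):
        raise ValueError(
            f"profile_size x genes ({n_needed}) exceeds leaf count ({len(leaves)})"
        )
    chosen = rng.choice(len(leaves), size=n_needed, replace=False)
    profiles: dict[str, tuple[str, ...]] = {}
    for gi, gene in enumerate(spec.genes):
        idx = chosen[gi * spec.profile_size : (gi + 1) * spec.profile_size]
        profiles[gene] = tuple(sorted(leaves[i] for i in idx))
    profile_union = {t for terms in profiles.values() for t in terms}
    background = [t for t in leaves if t not in profile_union]

    cases: list[CuratedCase] = []
    case_no = 0
    for gi, gene in enumerate(spec.genes):
        n_cases = int(dict(spec.cases_per_gene).get(gene, 20))
        n_pubs = _PUBLICATION_COUNTS.get(gene, max(1, n_cases // 2))
        pubs = [f"PMID:{9_000_000 + gi * 1000 + k}" for k in range(n_pubs)]
        variant_pool = [
            (f"c.{100 + 7 * k}A>G", f"c.{1000 + 13 * k}C>T") for k in range(max(2, n_cases))
        ]
        for _ in range(n_cases):
            case_no += 1
            kept = [t for t in profiles[gene] if rng.random() < spec.p_express]
            n_noise = int(rng.poisson(spec.noise_rate))
            noise = (
                [background[int(i)] for i in rng.integers(len(background), size=n_noise)]
                if background and n_noise
                else []
            )
            terms = _truncate_terms(kept, noise, spec.term_bounds)
            if not terms:
                terms = [profiles[gene][int(rng.integers(len(profiles[gene])))]]
            v1, v2 = variant_pool[int(rng.integers(len(variant_pool)))]
            cases.append(
                CuratedCase(
                    case_id=f"REF{case_no:04d}",
                    gene=gene,
                    variant1_hgvs=f"{gene}:{v1}",
                    variant1_class=("P" if rng.random() < 0.5 else "LP"),
                    variant2_hgvs=f"{gene}:{v2}",
                    variant2_class=("P" if rng.random() < 0.5 else "LP"),
                    terms=tuple(terms),
                    source_id=pubs[int(rng.integers(len(pubs)))],
                )
            )
    return ReferenceDatabase(cases, genes=spec.genes), profiles


def generate_query_cohorts(
    spec: GeneratorSpec,
    graph: OntologyGraph,
    profiles: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Labelled diagnosed cohort: positives overlap the reference profiles
    with weight ``theta_pos``; negatives are built on distinct background
    profiles with reference contamination ``theta_neg``.

    Returns a frame with ``individual_id``, ``label`` (positive/negative),
    ``causal_gene`` (blank for negatives) and ``hpo_terms`` (tuple).
    """
    rng = spec.rng(_STREAM_QUERIES)
    leaves = _leaves(graph)
    profile_union = {t for terms in profiles.values() for t in terms}
    background_pool = [t for t in leaves if t not in profile_union]
    if not background_pool:
        raise ValueError("no background leaves left outside the gene profiles")
    genes = list(profiles)
    lo, hi = spec.term_bounds

    bg_profiles = []
    for _ in range(spec.n_background_profiles):
        size = min(spec.profile_size, len(background_pool))
        idx = rng.choice(len(background_pool), size=size, replace=False)
        bg_profiles.append([background_pool[int(i)] for i in idx])

    # Both classes are drawn by one mechanism — an assigned reference-gene
    # profile mixed with an assigned background-disease profile — so the
    # classes are exchangeable whenever theta_pos == theta_neg: only the
    # label and the recorded causal gene differ.  (Downstream, scoring mode
    # follows the causal gene, so a null comparison must score label-blind.)
    def _draw(theta: float) -> tuple[str, tuple[str, ...]]:
        gene = genes[int(rng.integers(len(genes)))]
        bg = bg_profiles[int(rng.integers(len(bg_profiles)))]
        n_terms = int(np.clip(1 + rng.poisson(spec.query_term_rate), lo, hi))
        terms: set[str] = set()
        for _ in range(n_terms):
            pool = list(profiles[gene]) if rng.random() < theta else bg
            terms.add(pool[int(rng.integers(len(pool)))])
        return gene, tuple(sorted(terms))

    rows = []
    for i in range(spec.n_positive):
        gene, terms = _draw(spec.theta_pos)
        rows.append(
            {
                "individual_id": f"POS{i + 1:04d}",
                "label": "positive",
                "causal_gene": gene,
                "hpo_terms": terms,
            }
        )
    for i in range(spec.n_negative):
        _gene, terms = _draw(spec.theta_neg)
        rows.append(
            {
                "individual_id": f"NEG{i + 1:04d}",
                "label": "negative",
                "causal_gene": "",
                "hpo_terms": terms,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# variant fixture


@dataclass(frozen=True)
class VariantFixtureTruth:
    """Ground truth emitted alongside the variant fixture.

    ``candidates`` are ``(individual_id, gene, kind, sorted variant keys)``
    signatures expected to survive the full cascade; ``flagged`` is the
    subset expected to carry the phase-review flag; ``excluded_reasons``
    records the expected primary reason for the deterministic individuals.
    """

    candidates: frozenset
    flagged: frozenset
    excluded_reasons: Mapping[str, str]


def _sig(individual_id: str, gene: str, kind: str, keys: Iterable[str]) -> tuple:
    return (individual_id, gene, kind, tuple(sorted(keys)))


def _passes_rules(
    zygosity: str,
    gene: str,
    gnomad_af: float | None,
    hom_count: int | None,
    internal_af: float,
    impact: str,
    clinvar: str | None,
    qc: bool,
    config: FilterConfig,
) -> bool:
    """Independent restatement of the filter rules used to compute fixture
    ground truth at generation time (kept deliberately separate from the
    filter module's implementation)."""
    if gene in config.excluded_genes:
        return False
    af = 0.0 if gnomad_af is None else gnomad_af
    if af >= config.gnomad_af_max:
        return False
    if zygosity == "hom" and (0 if hom_count is None else hom_count) != 0:
        return False
    if internal_af >= config.internal_af_max:
        return False
    if impact not in config.allowed_impacts:
        return False
    if zygosity == "het" and clinvar in ("B", "LB"):
        return False
    return qc


def generate_variant_fixture(
    spec: GeneratorSpec,
    graph: OntologyGraph | None = None,
    profiles: Mapping[str, Sequence[str]] | None = None,
    config: FilterConfig | None = None,
) -> tuple[list[IndividualRecord], VariantFixtureTruth]:
    """Variant cohort exercising every filter rule once, plus seeded extras.

    The deterministic core contains one individual per rule (boundary
    frequencies at exactly 0.01 / 0.02, homozygote count 1, LOW impact,
    ClinVar LB, QC failure, excluded gene, single het, cis pair, missing
    phenotype, inconsistent segregation).  ``n_random_individuals`` further
    seeded individuals stress the cascade; their expected outcome is
    computed during generation with an independent restatement of the rules.
    """
    config = config or FilterConfig()
    rng = spec.rng(_STREAM_VARIANTS)
    genes = list(spec.genes)

    def terms_for(individual_idx: int, gene: str) -> tuple[str, ...]:
        if profiles is None or gene not in profiles:
            return ("PT:0000002",)
        pool = list(profiles[gene])
        theta = 0.9 if individual_idx % 2 == 0 else 0.25
        n_terms = int(np.clip(1 + rng.poisson(spec.query_term_rate), *spec.term_bounds))
        out: set[str] = set()
        all_profiles = [t for ts in profiles.values() for t in ts]
        for _ in range(n_terms):
            if rng.random() < theta:
                out.add(pool[int(rng.integers(len(pool)))])
            else:
                out.add(all_profiles[int(rng.integers(len(all_profiles)))])
        return tuple(sorted(out))

    def call(iid, gene, chrom, pos, ref, alt, zyg, af, hc, iaf, impact,
             clinvar=None, qc=True) -> VariantCall:
        return VariantCall(
            individual_id=iid, gene=gene, chrom=chrom, pos=pos, ref=ref,
            alt=alt, zygosity=zyg, gnomad_af=af, gnomad_hom_count=hc,
            internal_af=iaf, impact=impact, clinvar_class=clinvar, qc_pass=qc,
        )

    records: list[IndividualRecord] = []
    expected: set[tuple] = set()
    flagged: set[tuple] = set()
    reasons: dict[str, str] = {}
    idx = 0

    def add(rec: IndividualRecord) -> None:
        nonlocal idx
        records.append(rec)
        idx += 1

    g0, g1 = genes[0], genes[1 % len(genes)]

    # -- deterministic core: homozygous branch -----------------------------
    v = call("HOM_OK", g0, "chr1", 5000, "A", "G", "hom", 0.005, 0, 0.01, "HIGH")
    add(IndividualRecord("HOM_OK", True, False, terms_for(idx, g0), (v,)))
    expected.add(_sig("HOM_OK", g0, "hom", [v.key]))

    v = call("HOM_AF", g0, "chr1", 5100, "A", "G", "hom", 0.01, 0, 0.01, "HIGH")
    add(IndividualRecord("HOM_AF", True, False, terms_for(idx, g0), (v,)))
    reasons["HOM_AF"] = "gnomad_af"  # 0.01 is NOT < 0.01

    v = call("HOM_HC", g0, "chr1", 5200, "A", "G", "hom", 0.005, 1, 0.01, "HIGH")
    add(IndividualRecord("HOM_HC", True, False, terms_for(idx, g0), (v,)))
    reasons["HOM_HC"] = "hom_count"

    v = call("HOM_IAF", g0, "chr1", 5300, "A", "G", "hom", 0.005, 0, 0.02, "HIGH")
    add(IndividualRecord("HOM_IAF", True, False, terms_for(idx, g0), (v,)))
    reasons["HOM_IAF"] = "internal_af"  # 0.02 is NOT < 0.02

    v = call("HOM_IMP", g0, "chr1", 5400, "A", "G", "hom", 0.005, 0, 0.01, "LOW")
    add(IndividualRecord("HOM_IMP", True, False, terms_for(idx, g0), (v,)))
    reasons["HOM_IMP"] = "impact"

    v = call("HOM_QC", g0, "chr1", 5500, "A", "G", "hom", 0.005, 0, 0.01, "HIGH", qc=False)
    add(IndividualRecord("HOM_QC", True, False, terms_for(idx, g0), (v,)))
    reasons["HOM_QC"] = "qc_fail"

    v = call("HOM_GENE", "KARS", "chr16", 5600, "A", "G", "hom", 0.0, 0, 0.0, "HIGH")
    add(IndividualRecord("HOM_GENE", True, False, ("PT:0000002",), (v,)))
    reasons["HOM_GENE"] = "excluded_gene"

    # absent gnomAD annotations treated as rare
    v = call("HOM_NOAF", g0, "chr1", 5700, "A", "G", "hom", None, None, 0.001, "MODERATE")
    add(IndividualRecord("HOM_NOAF", True, False, terms_for(idx, g0), (v,)))
    expected.add(_sig("HOM_NOAF", g0, "hom", [v.key]))

    # -- deterministic core: compound-het branch ---------------------------
    v1 = call("CH_OK", g1, "chr2", 10_000, "C", "T", "het", 0.001, None, 0.001, "HIGH")
    v2 = call("CH_OK", g1, "chr2", 20_000, "G", "A", "het", 0.002, None, 0.001, "MODERATE")
    add(IndividualRecord("CH_OK", True, False, terms_for(idx, g1), (v1, v2)))
    expected.add(_sig("CH_OK", g1, "comp_het", [v1.key, v2.key]))

    v1 = call("CH_SINGLE", g1, "chr2", 30_000, "C", "T", "het", 0.001, None, 0.001, "HIGH")
    add(IndividualRecord("CH_SINGLE", True, False, terms_for(idx, g1), (v1,)))
    reasons["CH_SINGLE"] = "single_het"

    v1 = call("CH_LB", g1, "chr2", 40_000, "C", "T", "het", 0.001, None, 0.001, "HIGH")
    v2 = call("CH_LB", g1, "chr2", 50_000, "G", "A", "het", 0.001, None, 0.001, "HIGH",
              clinvar="LB")
    add(IndividualRecord("CH_LB", True, False, terms_for(idx, g1), (v1, v2)))
    reasons["CH_LB"] = "single_het"  # survivor count drops to one

    # six-variant table: one AF fail, one ClinVar LB, one LOW impact,
    # three passes in one gene -> C(3,2) = 3 candidate pairs
    six = [
        call("CH_SIX", g0, "chr1", 60_000, "C", "T", "het", 0.02, None, 0.001, "HIGH"),
        call("CH_SIX", g0, "chr1", 61_000, "C", "T", "het", 0.001, None, 0.001, "HIGH",
             clinvar="LB"),
        call("CH_SIX", g0, "chr1", 62_000, "C", "T", "het", 0.001, None, 0.001, "LOW"),
        call("CH_SIX", g0, "chr1", 63_000, "C", "T", "het", 0.001, None, 0.001, "HIGH"),
        call("CH_SIX", g0, "chr1", 64_000, "C", "T", "het", 0.001, None, 0.001, "MODERATE"),
        call("CH_SIX", g0, "chr1", 65_000, "C", "T", "het", 0.001, None, 0.001, "HIGH"),
    ]
    add(IndividualRecord("CH_SIX", True, False, terms_for(idx, g0), tuple(six)))
    for a in (3, 4, 5):
        for b in (3, 4, 5):
            if a < b:
                expected.add(_sig("CH_SIX", g0, "comp_het", [six[a].key, six[b].key]))

    # cis pair 40 bp apart -> flagged but retained
    v1 = call("CH_CIS", g1, "chr2", 70_000, "C", "T", "het", 0.001, None, 0.001, "HIGH")
    v2 = call("CH_CIS", g1, "chr2", 70_040, "G", "A", "het", 0.001, None, 0.001, "HIGH")
    add(IndividualRecord("CH_CIS", True, False, terms_for(idx, g1), (v1, v2)))
    sig = _sig("CH_CIS", g1, "comp_het", [v1.key, v2.key])
    expected.add(sig)
    flagged.add(sig)

    # candidate without phenotype terms -> excluded late
    v1 = call("CH_NOHPO", g1, "chr2", 80_000, "C", "T", "het", 0.001, None, 0.001, "HIGH")
    v2 = call("CH_NOHPO", g1, "chr2", 90_000, "G", "A", "het", 0.001, None, 0.001, "HIGH")
    add(IndividualRecord("CH_NOHPO", True, False, (), (v1, v2)))
    reasons["CH_NOHPO"] = "no_hpo"

    # inconsistent segregation -> excluded late
    v1 = call("CH_SEG", g1, "chr2", 100_000, "C", "T", "het", 0.001, None, 0.001, "HIGH")
    v2 = call("CH_SEG", g1, "chr2", 110_000, "G", "A", "het", 0.001, None, 0.001, "HIGH")
    add(
        IndividualRecord(
            "CH_SEG", True, False, terms_for(idx, g1), (v1, v2),
            segregation={frozenset((v1.key, v2.key)): "inconsistent"},
        )
    )
    reasons["CH_SEG"] = "segregation"

    # unknown segregation -> retained
    v1 = call("CH_SEGU", g1, "chr2", 120_000, "C", "T", "het", 0.001, None, 0.001, "HIGH")
    v2 = call("CH_SEGU", g1, "chr2", 130_000, "G", "A", "het", 0.001, None, 0.001, "HIGH")
    add(
        IndividualRecord(
            "CH_SEGU", True, False, terms_for(idx, g1), (v1, v2),
            segregation={frozenset((v1.key, v2.key)): "unknown"},
        )
    )
    expected.add(_sig("CH_SEGU", g1, "comp_het", [v1.key, v2.key]))

    # status exclusions
    v = call("NOT_AFF", g0, "chr1", 200_000, "A", "G", "hom", 0.0, 0, 0.0, "HIGH")
    add(IndividualRecord("NOT_AFF", False, False, terms_for(idx, g0), (v,)))
    reasons["NOT_AFF"] = "not_affected"
    v = call("SOLVED", g0, "chr1", 210_000, "A", "G", "hom", 0.0, 0, 0.0, "HIGH")
    add(IndividualRecord("SOLVED", True, True, terms_for(idx, g0), (v,)))
    reasons["SOLVED"] = "solved"

    # -- seeded random extras ----------------------------------------------
    af_pool = [0.0, 0.001, 0.005, 0.01, 0.02, None]
    iaf_pool = [0.0, 0.005, 0.019, 0.02, 0.03]
    impact_pool = ["HIGH", "MODERATE", "LOW", "MODIFIER"]
    clinvar_pool = [None, "VUS", "LB", "B", "P"]
    for k in range(spec.n_random_individuals):
        iid = f"RND{k + 1:03d}"
        gene = genes[int(rng.integers(len(genes)))]
        chrom = f"chr{int(rng.integers(1, 23))}"
        n_var = int(rng.integers(1, 5))
        zyg = "hom" if rng.random() < 0.3 else "het"
        variants = []
        for j in range(n_var):
            variants.append(
                call(
                    iid, gene, chrom, 1_000_000 + 10_000 * j + int(rng.integers(0, 300)),
                    "A", "G", zyg,
                    af_pool[int(rng.integers(len(af_pool)))],
                    int(rng.integers(0, 2)) if zyg == "hom" else None,
                    iaf_pool[int(rng.integers(len(iaf_pool)))],
                    impact_pool[int(rng.integers(len(impact_pool)))],
                    clinvar_pool[int(rng.integers(len(clinvar_pool)))],
                    qc=bool(rng.random() < 0.9),
                )
            )
        add(IndividualRecord(iid, True, False, terms_for(idx, gene), tuple(variants)))
        # ground truth via the independent rule restatement
        surv_hom = [
            v for v in variants
            if v.zygosity == "hom" and _passes_rules(
                "hom", v.gene, v.gnomad_af, v.gnomad_hom_count, v.internal_af,
                v.impact, v.clinvar_class, v.qc_pass, config)
        ]
        for v in surv_hom:
            expected.add(_sig(iid, v.gene, "hom", [v.key]))
        surv_het = [
            v for v in variants
            if v.zygosity == "het" and _passes_rules(
                "het", v.gene, v.gnomad_af, v.gnomad_hom_count, v.internal_af,
                v.impact, v.clinvar_class, v.qc_pass, config)
        ]
        for a in range(len(surv_het)):
            for b in range(a + 1, len(surv_het)):
                s = _sig(iid, gene, "comp_het", [surv_het[a].key, surv_het[b].key])
                expected.add(s)
                if abs(surv_het[a].pos - surv_het[b].pos) <= config.cis_window_bp:
                    flagged.add(s)

    truth = VariantFixtureTruth(
        candidates=frozenset(expected),
        flagged=frozenset(flagged),
        excluded_reasons=dict(reasons),
    )
    return records, truth


# ---------------------------------------------------------------------------
# workspace


def _evidence_presets(rng: np.random.Generator) -> list[str]:
    presets = [
        ["PVS1", "PM2"],            # -> LP
        ["PS1", "PM2"],             # -> LP
        ["PM2", "PP3"],             # -> VUS
        ["PS1", "PP1"],             # -> VUS, upgrades to LP with PP4 supporting
        ["PM2", "PP1", "PP3"],      # -> VUS, upgrades to LP with PP4 moderate
        ["PM2"],                    # -> VUS
        ["PP3"],                    # -> VUS
    ]
    weights = np.array([1, 1, 2, 2, 2, 2, 1], dtype=float)
    weights /= weights.sum()
    return presets[int(rng.choice(len(presets), p=weights))]


def materialise_workspace(spec: GeneratorSpec, outdir: str | os.PathLike) -> dict[str, str]:
    """Write a complete simulated study workspace in the formats the real
    pipeline reads; returns the path of every artefact plus a run config."""
    import yaml

    from .ontology import write_obo

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "ontology": "ontology.obo",
        "gene_annotations": "gene_annotations.tsv",
        "reference_db": "reference_db.tsv",
        "variants": "cohort_variants.tsv",
        "phenotypes": "cohort_phenotypes.tsv",
        "segregation": "segregation.tsv",
        "diagnosed": "diagnosed_cohort.tsv",
        "evidence": "evidence.tsv",
        "ranks": "exomiser_ranks.tsv",
        "config": "config.yaml",
    }.items()}

    graph = generate_toy_ontology(spec)
    write_obo(graph, paths["ontology"])

    reference, profiles = generate_reference_cohort(spec, graph)
    reference.to_tsv(paths["reference_db"])

    # per-gene annotation export: profile terms plus their direct parents
    rows = []
    for gene, terms in profiles.items():
        annotated = set(terms)
        for t in terms:
            annotated |= set(graph.parents(t))
        for t in sorted(annotated):
            rows.append({"gene": gene, "term": t})
    pd.DataFrame(rows).to_csv(
        paths["gene_annotations"], sep="\t", index=False, header=False
    )

    diagnosed = generate_query_cohorts(spec, graph, profiles)
    export = diagnosed.copy()
    export["hpo_terms"] = export["hpo_terms"].map(";".join)
    export.to_csv(paths["diagnosed"], sep="\t", index=False)

    records, _truth = generate_variant_fixture(spec, graph, profiles)
    var_rows, phen_rows, seg_rows = [], [], []
    for rec in records:
        for v in rec.variants:
            var_rows.append({
                "individual_id": v.individual_id, "gene": v.gene,
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "zygosity": v.zygosity,
                "gnomad_af": "" if v.gnomad_af is None else v.gnomad_af,
                "gnomad_hom_count": "" if v.gnomad_hom_count is None else v.gnomad_hom_count,
                "internal_af": v.internal_af, "impact": v.impact,
                "clinvar_class": v.clinvar_class or "",
                "qc_pass": v.qc_pass,
            })
        phen_rows.append({
            "individual_id": rec.individual_id,
            "affected": rec.affected, "solved": rec.solved,
            "hpo_terms": ";".join(rec.terms),
        })
        for keys, outcome in rec.segregation.items():
            seg_rows.append({
                "individual_id": rec.individual_id,
                "variant_keys": "|".join(sorted(keys)),
                "outcome": outcome,
            })
    pd.DataFrame(var_rows).to_csv(paths["variants"], sep="\t", index=False)
    pd.DataFrame(phen_rows).to_csv(paths["phenotypes"], sep="\t", index=False)
    pd.DataFrame(
        seg_rows, columns=["individual_id", "variant_keys", "outcome"]
    ).to_csv(paths["segregation"], sep="\t", index=False)

    rng = spec.rng(_STREAM_VARIANTS + 100)
    ev_rows = []
    for rec in records:
        for v in rec.variants:
            if v.gene not in spec.genes:
                continue
            for code in _evidence_presets(rng):
                ev_rows.append({"variant_key": v.key, "code": code, "strength": ""})
    frame = pd.DataFrame(ev_rows).drop_duplicates(subset=["variant_key", "code"])
    frame.to_csv(paths["evidence"], sep="\t", index=False)

    rank_rows = []
    for rec in records:
        if rng.random() < 0.75 and rec.variants:
            rank_rows.append({
                "individual_id": rec.individual_id,
                "gene": rec.variants[0].gene,
                "rank": int(rng.integers(1, 41)),
            })
    pd.DataFrame(
        rank_rows, columns=["individual_id", "gene", "rank"]
    ).to_csv(paths["ranks"], sep="\t", index=False)

    config = {
        "ontology": paths["ontology"],
        "gene_annotations": paths["gene_annotations"],
        "reference_db": paths["reference_db"],
        "variants": paths["variants"],
        "phenotypes": paths["phenotypes"],
        "segregation": paths["segregation"],
        "diagnosed_cohort": paths["diagnosed"],
        "evidence": paths["evidence"],
        "rank_table": paths["ranks"],
        "seed": int(spec.seed),
        "balance": True,
        "evaluate_unbalanced": True,
        "output_dir": os.path.join(outdir, "results"),
    }
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths
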