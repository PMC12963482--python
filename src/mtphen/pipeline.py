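"""End-to-end orchestration: filter -> score -> PP4 -> classify -> evaluate.

A run consumes an ontology, a gene-annotation list, the curated reference
database, the cohort's variant/phenotype/segregation tables, per-variant
evidence and (optionally) an external gene-rank table, and writes a run
directory with the score table, the per-allele classification table, the
exclusion ledger, a machine-readable model report, a rank summary, a run
manifest and a human-readable report.  Reruns with identical inputs and
seeds are byte-identical (no timestamps are written).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .acmg import (
    CaseStatus,
    Classification,
    Evidence,
    Strength,
    classify_case_status,
    combine_evidence,
    pp4_from_score,
    revise_classifications,
)
from .model_eval import DiagnosticModel, build_modelling_dataset
from .ontology import (
    AnnotationCorpus,
    information_content,
    load_gene_annotation_set,
    parse_obo,
)
from .reference import load_reference_db
from .similarity import SimilarityConfig, SimilarityEngine, average_ic
from .variants import (
    CandidateSet,
    FilterConfig,
    apply_individual_exclusions,
    filter_compound_het_candidates,
    filter_homozygous_candidates,
    flag_cis_artefacts,
    load_cohort,
    merge_candidate_sets,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RankSummary",
    "run_workflow",
    "summarize_exomiser_ranks",
    "write_report",
]

#: Individual-level precedence when one person accrued several ledger rows.
_REASON_PRECEDENCE = [
    "not_affected",
    "solved",
    "no_hpo",
    "segregation",
    "excluded_gene",
    "gnomad_af",
    "hom_count",
    "internal_af",
    "impact",
    "clinvar_blb",
    "qc_fail",
    "gnomad_af_missing",
    "hom_count_missing",
    "single_het",
    "no_heterozygous_variant",
    "no_homozygous_variant",
]

_STATUS_ORDER = [
    CaseStatus.LIKELY_DIAGNOSIS,
    CaseStatus.CANDIDATE_FURTHER_INVESTIGATION,
    CaseStatus.VUS_FINDING,
    CaseStatus.NOT_PRIORITISED,
]


@dataclass
class RunConfig:
    """Paths, thresholds and seeds of one pipeline run."""

    ontology: str
    reference_db: str
    variants: str
    phenotypes: str
    output_dir: str
    gene_annotations: str | None = None
    segregation: str | None = None
    diagnosed_cohort: str | None = None
    evidence: str | None = None
    rank_table: str | None = None
    seed: int = 0
    balance: bool = True
    evaluate_unbalanced: bool = True
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    similarity_config: SimilarityConfig = field(default_factory=SimilarityConfig)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {
            "ontology", "reference_db", "variants", "phenotypes", "output_dir",
            "gene_annotations", "segregation", "diagnosed_cohort", "evidence",
            "rank_table", "seed", "balance", "evaluate_unbalanced",
        }
        kwargs = {k: v for k, v in raw.items() if k in known}
        return cls(**kwargs)

    def validate(self) -> None:
        for name in ("ontology", "reference_db", "variants", "phenotypes"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} path does not exist: {path}")


@dataclass(frozen=True)
class RankSummary:
    """Band counts of an external prioritiser's gene ranks."""

    top10: int
    rank11_20: int
    outliers: int  # ranked > 20
    unranked: int

    @property
    def total(self) -> int:
        return self.top10 + self.rank11_20 + self.outliers + self.unranked

    def as_dict(self) -> dict[str, int]:
        return {
            "top10": self.top10,
            "rank11_20": self.rank11_20,
            "outliers": self.outliers,
            "unranked": self.unranked,
        }


def summarize_exomiser_ranks(
    rank_table: pd.DataFrame | str | os.PathLike | None,
    individual_ids: Iterable[str],
) -> RankSummary:
    """Band the best external rank per individual (<=10 / 11-20 / >20 /
    unranked); individuals absent from the table count as unranked."""
    ids = list(dict.fromkeys(individual_ids))
    if rank_table is None:
        return RankSummary(0, 0, 0, len(ids))
    if not isinstance(rank_table, pd.DataFrame):
        rank_table = pd.read_csv(rank_table, sep="\t")
    best: dict[str, int] = {}
    if len(rank_table):
        for row in rank_table.to_dict(orient="records"):
            rank = int(row["rank"])
            if rank < 1:
                raise ValueError(f"non-positive rank {rank} for {row['individual_id']!r}")
            iid = str(row["individual_id"])
            best[iid] = min(best.get(iid, rank), rank)
    top10 = r11 = out = unranked = 0
    for iid in ids:
        rank = best.get(iid)
        if rank is None:
            unranked += 1
        elif rank <= 10:
            top10 += 1
        elif rank <= 20:
            r11 += 1
        else:
            out += 1
    return RankSummary(top10, r11, out, unranked)


def primary_exclusion_reasons(candidates: CandidateSet) -> dict[str, str]:
    """One primary reason per excluded individual, by fixed precedence."""
    reasons: dict[str, str] = {}
    for e in candidates.exclusions:
        if e.individual_id in candidates.candidate_individuals:
            continue
        current = reasons.get(e.individual_id)
        if current is None:
            reasons[e.individual_id] = e.reason
            continue
        if _REASON_PRECEDENCE.index(e.reason) < _REASON_PRECEDENCE.index(current):
            reasons[e.individual_id] = e.reason
    return reasons


def _load_evidence_table(path: str | None) -> dict[str, list[Evidence]]:
    if path is None:
        return {}
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, list[Evidence]] = {}
    for row in frame.to_dict(orient="records"):
        strength = Strength(row["strength"]) if row.get("strength") else None
        out.setdefault(row["variant_key"], []).append(
            Evidence(row["code"], strength)
        )
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"unserialisable {type(obj)!r}")


def run_workflow(config: RunConfig) -> dict[str, object]:
    """Execute the full pipeline and write every report to the run directory.

    Returns the in-memory artefacts (candidate set, score/classification
    frames, model report, rank summary, manifest) keyed by name.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)

    def _stage(name: str):
        logger.info("[stage:%s] starting", name)

    try:
        _stage("ontology")
        graph = parse_obo(config.ontology)
        annotation = (
            load_gene_annotation_set(config.gene_annotations, graph)
            if config.gene_annotations
            else None
        )
        _stage("reference")
        reference = load_reference_db(config.reference_db, graph, genes=None)
        _stage("cohort")
        cohort = load_cohort(config.variants, config.phenotypes, config.segregation)
    except Exception as err:
        raise RuntimeError(f"pipeline failed during input loading: {err}") from err

    _stage("filter")
    hom = filter_homozygous_candidates(cohort, config.filter_config)
    comp = filter_compound_het_candidates(cohort, config.filter_config)
    merged = merge_candidate_sets(hom, comp)
    merged = flag_cis_artefacts(merged, config.filter_config)
    candidates = apply_individual_exclusions(merged, cohort)

    cohort_ids = {rec.individual_id for rec in cohort}
    covered = candidates.candidate_individuals | candidates.excluded_individuals
    if covered != cohort_ids:
        missing = sorted(cohort_ids - covered)
        raise RuntimeError(f"filter stage lost individuals: {missing}")

    _stage("information_content")
    corpus = AnnotationCorpus(
        {case.case_id: case.terms for case in reference.cases}, graph
    )
    ic = information_content(graph, corpus)

    _stage("similarity")
    by_id = {rec.individual_id: rec for rec in cohort}
    diagnosed = None
    if config.diagnosed_cohort:
        diagnosed = pd.read_csv(config.diagnosed_cohort, sep="\t", dtype=str).fillna("")
        diagnosed["terms"] = diagnosed["hpo_terms"].map(
            lambda s: tuple(t for t in s.split(";") if t)
        )
    universe: set[str] = set()
    for case in reference.cases:
        universe.update(case.terms)
    for cand in candidates.candidates:
        universe.update(by_id[cand.individual_id].terms)
    if diagnosed is not None:
        for terms in diagnosed["terms"]:
            universe.update(terms)
    universe = {graph.resolve(t) for t in universe}
    engine = SimilarityEngine(graph, ic, config.similarity_config, sorted(universe))

    score_rows = []
    scores: dict[tuple[str, str], float] = {}
    for iid, gene in sorted({(c.individual_id, c.gene) for c in candidates.candidates}):
        score = engine.mean_phenotype_similarity(by_id[iid].terms, gene, reference)
        scores[(iid, gene)] = score.value
        score_rows.append(
            {
                "individual_id": iid,
                "gene": gene,
                "score": round(score.value, 6),
                "mode": score.mode,
                "n_used": score.n_reference_cases_used,
            }
        )
    score_frame = pd.DataFrame(
        score_rows, columns=["individual_id", "gene", "score", "mode", "n_used"]
    )

    _stage("classification")
    evidence_table = _load_evidence_table(config.evidence)
    class_rows = []
    individual_status: dict[str, CaseStatus] = {}
    for cand in sorted(
        candidates.candidates,
        key=lambda c: (c.individual_id, c.gene, tuple(sorted(c.variant_keys))),
    ):
        rec = by_id[cand.individual_id]
        value = scores[(cand.individual_id, cand.gene)]
        pp4 = pp4_from_score(
            value, config.similarity_config, has_phenotype=bool(rec.terms)
        )
        ev_lists = [list(evidence_table.get(v.key, [])) for v in cand.variants]
        initial = [combine_evidence(ev) for ev in ev_lists]
        revised = revise_classifications(initial, ev_lists, pp4)
        status = classify_case_status(revised)
        current = individual_status.get(cand.individual_id)
        if current is None or _STATUS_ORDER.index(status) < _STATUS_ORDER.index(current):
            individual_status[cand.individual_id] = status
        for allele_idx, (v, init, rev) in enumerate(zip(cand.variants, initial, revised), 1):
            class_rows.append(
                {
                    "individual_id": cand.individual_id,
                    "gene": cand.gene,
                    "genotype": "|".join(sorted(cand.variant_keys)),
                    "kind": cand.kind,
                    "allele": allele_idx,
                    "variant_key": v.key,
                    "initial_class": init.name,
                    "pp4": (pp4.effective_strength.value if pp4 else "none"),
                    "revised_class": rev.name,
                    "case_status": status.value,
                    "score": round(value, 6),
                    "flags": ";".join(sorted(cand.flags)),
                }
            )
    class_frame = pd.DataFrame(
        class_rows,
        columns=[
            "individual_id", "gene", "genotype", "kind", "allele", "variant_key",
            "initial_class", "pp4", "revised_class", "case_status", "score", "flags",
        ],
    )

    _stage("model_eval")
    model_report: dict[str, dict] = {}
    roc_frames: dict[str, pd.DataFrame] = {}
    if diagnosed is not None and len(reference):
        pos_rows, neg_rows = [], []
        for case in reference.cases:
            s = engine.mean_phenotype_similarity(
                case.terms, case.gene, reference, exclude_case_id=case.case_id
            )
            pos_rows.append(
                {
                    "individual_id": case.case_id,
                    "mean_similarity": s.value,
                    "term_count": len(set(case.terms)),
                    "average_ic": average_ic(case.terms, ic),
                }
            )
        for row in diagnosed.to_dict(orient="records"):
            gene = row.get("causal_gene", "") or None
            s = engine.mean_phenotype_similarity(row["terms"], gene, reference)
            entry = {
                "individual_id": row["individual_id"],
                "mean_similarity": s.value,
                "term_count": len(set(row["terms"])),
                "average_ic": average_ic(row["terms"], ic),
            }
            if gene is not None and gene in reference.gene_index:
                pos_rows.append(entry)
            else:
                neg_rows.append(entry)
        positives = pd.DataFrame(pos_rows)
        negatives = pd.DataFrame(neg_rows)

        datasets = [("balanced", True)]
        if config.evaluate_unbalanced:
            datasets.append(("unbalanced", False))
        for ds_name, balance in datasets:
            train, test = build_modelling_dataset(
                positives, negatives, balance=balance, seed=config.seed
            )
            for kind, tag in (("logistic", "glm"), ("random_forest", "rf")):
                results = DiagnosticModel(train, kind=kind, seed=config.seed).fit()
                metrics = results.evaluate(test)
                roc = results.roc(test)
                youden = results.youden(test)
                model_report[f"{tag}_{ds_name}"] = {
                    "n_train": int(len(train)),
                    "n_test": int(len(test)),
                    "metrics": metrics.as_dict(),
                    "auc": roc.auc,
                    "auc_ci": [roc.ci_lower, roc.ci_upper],
                    "cv_accuracy_mean": results.cv_accuracy_mean,
                    "youden": youden,
                    "importances": (
                        results.importances.to_dict()
                        if results.importances is not None
                        else None
                    ),
                    "params": dict(results.params) if results.params else None,
                }
                roc_frames[f"{tag}_{ds_name}"] = roc.points_frame()

    _stage("ranks")
    rank_summary = summarize_exomiser_ranks(
        config.rank_table if config.rank_table else None,
        sorted(candidates.candidate_individuals),
    )

    _stage("write")
    reasons = primary_exclusion_reasons(candidates)
    manifest = {
        "package_version": __version__,
        "seed": int(config.seed),
        "inputs": {
            "ontology": config.ontology,
            "reference_db": config.reference_db,
            "variants": config.variants,
            "phenotypes": config.phenotypes,
            "diagnosed_cohort": config.diagnosed_cohort,
            "evidence": config.evidence,
            "rank_table": config.rank_table,
        },
        "counts": {
            "cohort_individuals": len(cohort_ids),
            "candidate_individuals": len(candidates.candidate_individuals),
            "candidate_genotypes": len(candidates.candidates),
            "excluded_individuals": len(reasons),
            "reference_cases": len(reference),
            "statuses": {
                status.value: sum(
                    1 for s in individual_status.values() if s is status
                )
                for status in _STATUS_ORDER
            },
        },
        "rank_summary": rank_summary.as_dict(),
        "model_report_keys": sorted(model_report),
    }

    outputs = {
        "scores": os.path.join(config.output_dir, "scores.tsv"),
        "classifications": os.path.join(config.output_dir, "classifications.tsv"),
        "exclusions": os.path.join(config.output_dir, "exclusions.tsv"),
        "model_report": os.path.join(config.output_dir, "model_report.json"),
        "manifest": os.path.join(config.output_dir, "manifest.json"),
        "report": os.path.join(config.output_dir, "report.txt"),
    }
    score_frame.to_csv(outputs["scores"], sep="\t", index=False)
    class_frame.to_csv(outputs["classifications"], sep="\t", index=False)
    candidates.ledger_frame().sort_values(
        ["individual_id", "variant_key", "reason"]
    ).to_csv(outputs["exclusions"], sep="\t", index=False)
    with open(outputs["model_report"], "w", encoding="utf-8") as fh:
        json.dump(model_report, fh, indent=1, sort_keys=True, default=_json_default)
    with open(outputs["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
    for name, frame in roc_frames.items():
        frame.to_csv(
            os.path.join(config.output_dir, f"roc_points_{name}.tsv"),
            sep="\t",
            index=False,
        )

    artefacts = {
        "candidates": candidates,
        "scores": score_frame,
        "classifications": class_frame,
        "individual_status": individual_status,
        "exclusion_reasons": reasons,
        "model_report": model_report,
        "rank_summary": rank_summary,
        "manifest": manifest,
        "outputs": outputs,
    }
    report_text = write_report(artefacts)
    with open(outputs["report"], "w", encoding="utf-8") as fh:
        fh.write(report_text)
    artefacts["report_text"] = report_text
    return artefacts


def write_report(artefacts: Mapping[str, object]) -> str:
    """Human-readable run summary with conserved counts per stage."""
    manifest = artefacts["manifest"]
    counts = manifest["counts"]
    reasons: Mapping[str, str] = artefacts["exclusion_reasons"]
    lines = [
        "mtphen run summary",
        "==================",
        f"cohort individuals:        {counts['cohort_individuals']}",
        f"candidate individuals:     {counts['candidate_individuals']}",
        f"candidate genotypes:       {counts['candidate_genotypes']}",
        f"excluded individuals:      {counts['excluded_individuals']}",
        "",
        "exclusions by primary reason:",
    ]
    tally: dict[str, int] = {}
    for reason in reasons.values():
        tally[reason] = tally.get(reason, 0) + 1
    for reason in sorted(tally):
        lines.append(f"  {reason:<24} {tally[reason]}")
    if not tally:
        lines.append("  (none)")
    lines.append("")
    lines.append("case statuses:")
    for status, n in counts["statuses"].items():
        lines.append(f"  {status:<32} {n}")
    lines.append("")
    rank = manifest["rank_summary"]
    lines.append(
        "external ranks: "
        f"top10={rank['top10']} 11-20={rank['rank11_20']} "
        f">20={rank['outliers']} unranked={rank['unranked']}"
    )
    model_report: Mapping[str, dict] = artefacts["model_report"]
    if model_report:
        lines.append("")
        lines.append("model evaluation (test set):")
        for key in sorted(model_report):
            entry = model_report[key]
            lo, hi = entry["auc_ci"]
            lines.append(
                f"  {key:<16} AUC={entry['auc']:.3f} "
                f"(95% CI {lo:.3f}-{hi:.3f}) "
                f"acc={entry['metrics']['accuracy']:.3f} "
                f"youden_sim={entry['youden']['similarity_at_threshold']:.3f}"
            )
    total = counts["candidate_individuals"] + counts["excluded_individuals"]
    lines.append("")
    lines.append(
        f"conservation: candidates + excluded = {total} "
        f"(cohort {counts['cohort_individuals']})"
    )
    return "\n".join(lines) + "\n"
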