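"""Recessive candidate selection: filters, exclusions and cis flagging.

The cascade mirrors standard rare-disease practice for recessive candidate
genotypes in a pre-annotated cohort:

* homozygous branch: affected, unsolved individuals with a homozygous
  variant at gnomAD AF < 0.01, gnomAD homozygote count = 0, internal cohort
  AF < 0.02, HIGH/MODERATE impact, passing QC, outside the excluded
  (bifunctional) genes;
* compound-heterozygous branch: two or more heterozygous variants in the
  same gene, each passing the frequency/impact/QC rules and not annotated
  Benign or Likely Benign in ClinVar; every unordered pair of survivors in
  a gene is a candidate genotype;
* pairs closer than a read length are flagged for phase review (possible
  cis artefacts) but never auto-excluded;
* individuals without phenotype terms and genotypes with inconsistent
  segregation are removed last.

Absent gnomAD annotations are treated as "not observed" (0) by default.
Every non-surviving individual or variant lands in an exclusion ledger with
exactly one primary reason, so inputs always equal survivors + exclusions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "VariantCall",
    "IndividualRecord",
    "FilterConfig",
    "CandidateGenotype",
    "Exclusion",
    "CandidateSet",
    "filter_homozygous_candidates",
    "filter_compound_het_candidates",
    "flag_cis_artefacts",
    "apply_individual_exclusions",
    "merge_candidate_sets",
    "load_cohort",
]

_IMPACTS = {"HIGH", "MODERATE", "LOW", "MODIFIER"}
_CLINVAR = {"B", "LB", "VUS", "LP", "P", None}


@dataclass(frozen=True)
class VariantCall:
    """One annotated variant observed in one individual."""

    individual_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str  # "hom" | "het"
    gnomad_af: float | None
    gnomad_hom_count: int | None
    internal_af: float
    impact: str
    clinvar_class: str | None = None
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.zygosity not in ("hom", "het"):
            raise ValueError(f"zygosity must be hom/het, got {self.zygosity!r}")
        if self.impact not in _IMPACTS:
            raise ValueError(f"unknown impact {self.impact!r}")
        if self.clinvar_class not in _CLINVAR:
            raise ValueError(f"unknown ClinVar class {self.clinvar_class!r}")
        for name, value in (("gnomad_af", self.gnomad_af), ("internal_af", self.internal_af)):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {value}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class IndividualRecord:
    """A cohort member: status flags, phenotype terms and variant calls.

    ``segregation`` maps an unordered set of variant keys (one key for a
    homozygous genotype) to ``consistent`` / ``inconsistent`` / ``unknown``.
    """

    individual_id: str
    affected: bool
    solved: bool
    terms: tuple[str, ...] = ()
    variants: tuple[VariantCall, ...] = ()
    segregation: Mapping[frozenset, str] = field(default_factory=dict)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate-selection cascade (all strict `<`)."""

    gnomad_af_max: float = 0.01
    internal_af_max: float = 0.02
    hom_count_max: int = 0  # equality required: count must be == 0
    allowed_impacts: frozenset[str] = frozenset({"HIGH", "MODERATE"})
    excluded_genes: frozenset[str] = frozenset({"KARS", "GARS"})
    cis_window_bp: int = 150
    absent_gnomad_is_rare: bool = True
    clinvar_blb_on_hom: bool = False  # extend the B/LB exclusion to homozygotes

    def __post_init__(self) -> None:
        if not 0.0 <= self.gnomad_af_max <= 1.0 or not 0.0 <= self.internal_af_max <= 1.0:
            raise ValueError("frequency thresholds must lie in [0, 1]")
        if self.cis_window_bp < 0:
            raise ValueError("cis_window_bp must be >= 0")


@dataclass(frozen=True)
class CandidateGenotype:
    """A surviving recessive genotype: homozygous variant or het pair."""

    individual_id: str
    gene: str
    kind: str  # "hom" | "comp_het"
    variants: tuple[VariantCall, ...]
    flags: frozenset[str] = frozenset()

    @property
    def variant_keys(self) -> frozenset:
        return frozenset(v.key for v in self.variants)


@dataclass(frozen=True)
class Exclusion:
    """One ledger entry: an individual (and optionally a variant) + reason."""

    individual_id: str
    variant_key: str | None
    reason: str


@dataclass(frozen=True)
class CandidateSet:
    """Filter output: candidates plus the exclusion ledger."""

    candidates: tuple[CandidateGenotype, ...]
    exclusions: tuple[Exclusion, ...]

    @property
    def candidate_individuals(self) -> frozenset[str]:
        return frozenset(c.individual_id for c in self.candidates)

    @property
    def excluded_individuals(self) -> frozenset[str]:
        return frozenset(e.individual_id for e in self.exclusions)

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "individual_id": e.individual_id,
                    "variant_key": e.variant_key or "",
                    "reason": e.reason,
                }
                for e in self.exclusions
            ],
            columns=["individual_id", "variant_key", "reason"],
        )


def _variant_failure(
    v: VariantCall, config: FilterConfig, *, check_clinvar: bool
) -> str | None:
    """First failing rule for a variant, or None if it passes.

    Rule order fixes the single primary reason recorded in the ledger.
    """
    if v.gene in config.excluded_genes:
        return "excluded_gene"
    af = v.gnomad_af
    if af is None:
        if not config.absent_gnomad_is_rare:
            return "gnomad_af_missing"
        af = 0.0
    if not af < config.gnomad_af_max:
        return "gnomad_af"
    if v.zygosity == "hom":
        hom_count = v.gnomad_hom_count
        if hom_count is None:
            hom_count = 0 if config.absent_gnomad_is_rare else None
        if hom_count is None:
            return "hom_count_missing"
        if hom_count != config.hom_count_max:
            return "hom_count"
    if not v.internal_af < config.internal_af_max:
        return "internal_af"
    if v.impact not in config.allowed_impacts:
        return "impact"
    if check_clinvar and v.clinvar_class in ("B", "LB"):
        return "clinvar_blb"
    if not v.qc_pass:
        return "qc_fail"
    return None


def _status_exclusion(rec: IndividualRecord) -> str | None:
    if not rec.affected:
        return "not_affected"
    if rec.solved:
        return "solved"
    return None


def filter_homozygous_candidates(
    cohort: Iterable[IndividualRecord], config: FilterConfig | None = None
) -> CandidateSet:
    """Homozygous branch of the cascade (see module docstring)."""
    config = config or FilterConfig()
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    candidates: list[CandidateGenotype] = []
    exclusions: list[Exclusion] = []
    for rec in cohort:
        status = _status_exclusion(rec)
        if status is not None:
            exclusions.append(Exclusion(rec.individual_id, None, status))
            continue
        homs = [v for v in rec.variants if v.zygosity == "hom"]
        survived = False
        for v in homs:
            reason = _variant_failure(v, config, check_clinvar=config.clinvar_blb_on_hom)
            if reason is None:
                candidates.append(
                    CandidateGenotype(rec.individual_id, v.gene, "hom", (v,))
                )
                survived = True
            else:
                exclusions.append(Exclusion(rec.individual_id, v.key, reason))
        if not survived and not any(
            e.individual_id == rec.individual_id for e in exclusions
        ):
            exclusions.append(
                Exclusion(rec.individual_id, None, "no_homozygous_variant")
            )
    return _prune_survivor_exclusions(candidates, exclusions)


def filter_compound_het_candidates(
    cohort: Iterable[IndividualRecord], config: FilterConfig | None = None
) -> CandidateSet:
    """Compound-heterozygous branch of the cascade (see module docstring)."""
    config = config or FilterConfig()
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    candidates: list[CandidateGenotype] = []
    exclusions: list[Exclusion] = []
    for rec in cohort:
        status = _status_exclusion(rec)
        if status is not None:
            exclusions.append(Exclusion(rec.individual_id, None, status))
            continue
        hets = [v for v in rec.variants if v.zygosity == "het"]
        if not hets:
            exclusions.append(
                Exclusion(rec.individual_id, None, "no_heterozygous_variant")
            )
            continue
        surviving: dict[str, list[VariantCall]] = {}
        for v in hets:
            reason = _variant_failure(v, config, check_clinvar=True)
            if reason is None:
                surviving.setdefault(v.gene, []).append(v)
            else:
                exclusions.append(Exclusion(rec.individual_id, v.key, reason))
        any_pair = False
        for gene in sorted(surviving):
            gene_vars = sorted(surviving[gene], key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
            if len(gene_vars) < 2:
                continue
            any_pair = True
            for i in range(len(gene_vars)):
                for j in range(i + 1, len(gene_vars)):
                    candidates.append(
                        CandidateGenotype(
                            rec.individual_id,
                            gene,
                            "comp_het",
                            (gene_vars[i], gene_vars[j]),
                        )
                    )
        if not any_pair:
            n_surviving = sum(len(vs) for vs in surviving.values())
            if n_surviving >= 1:
                exclusions.append(Exclusion(rec.individual_id, None, "single_het"))
            elif not any(e.individual_id == rec.individual_id for e in exclusions):
                exclusions.append(Exclusion(rec.individual_id, None, "single_het"))
    return _prune_survivor_exclusions(candidates, exclusions)


def _prune_survivor_exclusions(
    candidates: list[CandidateGenotype], exclusions: list[Exclusion]
) -> CandidateSet:
    """Keep the ledger a partition of non-survivors: an individual who ends
    up with a candidate genotype loses their variant-level failure rows."""
    survivors = {c.individual_id for c in candidates}
    pruned = tuple(e for e in exclusions if e.individual_id not in survivors)
    return CandidateSet(tuple(candidates), pruned)


def flag_cis_artefacts(
    candidates: CandidateSet, config: FilterConfig | None = None
) -> CandidateSet:
    """Flag het pairs within ``cis_window_bp`` for phase review.

    Variants this close are frequently called on the same read pair and may
    lie in cis; they are retained but marked ``needs_phase_review`` for
    manual alignment inspection (out of scope here).
    """
    config = config or FilterConfig()
    flagged: list[CandidateGenotype] = []
    for cand in candidates.candidates:
        if cand.kind == "comp_het":
            v1, v2 = cand.variants
            if v1.chrom == v2.chrom and abs(v1.pos - v2.pos) <= config.cis_window_bp:
                flagged.append(
                    replace(cand, flags=cand.flags | {"needs_phase_review"})
                )
                continue
        flagged.append(cand)
    return CandidateSet(tuple(flagged), candidates.exclusions)


def apply_individual_exclusions(
    candidates: CandidateSet, cohort: Iterable[IndividualRecord]
) -> CandidateSet:
    """Drop candidates without phenotype terms or with inconsistent segregation."""
    by_id = {rec.individual_id: rec for rec in cohort}
    kept: list[CandidateGenotype] = []
    exclusions = list(candidates.exclusions)
    for cand in candidates.candidates:
        rec = by_id.get(cand.individual_id)
        if rec is None or not rec.terms:
            exclusions.append(Exclusion(cand.individual_id, None, "no_hpo"))
            continue
        outcome = rec.segregation.get(cand.variant_keys, "unknown")
        if outcome == "inconsistent":
            exclusions.append(
                Exclusion(
                    cand.individual_id,
                    "|".join(sorted(cand.variant_keys)),
                    "segregation",
                )
            )
            continue
        kept.append(cand)
    # deduplicate ledger rows produced by repeated genotypes of one individual
    seen: set[tuple] = set()
    unique: list[Exclusion] = []
    for e in exclusions:
        sig = (e.individual_id, e.variant_key, e.reason)
        if sig not in seen:
            seen.add(sig)
            unique.append(e)
    return _prune_survivor_exclusions(kept, unique)


def merge_candidate_sets(*sets: CandidateSet) -> CandidateSet:
    """Union of branch outputs; ledger rows for now-candidate individuals stay
    (they document per-variant failures) but duplicates collapse."""
    candidates: list[CandidateGenotype] = []
    seen_c: set[tuple] = set()
    for s in sets:
        for c in s.candidates:
            sig = (c.individual_id, c.gene, c.kind, tuple(sorted(c.variant_keys)))
            if sig not in seen_c:
                seen_c.add(sig)
                candidates.append(c)
    exclusions: list[Exclusion] = []
    seen_e: set[tuple] = set()
    for s in sets:
        for e in s.exclusions:
            sig = (e.individual_id, e.variant_key, e.reason)
            if sig not in seen_e:
                seen_e.add(sig)
                exclusions.append(e)
    return CandidateSet(tuple(candidates), tuple(exclusions))


# -- cohort I/O --------------------------------------------------------------


def _parse_optional_float(value) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def load_cohort(
    variant_path: str | os.PathLike | TextIO,
    phenotype_path: str | os.PathLike | TextIO,
    segregation_path: str | os.PathLike | TextIO | None = None,
) -> list[IndividualRecord]:
    """Assemble IndividualRecords from the variant/phenotype/segregation TSVs.

    Variant TSV columns: individual_id, gene, chrom, pos, ref, alt, zygosity,
    gnomad_af, gnomad_hom_count, internal_af, impact, clinvar_class, qc_pass.
    Phenotype TSV: individual_id, affected, solved, hpo_terms (semicolon
    separated, may be empty).  Segregation TSV (optional): individual_id,
    variant_keys (``|``-joined), outcome.
    """
    variants = pd.read_csv(variant_path, sep="\t", dtype=str).fillna("")
    phenotypes = pd.read_csv(phenotype_path, sep="\t", dtype=str).fillna("")

    calls: dict[str, list[VariantCall]] = {}
    for row in variants.to_dict(orient="records"):
        call = VariantCall(
            individual_id=row["individual_id"],
            gene=row["gene"],
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            zygosity=row["zygosity"],
            gnomad_af=_parse_optional_float(row.get("gnomad_af", "")),
            gnomad_hom_count=(
                int(row["gnomad_hom_count"]) if str(row.get("gnomad_hom_count", "")) != "" else None
            ),
            internal_af=float(row["internal_af"]),
            impact=row["impact"],
            clinvar_class=(row.get("clinvar_class") or None),
            qc_pass=str(row.get("qc_pass", "True")).lower() in ("true", "1", "yes"),
        )
        calls.setdefault(call.individual_id, []).append(call)

    segregation: dict[str, dict[frozenset, str]] = {}
    if segregation_path is not None:
        seg = pd.read_csv(segregation_path, sep="\t", dtype=str).fillna("")
        for row in seg.to_dict(orient="records"):
            keys = frozenset(k for k in str(row["variant_keys"]).split("|") if k)
            segregation.setdefault(row["individual_id"], {})[keys] = row["outcome"]

    records: list[IndividualRecord] = []
    for row in phenotypes.to_dict(orient="records"):
        iid = row["individual_id"]
        terms = tuple(t for t in str(row.get("hpo_terms", "")).split(";") if t)
        records.append(
            IndividualRecord(
                individual_id=iid,
                affected=str(row["affected"]).lower() in ("true", "1", "yes"),
                solved=str(row["solved"]).lower() in ("true", "1", "yes"),
                terms=terms,
                variants=tuple(calls.get(iid, ())),
                segregation=segregation.get(iid, {}),
            )
        )
    return records
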