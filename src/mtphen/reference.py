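"""Curated reference database of published genotype-phenotype cases.

Each case records one published individual with a recessive diagnosis in a
mitochondrial aminoacyl-tRNA synthetase (mt-aaRS) gene: the two causal
variant descriptors with their LP/P classifications, the individual's
phenotype terms, and the source publication.  The database backs both the
similarity scoring (it is the corpus patients are compared against) and the
shared-term audit against a downloaded per-gene annotation list.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence, TextIO

import pandas as pd

from .ontology import OntologyError, OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GENES",
    "CuratedCase",
    "ReferenceDatabase",
    "SharedTermReport",
    "load_reference_db",
    "summarize_by_gene",
    "shared_term_analysis",
]

#: The ten mt-aaRS genes with LP/P variants in the discovery cohort; the
#: default configured gene set (override per study).
DEFAULT_GENES: tuple[str, ...] = (
    "AARS2",
    "CARS2",
    "DARS2",
    "EARS2",
    "IARS2",
    "LARS2",
    "NARS2",
    "RARS2",
    "VARS2",
    "WARS2",
)

_VALID_CLASSES = {"LP", "P"}

TSV_COLUMNS = [
    "case_id",
    "gene",
    "variant1_hgvs",
    "variant1_class",
    "variant2_hgvs",
    "variant2_class",
    "hpo_terms",
    "source_id",
]


@dataclass(frozen=True)
class CuratedCase:
    """One published individual with a biallelic LP/P mt-aaRS genotype."""

    case_id: str
    gene: str
    variant1_hgvs: str
    variant1_class: str
    variant2_hgvs: str
    variant2_class: str
    terms: tuple[str, ...]
    source_id: str

    def __post_init__(self) -> None:
        if self.variant1_class not in _VALID_CLASSES or self.variant2_class not in _VALID_CLASSES:
            raise ValueError(
                f"case {self.case_id!r}: variant classifications must be LP or P"
            )
        if not self.terms:
            raise ValueError(f"case {self.case_id!r} has no phenotype terms")

    @property
    def variant_pair(self) -> frozenset[str]:
        """Unordered pair of variant descriptors (a singleton for homozygotes)."""
        return frozenset((self.variant1_hgvs, self.variant2_hgvs))


class ReferenceDatabase:
    """A validated collection of curated cases with a gene index."""

    def __init__(
        self,
        cases: Iterable[CuratedCase],
        genes: Sequence[str] | None = DEFAULT_GENES,
    ) -> None:
        self.cases: list[CuratedCase] = list(cases)
        seen: set[str] = set()
        for case in self.cases:
            if case.case_id in seen:
                raise ValueError(f"duplicate case id {case.case_id!r}")
            seen.add(case.case_id)
            if genes is not None and case.gene not in genes:
                raise ValueError(
                    f"case {case.case_id!r}: gene {case.gene!r} not in configured set"
                )
        self.genes: tuple[str, ...] | None = tuple(genes) if genes is not None else None
        index: dict[str, list[str]] = {}
        for case in self.cases:
            index.setdefault(case.gene, []).append(case.case_id)
        self.gene_index: dict[str, tuple[str, ...]] = {
            g: tuple(ids) for g, ids in index.items()
        }
        self._by_id = {case.case_id: case for case in self.cases}

    def __len__(self) -> int:
        return len(self.cases)

    def __getitem__(self, case_id: str) -> CuratedCase:
        return self._by_id[case_id]

    def cases_for_gene(self, gene: str) -> list[CuratedCase]:
        return [self._by_id[cid] for cid in self.gene_index.get(gene, ())]

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | os.PathLike | TextIO) -> None:
        rows = [
            {
                "case_id": c.case_id,
                "gene": c.gene,
                "variant1_hgvs": c.variant1_hgvs,
                "variant1_class": c.variant1_class,
                "variant2_hgvs": c.variant2_hgvs,
                "variant2_class": c.variant2_class,
                "hpo_terms": ";".join(c.terms),
                "source_id": c.source_id,
            }
            for c in self.cases
        ]
        pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | os.PathLike | TextIO) -> None:
        payload = [
            {
                "case_id": c.case_id,
                "gene": c.gene,
                "variant1_hgvs": c.variant1_hgvs,
                "variant1_class": c.variant1_class,
                "variant2_hgvs": c.variant2_hgvs,
                "variant2_class": c.variant2_class,
                "hpo_terms": list(c.terms),
                "source_id": c.source_id,
            }
            for c in self.cases
        ]
        if hasattr(path, "write"):
            json.dump(payload, path, indent=1, sort_keys=True)  # type: ignore[arg-type]
        else:
            with open(path, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)


def _rows_from_source(source: str | os.PathLike | TextIO) -> list[dict]:
    """Load raw case rows from a TSV or JSON source (sniffed by content)."""
    if hasattr(source, "read"):
        text = source.read()  # type: ignore[union-attr]
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        payload = json.loads(text)
        rows = []
        for entry in payload:
            row = dict(entry)
            terms = row.get("hpo_terms", [])
            if isinstance(terms, str):
                terms = [t for t in terms.split(";") if t]
            row["hpo_terms"] = list(terms)
            rows.append(row)
        return rows
    import io

    frame = pd.read_csv(io.StringIO(text), sep="\t", dtype=str).fillna("")
    missing = [c for c in TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"reference table missing columns: {missing}")
    rows = []
    for record in frame.to_dict(orient="records"):
        record["hpo_terms"] = [t for t in str(record["hpo_terms"]).split(";") if t]
        rows.append(record)
    return rows


def load_reference_db(
    source: str | os.PathLike | TextIO,
    graph: OntologyGraph,
    genes: Sequence[str] | None = DEFAULT_GENES,
) -> ReferenceDatabase:
    """Load and validate a reference database from TSV or JSON.

    Terms are resolved against the ontology; unresolvable or obsolete terms
    are dropped with a logged count, and a case left without any usable term
    is rejected with an error naming it.
    """
    rows = _rows_from_source(source)
    cases: list[CuratedCase] = []
    n_dropped = 0
    for row in rows:
        kept: list[str] = []
        for term in row["hpo_terms"]:
            try:
                primary = graph.resolve(term)
            except OntologyError:
                n_dropped += 1
                continue
            if primary in graph.obsolete:
                n_dropped += 1
                continue
            if primary not in kept:
                kept.append(primary)
        if not kept:
            raise ValueError(
                f"case {row.get('case_id')!r}: no phenotype terms resolve in the ontology"
            )
        cases.append(
            CuratedCase(
                case_id=str(row["case_id"]),
                gene=str(row["gene"]),
                variant1_hgvs=str(row["variant1_hgvs"]),
                variant1_class=str(row["variant1_class"]),
                variant2_hgvs=str(row["variant2_hgvs"]),
                variant2_class=str(row["variant2_class"]),
                terms=tuple(kept),
                source_id=str(row["source_id"]),
            )
        )
    if n_dropped:
        logger.warning("dropped %d unresolvable reference terms", n_dropped)
    return ReferenceDatabase(cases, genes=genes)


def summarize_by_gene(db: ReferenceDatabase) -> pd.DataFrame:
    """Per-gene counts of individuals, publications and distinct variant pairs.

    Variant pairs are counted unordered (swapped allele order is the same
    pair); a totals row labelled ``TOTAL`` closes the table.
    """
    if len(db) == 0:
        raise ValueError("cannot summarise an empty reference database")
    rows = []
    for gene in sorted(db.gene_index):
        cases = db.cases_for_gene(gene)
        rows.append(
            {
                "gene": gene,
                "n_individuals": len(cases),
                "n_publications": len({c.source_id for c in cases}),
                "n_variant_pairs": len({c.variant_pair for c in cases}),
            }
        )
    frame = pd.DataFrame(rows)
    total = {
        "gene": "TOTAL",
        "n_individuals": int(frame["n_individuals"].sum()),
        "n_publications": int(frame["n_publications"].sum()),
        "n_variant_pairs": int(frame["n_variant_pairs"].sum()),
    }
    return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)


@dataclass(frozen=True)
class SharedTermReport:
    """Shared/unshared status of well-reported terms across two sources.

    ``status`` maps each qualifying term to ``shared``, ``reference_only`` or
    ``downloaded_only``; the qualification thresholds are recorded.
    """

    status: Mapping[str, str]
    ref_min: int
    dl_min: int

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.status.items()), columns=["term", "status"]
        )


def shared_term_analysis(
    db: ReferenceDatabase,
    annotation: Mapping[str, Iterable[str]],
    ref_min: int = 5,
    dl_min: int = 2,
) -> SharedTermReport:
    """Compare well-reported reference terms with a downloaded annotation set.

    A term qualifies from the reference side when it occurs in at least
    ``ref_min`` cases (each case counts once per term) and from the
    downloaded side when it annotates at least ``dl_min`` gene entries.  Both
    inputs are restricted to their common gene set first.
    """
    common_genes = set(db.gene_index) & set(annotation)
    if not common_genes:
        raise ValueError("reference database and annotation set share no genes")

    ref_counts: dict[str, int] = {}
    for gene in common_genes:
        for case in db.cases_for_gene(gene):
            for term in set(case.terms):
                ref_counts[term] = ref_counts.get(term, 0) + 1
    dl_counts: dict[str, int] = {}
    for gene in common_genes:
        for term in set(annotation[gene]):
            dl_counts[term] = dl_counts.get(term, 0) + 1

    ref_qualifying = {t for t, n in ref_counts.items() if n >= ref_min}
    dl_qualifying = {t for t, n in dl_counts.items() if n >= dl_min}
    status: dict[str, str] = {}
    for term in ref_qualifying | dl_qualifying:
        if term in ref_qualifying and term in dl_qualifying:
            status[term] = "shared"
        elif term in ref_qualifying:
            status[term] = "reference_only"
        else:
            status[term] = "downloaded_only"
    return SharedTermReport(status=status, ref_min=ref_min, dl_min=dl_min)
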