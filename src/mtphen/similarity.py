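"""Semantic similarity between phenotype term sets and the mean similarity score.

Term-level similarity follows Lin: ``2·IC(MICA) / (IC(t1) + IC(t2))`` where
MICA is the common ancestor of maximal information content (Resnik, the raw
``IC(MICA)``, is available as an alternative).  Term sets are compared with
the symmetric best-match-average (BMA): each term's best cross-set match is
averaged, in both directions, and the two directional means averaged.

A patient's *mean phenotype similarity score* against a reference cohort of
published cases is the mean BMA similarity to all reference cases of the
candidate gene (gene-matched mode); when no candidate gene is present in the
reference, the mean over the ``k`` most similar reference cases is used
instead (top-k fallback, default k=5).  A query that is itself a reference
case is excluded from its own pool (leave-one-out).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

from .ontology import ICTable, OntologyError, OntologyGraph

if TYPE_CHECKING:  # pragma: no cover
    from .reference import ReferenceDatabase

__all__ = [
    "SimilarityConfig",
    "PhenotypeScore",
    "term_similarity",
    "set_similarity",
    "mean_phenotype_similarity",
    "average_ic",
    "SimilarityEngine",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Tunable knobs of the similarity score.

    ``pp4_supporting_min`` / ``pp4_moderate_min`` are referenced by the ACMG
    layer when converting scores into PP4 evidence (0.3 / 0.4 by default).
    """

    measure: str = "lin"  # "lin" | "resnik"
    combiner: str = "symmetric_bma"  # "symmetric_bma" | "asymmetric_bma"
    fallback_k: int = 5
    pp4_supporting_min: float = 0.3
    pp4_moderate_min: float = 0.4

    def __post_init__(self) -> None:
        if self.measure not in ("lin", "resnik"):
            raise ValueError(f"unknown term measure {self.measure!r}")
        if self.combiner not in ("symmetric_bma", "asymmetric_bma"):
            raise ValueError(f"unknown set combiner {self.combiner!r}")
        if self.fallback_k < 1:
            raise ValueError("fallback_k must be >= 1")
        if not 0.0 <= self.pp4_supporting_min <= self.pp4_moderate_min <= 1.0:
            raise ValueError("PP4 thresholds must satisfy 0 <= supporting <= moderate <= 1")


@dataclass(frozen=True)
class PhenotypeScore:
    """A mean phenotype similarity score with its provenance."""

    value: float
    mode: str  # "gene_matched" | "top_k_fallback"
    n_reference_cases_used: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"score {self.value} outside [0, 1]")
        if self.n_reference_cases_used < 1:
            raise ValueError("a score must rest on at least one reference case")


def _mica_ic(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:
        return 0.0
    return max(ic[t] for t in common)


def term_similarity(
    graph: OntologyGraph,
    ic: ICTable,
    t1: str,
    t2: str,
    measure: str = "lin",
) -> float:
    """Lin or Resnik similarity between two terms."""
    a = graph.resolve(t1)
    b = graph.resolve(t2)
    mica = _mica_ic(graph, ic, a, b)
    if measure == "resnik":
        return mica
    if measure != "lin":
        raise ValueError(f"unknown term measure {measure!r}")
    denom = ic[a] + ic[b]
    if denom == 0.0:
        return 1.0 if a == b else 0.0
    return 2.0 * mica / denom


def set_similarity(
    graph: OntologyGraph,
    ic: ICTable,
    set_a: Iterable[str],
    set_b: Iterable[str],
    config: SimilarityConfig | None = None,
) -> float:
    """Best-match-average similarity between two non-empty term sets."""
    config = config or SimilarityConfig()
    a_terms = sorted({graph.resolve(t) for t in set_a})
    b_terms = sorted({graph.resolve(t) for t in set_b})
    if not a_terms or not b_terms:
        raise OntologyError("set_similarity requires two non-empty term sets")
    matrix = np.array(
        [
            [term_similarity(graph, ic, a, b, config.measure) for b in b_terms]
            for a in a_terms
        ]
    )
    forward = matrix.max(axis=1).mean()
    if config.combiner == "asymmetric_bma":
        return float(forward)
    backward = matrix.max(axis=0).mean()
    return float(0.5 * (forward + backward))


def mean_phenotype_similarity(
    query_terms: Iterable[str],
    candidate_gene: str | None,
    reference: "ReferenceDatabase",
    graph: OntologyGraph,
    ic: ICTable,
    config: SimilarityConfig | None = None,
    exclude_case_id: str | None = None,
) -> PhenotypeScore:
    """Mean similarity of a query patient to the reference cohort.

    Gene-matched mode averages over every reference case of
    ``candidate_gene``; without a gene match the ``fallback_k`` most similar
    cases across the whole reference are averaged (ties at the k-th value
    resolved by case id for determinism).  ``exclude_case_id`` implements
    leave-one-out when the query is itself a reference member; if the
    excluded case was its gene's only representative the score falls back to
    top-k mode.
    """
    config = config or SimilarityConfig()
    query = list(query_terms)
    if not query:
        raise OntologyError("query has no phenotype terms")
    if len(reference) == 0:
        raise OntologyError("reference database is empty")

    def _sims(cases) -> list[tuple[float, str]]:
        return [
            (set_similarity(graph, ic, query, case.terms, config), case.case_id)
            for case in cases
            if case.case_id != exclude_case_id
        ]

    if candidate_gene is not None and candidate_gene in reference.gene_index:
        pool = _sims(reference.cases_for_gene(candidate_gene))
        if pool:
            value = float(np.mean([v for v, _ in pool]))
            return PhenotypeScore(value, "gene_matched", len(pool))
        # leave-one-out removed the gene's only case: fall through to top-k

    pool = _sims(reference.cases)
    if not pool:
        raise OntologyError("no reference cases available after self-exclusion")
    pool.sort(key=lambda pair: (-pair[0], pair[1]))
    top = pool[: config.fallback_k]
    value = float(np.mean([v for v, _ in top]))
    return PhenotypeScore(value, "top_k_fallback", len(top))


def average_ic(query_terms: Iterable[str], ic: ICTable) -> float:
    """Arithmetic mean IC over the distinct terms of a query."""
    terms = set(query_terms)
    if not terms:
        raise OntologyError("average_ic of an empty term set")
    missing = [t for t in terms if t not in ic]
    if missing:
        raise OntologyError(f"terms absent from IC table: {sorted(missing)!r}")
    return float(np.mean([ic[t] for t in terms]))


class SimilarityEngine:
    """Vectorised batch scorer over a fixed term universe.

    Precomputes the full term-by-term Lin (or Resnik) matrix once so that
    cohort-scale scoring (hundreds of queries against hundreds of reference
    cases) avoids repeated MICA searches.  Produces values identical to the
    scalar functions above; memory is O(T²) in the universe size, so pass
    only the terms actually in play for very large ontologies.
    """

    def __init__(
        self,
        graph: OntologyGraph,
        ic: ICTable,
        config: SimilarityConfig | None = None,
        universe: Sequence[str] | None = None,
    ) -> None:
        self.graph = graph
        self.ic = ic
        self.config = config or SimilarityConfig()
        if universe is None:
            terms = sorted(graph.active_terms)
        else:
            terms = sorted({graph.resolve(t) for t in universe})
        self._index: dict[str, int] = {t: i for i, t in enumerate(terms)}
        self._terms = terms

        n = len(terms)
        anc_universe = sorted({a for t in terms for a in graph.ancestors(t)})
        anc_idx = {t: i for i, t in enumerate(anc_universe)}
        anc = np.zeros((n, len(anc_universe)), dtype=bool)
        for i, t in enumerate(terms):
            for a in graph.ancestors(t):
                anc[i, anc_idx[a]] = True
        ic_vec_universe = np.array([ic[t] for t in anc_universe])
        ic_vec = np.array([ic[t] for t in terms])

        mica = np.zeros((n, n))
        for i in range(n):
            shared = anc & anc[i]
            masked = np.where(shared, ic_vec_universe, -np.inf)
            row = masked.max(axis=1)
            row[~shared.any(axis=1)] = 0.0
            mica[i] = row
        if self.config.measure == "resnik":
            self._matrix = mica
        else:
            denom = ic_vec[:, None] + ic_vec[None, :]
            lin = np.where(denom > 0, 2.0 * mica / np.where(denom > 0, denom, 1.0), 0.0)
            # zero-IC pairs: identical terms compare as 1, distinct ones as 0
            np.fill_diagonal(lin, 1.0)
            self._matrix = lin

    def indices(self, terms: Iterable[str]) -> np.ndarray:
        return np.array(
            sorted({self._index[self.graph.resolve(t)] for t in terms}), dtype=int
        )

    def set_similarity(self, set_a: Iterable[str], set_b: Iterable[str]) -> float:
        ia = self.indices(set_a)
        ib = self.indices(set_b)
        if ia.size == 0 or ib.size == 0:
            raise OntologyError("set_similarity requires two non-empty term sets")
        sub = self._matrix[np.ix_(ia, ib)]
        forward = sub.max(axis=1).mean()
        if self.config.combiner == "asymmetric_bma":
            return float(forward)
        return float(0.5 * (forward + sub.max(axis=0).mean()))

    def mean_phenotype_similarity(
        self,
        query_terms: Iterable[str],
        candidate_gene: str | None,
        reference: "ReferenceDatabase",
        exclude_case_id: str | None = None,
    ) -> PhenotypeScore:
        query_idx = self.indices(query_terms)
        if query_idx.size == 0:
            raise OntologyError("query has no phenotype terms")
        if len(reference) == 0:
            raise OntologyError("reference database is empty")

        def _sims(cases) -> list[tuple[float, str]]:
            out = []
            for case in cases:
                if case.case_id == exclude_case_id:
                    continue
                ib = self.indices(case.terms)
                sub = self._matrix[np.ix_(query_idx, ib)]
                forward = sub.max(axis=1).mean()
                if self.config.combiner == "asymmetric_bma":
                    val = forward
                else:
                    val = 0.5 * (forward + sub.max(axis=0).mean())
                out.append((float(val), case.case_id))
            return out

        if candidate_gene is not None and candidate_gene in reference.gene_index:
            pool = _sims(reference.cases_for_gene(candidate_gene))
            if pool:
                return PhenotypeScore(
                    float(np.mean([v for v, _ in pool])), "gene_matched", len(pool)
                )
        pool = _sims(reference.cases)
        if not pool:
            raise OntologyError("no reference cases available after self-exclusion")
        pool.sort(key=lambda pair: (-pair[0], pair[1]))
        top = pool[: self.config.fallback_k]
        return PhenotypeScore(
            float(np.mean([v for v, _ in top])), "top_k_fallback", len(top)
        )
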