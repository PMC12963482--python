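"""Ontology handling: OBO parsing, ancestor closure and information content.

The phenotype vocabulary used throughout this package is an HPO-like
directed acyclic graph of terms linked by ``is_a`` edges.  Semantic
similarity between patients rests on two primitives provided here:

* the reflexive transitive ancestor closure of a term, and
* per-term information content (IC), either estimated from an annotation
  corpus (``IC(t) = -log p(t)`` with ``p(t) = n(t)/N`` after propagating
  each record's terms to all ancestors) or from ontology structure alone
  (``IC(t) = -log(|descendants(t)| / |terms|)``).

Only ``is_a`` edges are honoured; HPO's phenotypic-abnormality hierarchy is
``is_a``-structured and other relation types carry no similarity semantics
here.  IC is reported in nats by default; the log base is configurable.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyError",
    "OntologyGraph",
    "AnnotationCorpus",
    "ICTable",
    "parse_obo",
    "write_obo",
    "ancestors",
    "information_content",
    "load_gene_annotation_set",
]


class OntologyError(ValueError):
    """Raised for structural problems in an ontology or its annotations."""


class OntologyGraph:
    """An ``is_a`` DAG of terms with alt-id resolution and closure caching.

    Parameters
    ----------
    parents
        Mapping term -> iterable of direct ``is_a`` parents.  Every term of
        the ontology must appear as a key (roots map to an empty set).
    labels
        Optional term -> human-readable name.
    alt_ids
        Optional alternative id -> primary id mapping.
    obsolete
        Terms marked obsolete; kept for id resolution but excluded from the
        active term set used for IC and similarity.
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        labels: Mapping[str, str] | None = None,
        alt_ids: Mapping[str, str] | None = None,
        obsolete: Iterable[str] | None = None,
    ) -> None:
        self._parents: dict[str, frozenset[str]] = {
            t: frozenset(ps) for t, ps in parents.items()
        }
        self.labels: dict[str, str] = dict(labels or {})
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.obsolete: frozenset[str] = frozenset(obsolete or ())

        terms = set(self._parents)
        for t, ps in self._parents.items():
            for p in ps:
                if p not in terms:
                    raise OntologyError(
                        f"term {t!r} references undeclared parent {p!r}"
                    )
        for alt, primary in self.alt_ids.items():
            if primary not in terms:
                raise OntologyError(
                    f"alt_id {alt!r} maps to unknown term {primary!r}"
                )

        dag = nx.DiGraph((t, p) for t, ps in self._parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise OntologyError(
                f"is_a cycle detected involving term {cycle[0][0]!r}"
            )

        self._children: dict[str, set[str]] = {t: set() for t in terms}
        for t, ps in self._parents.items():
            for p in ps:
                self._children[p].add(t)

        roots = frozenset(t for t, ps in self._parents.items() if not ps)
        if not roots:
            raise OntologyError("ontology has no root term")
        self._roots = roots
        self._anc_cache: dict[str, frozenset[str]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._parents)

    @property
    def active_terms(self) -> frozenset[str]:
        return frozenset(t for t in self._parents if t not in self.obsolete)

    @property
    def roots(self) -> frozenset[str]:
        return self._roots

    def parents(self, term: str) -> frozenset[str]:
        return self._parents[self.resolve(term)]

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._children[self.resolve(term)])

    def __contains__(self, term: str) -> bool:
        return term in self._parents or term in self.alt_ids

    def __len__(self) -> int:
        return len(self._parents)

    def resolve(self, term: str) -> str:
        """Map an id (primary or alternative) to its primary id."""
        if term in self._parents:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise OntologyError(f"unknown term {term!r}")

    # -- closures ----------------------------------------------------------

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive transitive ``is_a`` closure of *term*."""
        t = self.resolve(term)
        cached = self._anc_cache.get(t)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = [t]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self._parents[cur])
        result = frozenset(out)
        self._anc_cache[t] = result
        return result

    def descendants(self, term: str) -> frozenset[str]:
        """Reflexive transitive closure over child edges."""
        t = self.resolve(term)
        out: set[str] = set()
        stack = [t]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self._children[cur])
        return frozenset(out)


def _as_handle(source: str | os.PathLike | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    text = str(source)
    if "\n" in text or text.lstrip().startswith("format-version"):
        return io.StringIO(text)
    return open(text, "r", encoding="utf-8")


def parse_obo(source: str | os.PathLike | TextIO) -> OntologyGraph:
    """Parse OBO text (path, handle or literal string) into an OntologyGraph.

    Honours ``id``, ``name``, ``is_a``, ``alt_id`` and ``is_obsolete``; all
    other stanza tags are ignored.  Rejects cyclic graphs and references to
    undeclared parents.
    """
    handle = _as_handle(source)
    multigraph = obonet.read_obo(handle, ignore_obsolete=False)

    parents: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    alt_ids: dict[str, str] = {}
    obsolete: set[str] = set()

    declared = {n for n, data in multigraph.nodes(data=True) if data}
    for node, data in multigraph.nodes(data=True):
        if not data:
            # node created only because somebody's is_a points at it
            child = next(iter(multigraph.predecessors(node)), "?")
            raise OntologyError(
                f"term {child!r} references undeclared parent {node!r}"
            )
        parents.setdefault(node, set())
        if "name" in data:
            labels[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)

    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in declared:
            raise OntologyError(
                f"term {child!r} references undeclared parent {parent!r}"
            )
        parents[child].add(parent)

    return OntologyGraph(parents, labels=labels, alt_ids=alt_ids, obsolete=obsolete)


def write_obo(graph: OntologyGraph, path_or_handle: str | os.PathLike | TextIO) -> None:
    """Serialise a graph back to the OBO subset ``parse_obo`` reads."""
    own = False
    if hasattr(path_or_handle, "write"):
        fh = path_or_handle  # type: ignore[assignment]
    else:
        fh = open(path_or_handle, "w", encoding="utf-8")
        own = True
    try:
        fh.write("format-version: 1.2\nontology: mtphen-synthetic\n")
        back_alts: dict[str, list[str]] = {}
        for alt, primary in graph.alt_ids.items():
            back_alts.setdefault(primary, []).append(alt)
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\n")
            fh.write(f"name: {graph.labels.get(term, term)}\n")
            for alt in sorted(back_alts.get(term, [])):
                fh.write(f"alt_id: {alt}\n")
            for parent in sorted(graph.parents(term)):
                fh.write(f"is_a: {parent}\n")
            if term in graph.obsolete:
                fh.write("is_obsolete: true\n")
    finally:
        if own:
            fh.close()


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term)


class AnnotationCorpus:
    """Record-id -> term-set annotations, normalised against an ontology.

    Alternative ids are resolved to primary ids; obsolete terms are dropped
    with a warning (real HPO releases churn ids).  A record left with no
    terms after normalisation is an error, as is a term absent from the
    ontology altogether.
    """

    def __init__(self, records: Mapping[str, Iterable[str]], graph: OntologyGraph) -> None:
        if not records:
            raise OntologyError("annotation corpus is empty")
        norm: dict[str, frozenset[str]] = {}
        n_obsolete = 0
        for rid, raw_terms in records.items():
            kept: set[str] = set()
            for t in raw_terms:
                primary = graph.resolve(t)
                if primary in graph.obsolete:
                    n_obsolete += 1
                    continue
                kept.add(primary)
            if not kept:
                raise OntologyError(f"record {rid!r} has no usable terms")
            norm[rid] = frozenset(kept)
        if n_obsolete:
            logger.warning("dropped %d obsolete term annotations", n_obsolete)
        self.records: dict[str, frozenset[str]] = norm

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class ICTable:
    """Per-term information content with the estimation method recorded."""

    ic: Mapping[str, float]
    method: str  # "corpus" | "structure"
    log_base: float | None = None  # None -> natural log (nats)

    def __getitem__(self, term: str) -> float:
        return self.ic[term]

    def __contains__(self, term: str) -> bool:
        return term in self.ic


def information_content(
    graph: OntologyGraph,
    corpus: AnnotationCorpus | None = None,
    *,
    log_base: float | None = None,
) -> ICTable:
    """Estimate IC for every active term of *graph*.

    With a corpus, each record's terms are propagated to all ancestors and
    ``IC(t) = -log(n(t)/N)``; terms never observed receive the smoothed
    probability ``1/(N+1)`` so queries carrying reference-absent terms stay
    finite.  Without a corpus the structural surrogate
    ``IC(t) = -log(|reflexive descendants| / |active terms|)`` is used.
    """

    def _log(x: float) -> float:
        if log_base is None:
            return math.log(x)
        return math.log(x) / math.log(log_base)

    active = graph.active_terms
    ic: dict[str, float] = {}
    if corpus is not None:
        n = len(corpus)
        counts: dict[str, int] = {}
        for terms in corpus.records.values():
            propagated: set[str] = set()
            for t in terms:
                propagated |= graph.ancestors(t)
            for t in propagated:
                counts[t] = counts.get(t, 0) + 1
        for t in active:
            c = counts.get(t, 0)
            p = c / n if c > 0 else 1.0 / (n + 1)
            ic[t] = -_log(p)
        method = "corpus"
    else:
        n_active = len(active)
        for t in active:
            n_desc = len(graph.descendants(t) & active)
            ic[t] = -_log(n_desc / n_active)
        method = "structure"
    # guard against -0.0 from floating log
    ic = {t: (0.0 if v == 0 else v) for t, v in ic.items()}
    return ICTable(ic=ic, method=method, log_base=log_base)


def load_gene_annotation_set(
    source: str | os.PathLike | TextIO, graph: OntologyGraph
) -> dict[str, frozenset[str]]:
    """Read a two-column gene/term TSV into per-gene term sets.

    Lines starting with ``#`` are skipped; duplicate (gene, term) rows are
    collapsed; terms that do not resolve in the ontology are dropped with a
    logged count.  Malformed rows and an effectively empty file are errors.
    """
    handle = _as_handle(source)
    out: dict[str, set[str]] = {}
    n_dropped = 0
    n_rows = 0
    for lineno, line in enumerate(handle, start=1):
        stripped = line.rstrip("\n")
        if not stripped.strip() or stripped.lstrip().startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise OntologyError(
                f"malformed gene-annotation row at line {lineno}: {stripped!r}"
            )
        gene, term = fields[0].strip(), fields[1].strip()
        n_rows += 1
        try:
            primary = graph.resolve(term)
        except OntologyError:
            n_dropped += 1
            continue
        if primary in graph.obsolete:
            n_dropped += 1
            continue
        out.setdefault(gene, set()).add(primary)
    if n_rows == 0:
        raise OntologyError("gene-annotation file contains no data rows")
    if n_dropped:
        logger.warning("dropped %d unresolvable gene-annotation terms", n_dropped)
    out = {g: ts for g, ts in out.items() if ts}
    if not out:
        raise OntologyError("no gene annotations survived term resolution")
    return {g: frozenset(ts) for g, ts in out.items()}
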