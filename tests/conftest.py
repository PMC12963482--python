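"""Shared fixtures: tiny hand-built ontologies and random-structure helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mtphen.ontology import AnnotationCorpus, OntologyGraph, information_content, parse_obo

DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: root

[Term]
id: HP:0000002
name: left
is_a: HP:0000001

[Term]
id: HP:0000003
name: right
is_a: HP:0000001

[Term]
id: HP:0000004
name: bottom
is_a: HP:0000002
is_a: HP:0000003

[Term]
id: HP:0000005
name: leaf under left
alt_id: HP:0000105
is_a: HP:0000002
"""


@pytest.fixture
def diamond_graph() -> OntologyGraph:
    return parse_obo(DIAMOND_OBO)


@pytest.fixture
def diamond_corpus(diamond_graph) -> AnnotationCorpus:
    # 8 records; HP:0000004 occurs in 2 of 8 -> IC = ln 4 after propagation
    records = {
        "r1": {"HP:0000004"},
        "r2": {"HP:0000004"},
        "r3": {"HP:0000002"},
        "r4": {"HP:0000002"},
        "r5": {"HP:0000003"},
        "r6": {"HP:0000005"},
        "r7": {"HP:0000005"},
        "r8": {"HP:0000001"},
    }
    return AnnotationCorpus(records, diamond_graph)


@pytest.fixture
def diamond_ic(diamond_graph, diamond_corpus):
    return information_content(diamond_graph, diamond_corpus)


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyGraph:
    """Random rooted DAG with edges pointing to strictly earlier terms."""
    terms = [f"T:{i:03d}" for i in range(n_terms)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    for i in range(1, n_terms):
        k = 2 if (i > 1 and rng.random() < 0.3) else 1
        idx = rng.choice(i, size=min(k, i), replace=False)
        parents[terms[i]] = {terms[int(j)] for j in np.atleast_1d(idx)}
    return OntologyGraph(parents)


def random_corpus(
    rng: np.random.Generator, graph: OntologyGraph, n_records: int
) -> AnnotationCorpus:
    terms = sorted(graph.terms)
    records = {}
    for r in range(n_records):
        size = int(rng.integers(1, min(4, len(terms)) + 1))
        idx = rng.choice(len(terms), size=size, replace=False)
        records[f"rec{r}"] = {terms[int(i)] for i in np.atleast_1d(idx)}
    return AnnotationCorpus(records, graph)


def brute_ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Exhaustive recursive DFS closure, independent of the cached walker."""
    out = {term}
    for parent in graph.parents(term):
        out |= brute_ancestors(graph, parent)
    return frozenset(out)
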