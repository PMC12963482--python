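"""Lin/BMA similarity and the mean phenotype similarity score."""

import itertools
import math

import numpy as np
import pytest

from mtphen.ontology import AnnotationCorpus, information_content
from mtphen.reference import CuratedCase, ReferenceDatabase
from mtphen.similarity import (
    OntologyError,
    PhenotypeScore,
    SimilarityConfig,
    SimilarityEngine,
    average_ic,
    mean_phenotype_similarity,
    set_similarity,
    term_similarity,
)

from conftest import brute_ancestors, random_corpus, random_dag


def brute_term_similarity(graph, ic, t1, t2):
    common = brute_ancestors(graph, t1) & brute_ancestors(graph, t2)
    mica = max((ic[t] for t in common), default=0.0)
    denom = ic[t1] + ic[t2]
    if denom == 0:
        return 1.0 if t1 == t2 else 0.0
    return 2.0 * mica / denom


def brute_bma(graph, ic, set_a, set_b):
    a, b = sorted(set_a), sorted(set_b)
    matrix = [[brute_term_similarity(graph, ic, x, y) for y in b] for x in a]
    forward = sum(max(row) for row in matrix) / len(a)
    backward = sum(max(matrix[i][j] for i in range(len(a))) for j in range(len(b))) / len(b)
    return 0.5 * (forward + backward)


def make_case(case_id, gene, terms, source="PMID:1"):
    return CuratedCase(case_id, gene, "c.1A>G", "P", "c.2C>T", "LP", tuple(terms), source)


class TestTermSimilarity:
    def test_identical_term_with_positive_ic(self, diamond_graph, diamond_ic):
        assert term_similarity(diamond_graph, diamond_ic, "HP:0000004", "HP:0000004") == 1.0

    def test_siblings_under_zero_ic_root(self, diamond_graph):
        corpus = AnnotationCorpus(
            {"r1": {"HP:0000002"}, "r2": {"HP:0000003"}}, diamond_graph
        )
        ic = information_content(diamond_graph, corpus)
        assert ic["HP:0000001"] == 0.0
        assert term_similarity(diamond_graph, ic, "HP:0000002", "HP:0000003") == 0.0

    def test_diamond_hand_value(self, diamond_graph, diamond_ic):
        # MICA of bottom (HP4) and leaf (HP5) is 'left' (HP2)
        expected = (
            2 * diamond_ic["HP:0000002"]
            / (diamond_ic["HP:0000004"] + diamond_ic["HP:0000005"])
        )
        got = term_similarity(diamond_graph, diamond_ic, "HP:0000004", "HP:0000005")
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(
            brute_term_similarity(diamond_graph, diamond_ic, "HP:0000004", "HP:0000005")
        )

    def test_resnik_is_mica_ic(self, diamond_graph, diamond_ic):
        got = term_similarity(
            diamond_graph, diamond_ic, "HP:0000004", "HP:0000005", measure="resnik"
        )
        assert got == pytest.approx(diamond_ic["HP:0000002"])

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pairs_match_brute_force(self, seed):
        rng = np.random.default_rng(400 + seed)
        graph = random_dag(rng, 14)
        ic = information_content(graph, random_corpus(rng, graph, 8))
        terms = sorted(graph.terms)
        for _ in range(20):
            t1, t2 = (terms[int(i)] for i in rng.integers(len(terms), size=2))
            assert term_similarity(graph, ic, t1, t2) == pytest.approx(
                brute_term_similarity(graph, ic, t1, t2), abs=1e-12
            )


class TestSetSimilarity:
    def test_identical_sets_score_one(self, diamond_graph, diamond_ic):
        terms = {"HP:0000004", "HP:0000005"}
        assert set_similarity(diamond_graph, diamond_ic, terms, terms) == pytest.approx(1.0)

    def test_singletons_reduce_to_term_similarity(self, diamond_graph, diamond_ic):
        got = set_similarity(diamond_graph, diamond_ic, {"HP:0000004"}, {"HP:0000005"})
        assert got == pytest.approx(
            term_similarity(diamond_graph, diamond_ic, "HP:0000004", "HP:0000005")
        )

    def test_two_by_three_matches_brute_force(self, diamond_graph, diamond_ic):
        a = {"HP:0000004", "HP:0000005"}
        b = {"HP:0000002", "HP:0000003", "HP:0000001"}
        assert set_similarity(diamond_graph, diamond_ic, a, b) == pytest.approx(
            brute_bma(diamond_graph, diamond_ic, a, b), abs=1e-12
        )

    def test_empty_set_rejected(self, diamond_graph, diamond_ic):
        with pytest.raises(OntologyError):
            set_similarity(diamond_graph, diamond_ic, set(), {"HP:0000004"})

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_range_on_random_instances(self, seed):
        rng = np.random.default_rng(500 + seed)
        graph = random_dag(rng, 15)
        ic = information_content(graph, random_corpus(rng, graph, 8))
        terms = sorted(graph.terms)
        pick = lambda k: {terms[int(i)] for i in rng.choice(len(terms), k, replace=False)}
        a, b = pick(int(rng.integers(1, 5))), pick(int(rng.integers(1, 5)))
        ab = set_similarity(graph, ic, a, b)
        ba = set_similarity(graph, ic, b, a)
        assert ab == pytest.approx(ba, abs=1e-12)
        assert 0.0 <= ab <= 1.0

    def test_adding_matching_term_never_decreases(self, diamond_graph, diamond_ic):
        a = {"HP:0000004", "HP:0000005"}
        b = {"HP:0000002"}
        before = set_similarity(diamond_graph, diamond_ic, a, b)
        after = set_similarity(diamond_graph, diamond_ic, a, b | {"HP:0000004"})
        assert after >= before - 1e-12

    def test_engine_matches_scalar_path(self, diamond_graph, diamond_ic):
        engine = SimilarityEngine(diamond_graph, diamond_ic)
        rng = np.random.default_rng(0)
        terms = sorted(diamond_graph.active_terms)
        for _ in range(20):
            a = {terms[int(i)] for i in rng.choice(len(terms), 2, replace=False)}
            b = {terms[int(i)] for i in rng.choice(len(terms), 3, replace=False)}
            assert engine.set_similarity(a, b) == pytest.approx(
                set_similarity(diamond_graph, diamond_ic, a, b), abs=1e-12
            )


class TestMeanPhenotypeSimilarity:
    @pytest.fixture
    def reference(self, diamond_graph):
        cases = [
            make_case("c1", "DARS2", ("HP:0000004", "HP:0000005")),
            make_case("c2", "DARS2", ("HP:0000004", "HP:0000005")),
            make_case("c3", "DARS2", ("HP:0000004", "HP:0000005")),
            make_case("c4", "EARS2", ("HP:0000003",)),
            make_case("c5", "EARS2", ("HP:0000002",)),
        ]
        return ReferenceDatabase(cases)

    def test_identical_query_gene_matched(self, diamond_graph, diamond_ic, reference):
        score = mean_phenotype_similarity(
            {"HP:0000004", "HP:0000005"}, "DARS2", reference, diamond_graph, diamond_ic
        )
        assert score.value == pytest.approx(1.0)
        assert score.mode == "gene_matched"
        assert score.n_reference_cases_used == 3

    def test_fallback_uses_all_when_fewer_than_k(
        self, diamond_graph, diamond_ic, reference
    ):
        score = mean_phenotype_similarity(
            {"HP:0000004"}, "WARS2", reference, diamond_graph, diamond_ic,
            SimilarityConfig(fallback_k=10),
        )
        assert score.mode == "top_k_fallback"
        assert score.n_reference_cases_used == 5

    def test_top_k_mean_matches_sorted_oracle(self, diamond_graph, diamond_ic):
        terms_pool = ["HP:0000002", "HP:0000003", "HP:0000004", "HP:0000005"]
        cases = [
            make_case(f"c{i}", "DARS2", (terms_pool[i % 4], terms_pool[(i + 1) % 4]))
            for i in range(8)
        ]
        reference = ReferenceDatabase(cases)
        query = {"HP:0000004", "HP:0000002"}
        sims = sorted(
            (
                set_similarity(diamond_graph, diamond_ic, query, c.terms)
                for c in cases
            ),
            reverse=True,
        )
        expected = float(np.mean(sims[:5]))
        score = mean_phenotype_similarity(
            query, None, reference, diamond_graph, diamond_ic
        )
        assert score.value == pytest.approx(expected, abs=1e-12)
        assert score.mode == "top_k_fallback"
        assert score.n_reference_cases_used == 5

    def test_leave_one_out_excludes_self(self, diamond_graph, diamond_ic, reference):
        score = mean_phenotype_similarity(
            {"HP:0000004", "HP:0000005"}, "DARS2", reference, diamond_graph,
            diamond_ic, exclude_case_id="c1",
        )
        assert score.n_reference_cases_used == 2

    def test_gene_matched_equals_fallback_when_gene_cases_are_top_k(
        self, diamond_graph, diamond_ic
    ):
        # DARS2 cases match the query perfectly and are exactly the k best
        cases = [
            make_case("d1", "DARS2", ("HP:0000004",)),
            make_case("d2", "DARS2", ("HP:0000004",)),
            make_case("e1", "EARS2", ("HP:0000003",)),
            make_case("e2", "EARS2", ("HP:0000003",)),
        ]
        reference = ReferenceDatabase(cases)
        config = SimilarityConfig(fallback_k=2)
        query = {"HP:0000004"}
        matched = mean_phenotype_similarity(
            query, "DARS2", reference, diamond_graph, diamond_ic, config
        )
        fallback = mean_phenotype_similarity(
            query, None, reference, diamond_graph, diamond_ic, config
        )
        assert matched.value == pytest.approx(fallback.value)

    def test_empty_query_rejected(self, diamond_graph, diamond_ic, reference):
        with pytest.raises(OntologyError):
            mean_phenotype_similarity(
                set(), "DARS2", reference, diamond_graph, diamond_ic
            )

    def test_engine_agrees_with_scalar_scoring(self, diamond_graph, diamond_ic, reference):
        engine = SimilarityEngine(diamond_graph, diamond_ic)
        for gene in ("DARS2", None):
            fast = engine.mean_phenotype_similarity(
                {"HP:0000004", "HP:0000002"}, gene, reference
            )
            slow = mean_phenotype_similarity(
                {"HP:0000004", "HP:0000002"}, gene, reference, diamond_graph, diamond_ic
            )
            assert fast.value == pytest.approx(slow.value, abs=1e-12)
            assert fast.mode == slow.mode


class TestAverageIC:
    def test_single_and_pair(self, diamond_graph, diamond_ic):
        table = diamond_ic
        assert average_ic({"HP:0000004"}, table) == pytest.approx(table["HP:0000004"])
        got = average_ic({"HP:0000001", "HP:0000004"}, table)
        assert got == pytest.approx((table["HP:0000001"] + table["HP:0000004"]) / 2)

    def test_duplicates_collapsed_and_random_mean(self, diamond_graph, diamond_ic):
        terms = ["HP:0000004", "HP:0000004", "HP:0000005", "HP:0000002"]
        expected = np.mean([diamond_ic[t] for t in set(terms)])
        assert average_ic(terms, diamond_ic) == pytest.approx(expected)

    def test_empty_rejected(self, diamond_ic):
        with pytest.raises(OntologyError):
            average_ic(set(), diamond_ic)


class TestScoreInvariants:
    def test_phenotype_score_validation(self):
        with pytest.raises(ValueError):
            PhenotypeScore(1.2, "gene_matched", 3)
        with pytest.raises(ValueError):
            PhenotypeScore(0.5, "gene_matched", 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimilarityConfig(fallback_k=0)
        with pytest.raises(ValueError):
            SimilarityConfig(pp4_supporting_min=0.5, pp4_moderate_min=0.4)
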