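"""Search scoring, filtering and tie-aware ranking."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdmap.annotations import KnowledgeBase
from rdmap.errors import ValidationError
from rdmap.search import (
    NOT_RETRIEVED,
    Query,
    SearchHit,
    rank_of_target,
    score_one_way,
    score_similarity_avg,
    search,
)

from conftest import disease


@pytest.fixture()
def toy_kb(toy_dag):
    diseases = {
        "ORPHA:1": disease("ORPHA:1", ("A1", 1.0), ("A2", 1.0)),
        "ORPHA:2": disease("ORPHA:2", ("B1", 1.0), ("B2", 1.0)),
        "ORPHA:3": disease("ORPHA:3", ("A1", 1.0), ("B1", 1.0)),
    }
    return KnowledgeBase(
        diseases=diseases, genes={},
        phenotype_dag=toy_dag, go_cc_dag=toy_dag, go_mf_dag=toy_dag,
        go_bp_dag=toy_dag,
    )


class TestScoreOneWay:
    def test_query_equals_annotation_scores_zero(self, toy_dag):
        d = disease("D", ("A1", 1.0), ("A2", 1.0))
        assert score_one_way(toy_dag, ["A1", "A2"], d) == 0.0

    def test_single_term_toy_value(self, toy_dag):
        d = disease("D", ("A2", 1.0))
        assert score_one_way(toy_dag, ["A1"], d) == pytest.approx(0.4)

    def test_weight_scales_match(self, toy_dag):
        d = disease("D", ("A2", 0.5))
        assert score_one_way(toy_dag, ["A1"], d) == pytest.approx(0.4 * 0.5)
        assert score_one_way(toy_dag, ["A1"], d, use_weights=False) == pytest.approx(0.4)

    def test_subset_query_is_zero_but_two_way_is_not(self, toy_dag):
        """The asymmetry that motivates the one-way default: a partial query
        scores 0 one-way, while the symmetric score penalizes the disease's
        unmatched annotation."""
        d = disease("D", ("A1", 1.0), ("B2", 1.0))
        assert score_one_way(toy_dag, ["A1"], d) == 0.0
        assert score_similarity_avg(toy_dag, ["A1"], d) > 0.0

    def test_two_way_equality_iff_sets_equal(self, toy_dag):
        d = disease("D", ("A1", 1.0), ("B2", 1.0))
        assert score_similarity_avg(toy_dag, ["A1", "B2"], d) == 0.0

    def test_monotone_degradation(self, toy_dag):
        """Appending a term whose best-match contribution is at least the
        current score can never lower the score."""
        d = disease("D", ("A1", 1.0), ("A2", 1.0))
        base = score_one_way(toy_dag, ["A1", "B1"], d)
        worse = score_one_way(toy_dag, ["A1", "B1", "B2"], d)  # B2 is farther still
        assert worse >= base

    def test_empty_inputs_rejected(self, toy_dag):
        with pytest.raises(ValidationError):
            score_one_way(toy_dag, [], disease("D", ("A1", 1.0)))
        with pytest.raises(ValidationError):
            score_one_way(toy_dag, ["A1"], disease("D"))


class TestSimilarityAvg:
    def test_single_term_collapse_to_one_way(self, toy_dag):
        d = disease("D", ("A2", 1.0))
        assert score_similarity_avg(toy_dag, ["A1"], d) == pytest.approx(
            score_one_way(toy_dag, ["A1"], d)
        )


class TestSearch:
    def test_exact_disease_ranks_first(self, toy_kb):
        hits = search(toy_kb, Query(terms=("A1", "A2"), method="similarity"))
        assert hits[0].disease_id == "ORPHA:1"
        assert hits[0].score == 0.0 and hits[0].rank == 1

    def test_zero_threshold_keeps_only_exact_hits(self, toy_kb):
        hits = search(
            toy_kb,
            Query(terms=("A1", "A2"), method="similarity", max_score_threshold=0.0),
        )
        assert [h.disease_id for h in hits] == ["ORPHA:1"]

    def test_prevalence_filter(self, toy_kb):
        hits = search(
            toy_kb,
            Query(terms=("A1",), method="similarity",
                  prevalence_filter=frozenset({"nonexistent class"})),
        )
        assert hits == []

    def test_jaccard_method_orders_by_set_overlap(self, toy_kb):
        hits = search(toy_kb, Query(terms=("A1", "A2"), method="jaccard"))
        assert hits[0].disease_id == "ORPHA:1"
        assert hits[0].jaccard == 1.0
        assert hits[0].score == 0.0
        overlap = {h.disease_id: h.jaccard for h in hits}
        assert overlap["ORPHA:3"] == pytest.approx(1 / 3)
        assert overlap["ORPHA:2"] == 0.0

    def test_unresolvable_query_term_listed(self, toy_kb):
        with pytest.raises(ValidationError, match="HP:NOPE"):
            search(toy_kb, Query(terms=("A1", "HP:NOPE")))

    def test_cap_keeps_boundary_ties(self, toy_dag):
        diseases = {
            f"ORPHA:{i}": disease(f"ORPHA:{i}", ("A1", 1.0)) for i in range(5)
        }
        kb = KnowledgeBase(
            diseases=diseases, genes={}, phenotype_dag=toy_dag,
            go_cc_dag=toy_dag, go_mf_dag=toy_dag, go_bp_dag=toy_dag,
        )
        hits = search(kb, Query(terms=("A1",)), cap=2)
        assert len(hits) == 5  # all tied at score 0; the cap cannot split ties


class TestTieAwareRank:
    def test_tied_scores_share_rank_one(self, toy_dag):
        # two diseases contain the query exactly, the third is worse
        diseases = {
            "ORPHA:1": disease("ORPHA:1", ("A1", 1.0)),
            "ORPHA:2": disease("ORPHA:2", ("A1", 1.0)),
            "ORPHA:3": disease("ORPHA:3", ("B2", 1.0)),
        }
        kb = KnowledgeBase(
            diseases=diseases, genes={}, phenotype_dag=toy_dag,
            go_cc_dag=toy_dag, go_mf_dag=toy_dag, go_bp_dag=toy_dag,
        )
        hits = search(kb, Query(terms=("A1",)))
        assert [h.rank for h in hits] == [1, 1, 3]
        assert rank_of_target(hits, "ORPHA:2") == 1
        assert rank_of_target(hits, "ORPHA:3") == 3

    def test_target_filtered_out_yields_sentinel(self, toy_kb):
        hits = search(
            toy_kb, Query(terms=("A1", "A2"), max_score_threshold=0.0)
        )
        assert rank_of_target(hits, "ORPHA:2") is NOT_RETRIEVED

    @settings(deadline=None, max_examples=40)
    @given(
        terms=st.lists(
            st.sampled_from(["A1", "A2", "B1", "B2", "A", "B"]),
            min_size=2, max_size=10,
        ),
        query_term=st.sampled_from(["A1", "B2", "A"]),
    )
    def test_search_ranks_count_strictly_better_scores(self, toy_dag, terms, query_term):
        """Property: whatever multiset of annotations the knowledge base
        holds, every returned rank equals 1 + the number of strictly smaller
        scores in the result list."""
        diseases = {
            f"ORPHA:{i}": disease(f"ORPHA:{i}", (t, 1.0))
            for i, t in enumerate(terms)
        }
        kb = KnowledgeBase(
            diseases=diseases, genes={}, phenotype_dag=toy_dag,
            go_cc_dag=toy_dag, go_mf_dag=toy_dag, go_bp_dag=toy_dag,
        )
        hits = search(kb, Query(terms=(query_term,)), cap=None)
        for h in hits:
            better = sum(1 for o in hits if o.score < h.score - 1e-12)
            assert h.rank == 1 + better
        assert hits[0].rank == 1


class TestQueryValidation:
    def test_empty_terms_rejected(self):
        with pytest.raises(ValidationError):
            Query(terms=())

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            Query(terms=("A1",), method="cosine")

    def test_threshold_range_checked(self):
        with pytest.raises(ValidationError):
            Query(terms=("A1",), max_score_threshold=1.5)
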