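"""Disease-level distances against hand values and brute-force oracles."""

import numpy as np
import pytest

from rdmap.annotations import GeneAnnotation
from rdmap.distances import (
    DistanceMatrix,
    build_distance_matrix,
    disease_gene_distance,
    disease_phenotype_distance,
    gene_distance,
    jaccard_similarity,
)
from rdmap.errors import ValidationError
from rdmap.ontology import compute_d_max, term_distance

import oracles
from conftest import disease, make_dag


@pytest.fixture(scope="module")
def toy_go():
    """Three tiny aspect DAGs sharing the 7-node topology of the toy DAG."""
    dags = []
    for a in ("cc", "mf", "bp"):
        d = make_dag({
            f"{a}R": [], f"{a}A": [f"{a}R"], f"{a}B": [f"{a}R"],
            f"{a}A1": [f"{a}A"], f"{a}A2": [f"{a}A"],
            f"{a}B1": [f"{a}B"], f"{a}B2": [f"{a}B1"],
        }, name=a)
        compute_d_max(d, mode="exact")
        dags.append(d)
    return tuple(dags)


class TestGeneDistance:
    def test_identical_annotation_zero(self, toy_go):
        g = GeneAnnotation("G", frozenset({"ccA1"}), frozenset({"mfB1"}),
                           frozenset({"bpA2"}))
        assert gene_distance(toy_go, g, g) == 0.0

    def test_single_term_aspects_hand_value(self, toy_go):
        # per aspect (d_max=5): cc A1 vs A2 = 2/5; mf A1 vs B1 = 4/5; bp A1 vs B2 = 5/5
        g1 = GeneAnnotation("G1", frozenset({"ccA1"}), frozenset({"mfA1"}),
                            frozenset({"bpA1"}))
        g2 = GeneAnnotation("G2", frozenset({"ccA2"}), frozenset({"mfB1"}),
                            frozenset({"bpB2"}))
        want = (0.4 + 0.8 + 1.0) / 3
        assert gene_distance(toy_go, g1, g2) == pytest.approx(want)
        assert gene_distance(toy_go, g2, g1) == pytest.approx(want)

    def test_missing_aspect_contributes_one(self, toy_go):
        g1 = GeneAnnotation("G1", frozenset({"ccA1"}), frozenset({"mfA1"}),
                            frozenset())
        g2 = GeneAnnotation("G2", frozenset({"ccA1"}), frozenset({"mfA1"}),
                            frozenset({"bpA1"}))
        assert gene_distance(toy_go, g1, g2) == pytest.approx((0 + 0 + 1.0) / 3)

    def test_fully_empty_gene_rejected(self, toy_go):
        empty = GeneAnnotation("G0")
        other = GeneAnnotation("G1", cc_terms=frozenset({"ccA1"}))
        with pytest.raises(ValidationError, match="G0"):
            gene_distance(toy_go, empty, other)


class TestDiseasePhenotypeDistance:
    def test_identical_sets_unit_weights_zero(self, toy_dag):
        d1 = disease("D1", ("A1", 1.0), ("B1", 1.0))
        assert disease_phenotype_distance(toy_dag, d1, d1) == 0.0

    def test_single_term_pair_hand_value(self, toy_dag):
        d1 = disease("D1", ("A1", 1.0))
        d2 = disease("D2", ("A2", 1.0))
        assert disease_phenotype_distance(toy_dag, d1, d2) == pytest.approx(0.4)

    def test_weights_scale_the_match(self, toy_dag):
        d1 = disease("D1", ("A1", 0.5))
        d2 = disease("D2", ("A2", 0.8))
        # both directions: 0.4 * 0.5 * 0.8
        assert disease_phenotype_distance(toy_dag, d1, d2) == pytest.approx(0.4 * 0.4)

    def test_distance_tie_broken_toward_larger_weight(self, toy_dag):
        # A1 is two edges from both A2 and R (0.4 each): the matched weight
        # must be the larger one (R at 0.9), not the id-first candidate
        d1 = disease("D1", ("A1", 1.0))
        d2 = disease("D2", ("A2", 0.1), ("R", 0.9))
        got = disease_phenotype_distance(toy_dag, d1, d2)
        # forward: 0.4*1.0*0.9; reverse: A2->A1 0.4*0.1 and R->A1 0.4*0.9
        want = 0.5 * (0.4 * 0.9 + (0.4 * 0.1 + 0.4 * 0.9) / 2)
        assert got == pytest.approx(want)

    def test_empty_phenotypes_rejected(self, toy_dag):
        with pytest.raises(ValidationError, match="D2"):
            disease_phenotype_distance(toy_dag, disease("D1", ("A1", 1.0)),
                                       disease("D2"))

    def test_matches_bruteforce_on_fixture(self, small_kb):
        kb, _ = small_kb
        parents = oracles.parents_of_dag(kb.phenotype_dag)
        d_max = kb.phenotype_dag.d_max
        ids = kb.phenotype_disease_ids()[:12]
        for i, a in enumerate(ids):
            for b in ids[i:]:
                ra, rb = kb.diseases[a], kb.diseases[b]
                want = oracles.weighted_disease_distance(
                    parents, d_max, ra.term_ids, ra.weights, rb.term_ids, rb.weights
                )
                got = disease_phenotype_distance(kb.phenotype_dag, ra, rb)
                assert got == pytest.approx(want), (a, b)

    def test_weight_degeneration_reduces_to_unweighted_best_match(self, small_kb):
        """With all weights forced to 1, the phenotype distance collapses to the
        same two-way best-match shape as the gene distance."""
        from dataclasses import replace
        from rdmap.annotations import WeightedPhenotype

        kb, _ = small_kb
        dag = kb.phenotype_dag
        ids = kb.phenotype_disease_ids()[:8]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ra = replace(kb.diseases[a], phenotypes=tuple(
                    WeightedPhenotype(p.term_id, 1.0) for p in kb.diseases[a].phenotypes))
                rb = replace(kb.diseases[b], phenotypes=tuple(
                    WeightedPhenotype(p.term_id, 1.0) for p in kb.diseases[b].phenotypes))
                matrix = [
                    [term_distance(dag, x, y) for y in rb.term_ids]
                    for x in ra.term_ids
                ]
                want = oracles.unweighted_two_way_best_match(matrix)
                assert disease_phenotype_distance(dag, ra, rb) == pytest.approx(want)

    def test_triangle_inequality_violation_pinned(self, toy_dag):
        """The weighted distance is not a metric: a low-weight intermediate
        disease sits 'close' to two diseases that are maximally far apart."""
        eps = 0.01
        d1 = disease("D1", ("A1", 1.0))
        d2 = disease("D2", ("A1", eps))
        d3 = disease("D3", ("B2", 1.0))
        d12 = disease_phenotype_distance(toy_dag, d1, d2)
        d23 = disease_phenotype_distance(toy_dag, d2, d3)
        d13 = disease_phenotype_distance(toy_dag, d1, d3)
        assert d13 > d12 + d23


class TestDiseaseGeneDistance:
    def test_identical_single_gene_zero(self, toy_go):
        anns = {"G1": GeneAnnotation("G1", frozenset({"ccA1"}), frozenset({"mfA1"}),
                                     frozenset({"bpA1"}))}
        from dataclasses import replace
        d = replace(disease("D1", ("x", 1.0)), phenotypes=(), genes=("G1",))
        assert disease_gene_distance(toy_go, d, d, anns) == 0.0

    def test_single_gene_pair_collapses_to_gene_distance(self, toy_go):
        anns = {
            "G1": GeneAnnotation("G1", frozenset({"ccA1"}), frozenset({"mfA1"}),
                                 frozenset({"bpA1"})),
            "G2": GeneAnnotation("G2", frozenset({"ccA2"}), frozenset({"mfB1"}),
                                 frozenset({"bpB2"})),
        }
        from dataclasses import replace
        d1 = replace(disease("D1"), genes=("G1",))
        d2 = replace(disease("D2"), genes=("G2",))
        assert disease_gene_distance(toy_go, d1, d2, anns) == pytest.approx(
            gene_distance(toy_go, anns["G1"], anns["G2"])
        )

    def test_matches_bruteforce_on_fixture(self, small_kb):
        kb, manifest = small_kb
        go_parents = {
            a: oracles.parents_of_dag(d) for a, d in zip(("cc", "mf", "bp"), kb.go_dags)
        }
        go_d_max = {a: d.d_max for a, d in zip(("cc", "mf", "bp"), kb.go_dags)}
        ids = kb.gene_disease_ids()[:8]
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ra, rb = kb.diseases[a], kb.diseases[b]
                mat = [
                    [
                        oracles.gene_pair_distance(
                            go_parents, go_d_max,
                            manifest.genes[g1], manifest.genes[g2],
                        )
                        for g2 in rb.genes
                    ]
                    for g1 in ra.genes
                ]
                want = oracles.unweighted_two_way_best_match(mat)
                got = disease_gene_distance(kb.go_dags, ra, rb, kb.genes)
                assert got == pytest.approx(want), (a, b)


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_similarity({"a"}, {"b"}) == 0.0

    def test_hand_count(self):
        assert jaccard_similarity({"a", "b", "c", "d"}, {"a", "b", "e"}) == pytest.approx(0.4)

    def test_alias_resolution(self, toy_dag):
        toy_dag.aliases["A1_alt"] = "A1"
        assert jaccard_similarity({"A1_alt"}, {"A1"}, dag=toy_dag) == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_similarity(set(), {"a"})


class TestDistanceMatrix:
    def test_entries_match_pairwise_calls(self, small_kb):
        kb, _ = small_kb
        dm = build_distance_matrix(kb, "phenotype")
        assert np.allclose(np.diag(dm.values), 0.0)
        ids = dm.ids
        for i in (0, 3):
            for j in (1, 5):
                want = disease_phenotype_distance(
                    kb.phenotype_dag, kb.diseases[ids[i]], kb.diseases[ids[j]]
                )
                assert dm.values[i, j] == pytest.approx(want)
        assert ids == sorted(ids)  # deterministic id ordering

    def test_matches_bruteforce_entrywise(self, small_kb):
        kb, _ = small_kb
        dm = build_distance_matrix(kb, "phenotype")
        parents = oracles.parents_of_dag(kb.phenotype_dag)
        d_max = kb.phenotype_dag.d_max
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i >= j:
                    continue
                ra, rb = kb.diseases[a], kb.diseases[b]
                want = oracles.weighted_disease_distance(
                    parents, d_max, ra.term_ids, ra.weights, rb.term_ids, rb.weights
                )
                assert dm.values[i, j] == pytest.approx(want)

    def test_gene_matrix_builds_and_validates(self, small_kb):
        kb, _ = small_kb
        dm = build_distance_matrix(kb, "gene")
        assert dm.kind == "gene"
        assert len(dm.ids) == len(kb.gene_disease_ids())

    def test_save_load_round_trip(self, small_kb, tmp_path):
        kb, _ = small_kb
        dm = build_distance_matrix(kb, "phenotype")
        prefix = tmp_path / "phen"
        dm.save(prefix)
        back = DistanceMatrix.load(prefix)
        assert back.ids == dm.ids
        assert np.allclose(back.values, dm.values)
        assert back.kind == dm.kind

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.2], [0.3, 0]]),
                           kind="phenotype")

    def test_too_few_diseases_rejected(self, toy_dag):
        from rdmap.annotations import KnowledgeBase

        kb = KnowledgeBase(
            diseases={"D1": disease("D1", ("A1", 1.0))}, genes={},
            phenotype_dag=toy_dag, go_cc_dag=toy_dag, go_mf_dag=toy_dag,
            go_bp_dag=toy_dag,
        )
        with pytest.raises(ValidationError, match="at least 2"):
            build_distance_matrix(kb, "phenotype")
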