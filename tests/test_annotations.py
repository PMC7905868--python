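"""Annotation loaders, frequency weights and knowledge-base assembly."""

import pytest

from rdmap.annotations import (
    DEFAULT_FREQUENCY_WEIGHTS,
    DiseaseRecord,
    WeightedPhenotype,
    assemble_knowledge_base,
    frequency_weight,
    load_disease_genes,
    load_disease_phenotypes,
    load_gene_annotations,
)
from rdmap.errors import InputError, ValidationError
from rdmap.fixtures import generate_knowledge_base
from rdmap.ontology import compute_d_max

from conftest import make_dag


class TestFrequencyWeight:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("Obligate (100%)", 1.0),
            ("Excluded (0%)", 0.0),
            ("Frequent (79-30%)", 0.545),  # midpoint of the printed band
            ("very frequent", 0.895),
            (0.25, 0.25),   # literal numeric fraction passes through
            ("0.33", 0.33),
        ],
    )
    def test_mapping(self, label, expected):
        assert frequency_weight(label) == pytest.approx(expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError, match="sometimes"):
            frequency_weight("sometimes")

    def test_out_of_range_numeric_rejected(self):
        with pytest.raises(ValidationError):
            frequency_weight(1.5)

    def test_ladder_is_monotone(self):
        ladder = ["obligate", "very frequent", "frequent", "occasional",
                  "very rare", "excluded"]
        weights = [frequency_weight(lab) for lab in ladder]
        assert weights == sorted(weights, reverse=True)
        assert len(set(weights)) == len(weights)


class TestTsvLoading:
    PHENO = (
        "disease_id\tdisease_name\thpo_id\tfrequency_label\n"
        "ORPHA:1\tdisease one\tHP:0000002\tObligate (100%)\n"
        "ORPHA:1\tdisease one\tHP:0000003\tFrequent (79-30%)\n"
        "ORPHA:2\tdisease two\tHP:0000002\tVery rare (<4-1%)\n"
        "ORPHA:2\tdisease two\tHP:0000004\tOccasional (29-5%)\n"
    )

    def test_two_diseases_two_phenotypes(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text(self.PHENO)
        records = load_disease_phenotypes(p)
        assert len(records) == 2
        by_id = {r.disease_id: r for r in records}
        assert len(by_id["ORPHA:1"].phenotypes) == 2
        assert by_id["ORPHA:1"].phenotypes[0].weight == 1.0
        assert by_id["ORPHA:2"].name == "disease two"

    def test_unknown_frequency_label_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "disease_id\tdisease_name\thpo_id\tfrequency_label\n"
            "ORPHA:1\td\tHP:0000002\tUsually\n"
        )
        with pytest.raises(ValidationError, match="Usually"):
            load_disease_phenotypes(p)

    def test_loading_is_idempotent(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text(self.PHENO)
        assert load_disease_phenotypes(p) == load_disease_phenotypes(p)

    def test_gene_tsv(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("disease_id\tgene_symbol\nORPHA:1\tTP53\nORPHA:1\tBRCA1\n")
        m = load_disease_genes(p)
        assert m == {"ORPHA:1": ["TP53", "BRCA1"]}

    def test_empty_gene_row_omitted(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("disease_id\tgene_symbol\nORPHA:1\tTP53\nORPHA:2\t\n")
        assert "ORPHA:2" not in load_disease_genes(p)


class TestGeneGoLoading:
    def test_tsv_aspects(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text(
            "gene_symbol\taspect\tgo_id\n"
            "G1\tcc\tGO:1\nG1\tmf\tGO:2\nG1\tmf\tGO:3\nG2\tbp\tGO:4\n"
        )
        anns = load_gene_annotations(p)
        assert anns["G1"].mf_terms == {"GO:2", "GO:3"}
        assert anns["G2"].cc_terms == frozenset()

    def test_gaf_dialect(self, tmp_path):
        p = tmp_path / "anno.gaf"
        row = ["DB", "ACC1", "G1", "", "GO:0005", "REF", "IEA", "", "C"] + [""] * 8
        p.write_text("!gaf-version: 2.2\n" + "\t".join(row) + "\n")
        anns = load_gene_annotations(p, dialect="gaf")
        assert anns["G1"].cc_terms == {"GO:0005"}

    def test_unknown_aspect_rejected(self, tmp_path):
        p = tmp_path / "go.tsv"
        p.write_text("gene_symbol\taspect\tgo_id\nG1\txx\tGO:1\n")
        with pytest.raises(ValidationError, match="xx"):
            load_gene_annotations(p)


class TestXmlDialect:
    def test_generated_xml_matches_manifest(self, tmp_path):
        kb, manifest = generate_knowledge_base(
            tmp_path, n_diseases=20, terms_per_disease=5, n_clusters=1,
            dag_terms=80, go_dag_terms=60, seed=17, dialect="orphanet_xml",
        )
        records = load_disease_phenotypes(
            manifest.files["disease_phenotypes"], dialect="orphanet_xml"
        )
        assert len(records) == 20
        by_id = {r.disease_id: r for r in records}
        for did, truth in manifest.diseases.items():
            assert sorted(by_id[did].term_ids) == sorted(truth["terms"])
            assert by_id[did].prevalence_class == truth["prevalence_class"]
            assert truth["omim"] in by_id[did].xrefs
        genes = load_disease_genes(
            manifest.files["disease_genes"], dialect="orphanet_xml"
        )
        for did, truth in manifest.diseases.items():
            assert sorted(genes.get(did, [])) == sorted(truth["genes"])

    def test_malformed_xml(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<JDBOR><Disorder>")
        with pytest.raises(InputError, match="malformed"):
            load_disease_phenotypes(p, dialect="orphanet_xml")


class TestKnowledgeBase:
    def _dags(self):
        hp = make_dag({"R": [], "P1": ["R"], "P2": ["R"]}, name="hp")
        go = {
            a: make_dag({"G": [], "T1": ["G"]}, name=a) for a in ("cc", "mf", "bp")
        }
        for d in [hp, *go.values()]:
            compute_d_max(d, mode="exact")
        return hp, go

    def _record(self, did, terms, genes=()):
        return DiseaseRecord(
            disease_id=did, name=did,
            phenotypes=tuple(WeightedPhenotype(t, 1.0) for t in terms),
            genes=tuple(genes),
        )

    def test_hand_counted_census(self):
        hp, go = self._dags()
        from rdmap.annotations import GeneAnnotation

        anns = {"G1": GeneAnnotation("G1", cc_terms=frozenset({"T1"}))}
        kb = assemble_knowledge_base(
            [self._record("D1", ["P1"]), self._record("D2", ["P2"]),
             self._record("D3", [])],
            {"D2": ["G1"], "D3": ["G1"]},
            anns,
            phenotype_dag=hp,
            go_cc_dag=go["cc"], go_mf_dag=go["mf"], go_bp_dag=go["bp"],
        )
        census = kb.census
        assert (census["phenotype_diseases"], census["gene_diseases"],
                census["overlap"]) == (2, 2, 1)
        # inclusion-exclusion identity
        assert census["union"] == (
            census["phenotype_diseases"] + census["gene_diseases"] - census["overlap"]
        )

    def test_bogus_term_dropped_census_unchanged(self):
        hp, go = self._dags()
        kb = assemble_knowledge_base(
            [self._record("D1", ["P1", "HP:NOPE"]), self._record("D2", ["P2"])],
            {}, {},
            phenotype_dag=hp,
            go_cc_dag=go["cc"], go_mf_dag=go["mf"], go_bp_dag=go["bp"],
        )
        assert kb.dropped_terms == 1
        assert kb.diseases["D1"].term_ids == ("P1",)
        assert kb.census["phenotype_diseases"] == 2

    def test_census_matches_generator_manifest(self, small_kb):
        kb, manifest = small_kb
        assert kb.census["phenotype_diseases"] == len(manifest.diseases)
        assert kb.census["gene_diseases"] == len(
            [d for d, v in manifest.diseases.items() if v["genes"]]
        )

    def test_all_excluded_disease_flagged_and_not_mapped(self):
        hp, go = self._dags()
        rec = DiseaseRecord(
            disease_id="D1", name="D1",
            phenotypes=(WeightedPhenotype("P1", 0.0),),
        )
        kb = assemble_knowledge_base(
            [rec, self._record("D2", ["P2"])], {}, {},
            phenotype_dag=hp,
            go_cc_dag=go["cc"], go_mf_dag=go["mf"], go_bp_dag=go["bp"],
        )
        assert kb.diseases["D1"].all_excluded
        assert "D1" not in kb.phenotype_disease_ids()
        assert "D1" in kb.phenotype_disease_ids(include_all_excluded=True)

    def test_resolve_xref(self, small_kb):
        kb, manifest = small_kb
        did, truth = sorted(manifest.diseases.items())[0]
        assert kb.resolve_xref(truth["omim"]) == did
        assert kb.resolve_xref("OMIM:000000") is None
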