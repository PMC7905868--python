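import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from rdmap.annotations import DiseaseRecord, WeightedPhenotype
from rdmap.ontology import OntologyDAG, Term, compute_d_max


def make_dag(parents: dict, name: str = "toy") -> OntologyDAG:
    terms = {
        t: Term(id=t, name=f"term {t}", parent_ids=tuple(ps))
        for t, ps in parents.items()
    }
    return OntologyDAG(terms=terms, name=name)


@pytest.fixture(scope="session")
def toy_dag() -> OntologyDAG:
    """Seven terms: root R; A, B below R; A1, A2 below A; B1 below B; B2 below B1.

    Hand-enumerable distances: A1-A2 = 2 (via A), A1-B1 = 4 (via R),
    farthest pair A-leaf vs B2 = 5, so the exact normalization constant is 5.
    """
    dag = make_dag({
        "R": [], "A": ["R"], "B": ["R"],
        "A1": ["A"], "A2": ["A"], "B1": ["B"], "B2": ["B1"],
    })
    compute_d_max(dag, mode="exact")
    return dag


@pytest.fixture(scope="session")
def chain_dag() -> OntologyDAG:
    dag = make_dag({"R": [], "A": ["R"], "A1": ["A"]})
    compute_d_max(dag, mode="exact")
    return dag


def disease(did: str, *pairs) -> DiseaseRecord:
    """Shorthand: disease('D1', ('A1', 1.0), ('B2', 0.5))."""
    return DiseaseRecord(
        disease_id=did,
        name=did,
        phenotypes=tuple(WeightedPhenotype(t, w) for t, w in pairs),
    )


@pytest.fixture(scope="session")
def small_kb(tmp_path_factory):
    """Unclustered 20-disease synthetic knowledge base, loaded via the real loaders."""
    from rdmap.fixtures import generate_knowledge_base

    out = tmp_path_factory.mktemp("small_kb")
    kb, manifest = generate_knowledge_base(
        out, n_diseases=20, terms_per_disease=6, n_clusters=1,
        n_genes=12, dag_terms=120, go_dag_terms=80, seed=101,
    )
    return kb, manifest


@pytest.fixture(scope="session")
def clustered_kb(tmp_path_factory):
    """Three planted clusters, 60 diseases — the map-recovery fixture."""
    from rdmap.fixtures import generate_knowledge_base

    out = tmp_path_factory.mktemp("clustered_kb")
    kb, manifest = generate_knowledge_base(
        out, n_diseases=60, terms_per_disease=8, n_clusters=3, seed=7,
    )
    return kb, manifest
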