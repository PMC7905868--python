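"""Disease-level distances built on the ontology term distance.

Phenotype side: a disease is a weighted term set; the distance between two
diseases is the symmetrized best-match average

    Dist_dp(d1, d2) = 1/2 [ (1/m) sum_i min_j Dist_p(p_i, p_j) * w_i * w_j*
                          + (1/n) sum_j min_i Dist_p(p_j, p_i) * w_j * w_i* ]

where each term of one disease is matched to its closest term in the other
and w* is the weight of the term attaining that minimum (ties in the minimum
are broken toward the larger weight, so the weighting reflects the most
typical matching phenotype).

Gene side: the distance between two genes is the mean over the three GO
aspects of the best-match term distance in that aspect's DAG,

    Dist_g(g1, g2) = (Dist_cc + Dist_mf + Dist_bp) / 3,

and the distance between two diseases is the unweighted two-way best-match
average of Dist_g over their pathogenic gene lists.  An aspect missing on
either gene contributes the maximal distance 1.0 rather than being silently
dropped.

All four operations are symmetric with values in [0, 1]; none of them is a
metric (the weighting can produce triangle-inequality violations, which is
documented and pinned by a test rather than hidden).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .annotations import DiseaseRecord, GeneAnnotation, KnowledgeBase
from .errors import ValidationError
from .ontology import OntologyDAG, term_distance

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "gene_distance",
    "disease_phenotype_distance",
    "disease_gene_distance",
    "jaccard_similarity",
    "build_distance_matrix",
]

ASPECTS = ("cc", "mf", "bp")


@dataclass
class DistanceMatrix:
    """Symmetric all-pairs disease distance matrix with provenance metadata."""

    ids: List[str]
    values: np.ndarray
    kind: str  # "phenotype" | "gene"
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} ids"
            )
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValidationError("distance matrix entries outside [0, 1]")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    def save(self, prefix) -> None:
        """Write ``<prefix>.tsv`` (matrix), ``<prefix>.ids`` and ``<prefix>.json``."""
        np.savetxt(f"{prefix}.tsv", self.values, delimiter="\t", fmt="%.10g")
        with open(f"{prefix}.ids", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.ids) + "\n")
        with open(f"{prefix}.json", "w", encoding="utf-8") as fh:
            json.dump({"kind": self.kind, **self.metadata}, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, prefix) -> "DistanceMatrix":
        values = np.loadtxt(f"{prefix}.tsv", delimiter="\t", ndmin=2)
        with open(f"{prefix}.ids", "r", encoding="utf-8") as fh:
            ids = [line.strip() for line in fh if line.strip()]
        with open(f"{prefix}.json", "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        kind = meta.pop("kind", "phenotype")
        return cls(ids=ids, values=values, kind=kind, metadata=meta)


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------

def _best_match(
    dag: OntologyDAG, term: str, candidates: Sequence[str], weights: Sequence[float]
) -> Tuple[float, float]:
    """(min distance, weight of the argmin term); distance ties -> larger weight."""
    best_d, best_w = None, 0.0
    for cand, w in zip(candidates, weights):
        d = term_distance(dag, term, cand)
        if best_d is None or d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and w > best_w):
            best_d, best_w = d, w
    assert best_d is not None
    return best_d, best_w


def _aspect_distance(dag: OntologyDAG, terms1: frozenset, terms2: frozenset) -> float:
    """Best-match (minimum) term distance between two GO term sets in one aspect."""
    if not terms1 or not terms2:
        return 1.0  # missing aspect on either gene -> maximal dissimilarity
    return min(
        term_distance(dag, a, b) for a in sorted(terms1) for b in sorted(terms2)
    )


def gene_distance(
    go_dags: Tuple[OntologyDAG, OntologyDAG, OntologyDAG],
    g1: GeneAnnotation,
    g2: GeneAnnotation,
) -> float:
    """Mean over the cc/mf/bp aspects of the best-match GO term distance."""
    if g1.empty or g2.empty:
        bad = g1.symbol if g1.empty else g2.symbol
        raise ValidationError(f"gene {bad!r} has no GO annotation in any aspect")
    cc_dag, mf_dag, bp_dag = go_dags
    parts = (
        _aspect_distance(cc_dag, g1.cc_terms, g2.cc_terms),
        _aspect_distance(mf_dag, g1.mf_terms, g2.mf_terms),
        _aspect_distance(bp_dag, g1.bp_terms, g2.bp_terms),
    )
    return sum(parts) / 3.0


def disease_phenotype_distance(
    dag: OntologyDAG, d1: DiseaseRecord, d2: DiseaseRecord
) -> float:
    """Weighted two-way best-match phenotype distance between two diseases."""
    for rec in (d1, d2):
        if not rec.phenotypes:
            raise ValidationError(f"disease {rec.disease_id!r} has no phenotypes")
    t1, w1 = d1.term_ids, d1.weights
    t2, w2 = d2.term_ids, d2.weights

    def one_way(terms, weights, other_terms, other_weights) -> float:
        total = 0.0
        for term, w in zip(terms, weights):
            dist, w_star = _best_match(dag, term, other_terms, other_weights)
            total += dist * w * w_star
        return total / len(terms)

    return 0.5 * (one_way(t1, w1, t2, w2) + one_way(t2, w2, t1, w1))


def disease_gene_distance(
    go_dags: Tuple[OntologyDAG, OntologyDAG, OntologyDAG],
    d1: DiseaseRecord,
    d2: DiseaseRecord,
    gene_annotations: Mapping[str, GeneAnnotation],
) -> float:
    """Unweighted two-way best-match average of the gene distance."""
    lists = []
    for rec in (d1, d2):
        anns = [
            gene_annotations[g]
            for g in rec.genes
            if g in gene_annotations and not gene_annotations[g].empty
        ]
        if not anns:
            raise ValidationError(
                f"disease {rec.disease_id!r} has no GO-annotated genes"
            )
        lists.append(anns)
    g1s, g2s = lists
    d = np.array([[gene_distance(go_dags, a, b) for b in g2s] for a in g1s])
    return 0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean())


def jaccard_similarity(q: Iterable[str], t: Iterable[str],
                       dag: Optional[OntologyDAG] = None) -> float:
    """|q n t| / |q u t| after alias resolution (when a DAG is supplied)."""
    qs, ts = set(q), set(t)
    if not qs or not ts:
        raise ValidationError("Jaccard similarity of an empty term set")
    if dag is not None:
        qs = {dag.resolve(x) for x in qs}
        ts = {dag.resolve(x) for x in ts}
    return len(qs & ts) / len(qs | ts)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

def build_distance_matrix(kb: KnowledgeBase, kind: str) -> DistanceMatrix:
    """All-pairs disease distance matrix over the eligible diseases.

    ``kind="phenotype"`` admits diseases with a non-degenerate weighted
    phenotype set; ``kind="gene"`` admits diseases with at least one
    GO-annotated pathogenic gene.  Rows/columns are ordered by disease id, so
    the result is independent of input ordering.
    """
    if kind == "phenotype":
        ids = kb.phenotype_disease_ids()
        dag = kb.phenotype_dag
        meta = {
            "d_max": dag.d_max,
            "d_max_mode": dag.d_max_mode,
            "census": kb.census,
        }

        def pair(a: str, b: str) -> float:
            return disease_phenotype_distance(dag, kb.diseases[a], kb.diseases[b])

    elif kind == "gene":
        ids = kb.gene_disease_ids()
        meta = {
            "d_max": {
                aspect: dag.d_max for aspect, dag in zip(ASPECTS, kb.go_dags)
            },
            "d_max_mode": {
                aspect: dag.d_max_mode for aspect, dag in zip(ASPECTS, kb.go_dags)
            },
            "census": kb.census,
        }

        def pair(a: str, b: str) -> float:
            return disease_gene_distance(
                kb.go_dags, kb.diseases[a], kb.diseases[b], kb.genes
            )

    else:
        raise ValidationError(f"unknown distance matrix kind {kind!r}")

    n = len(ids)
    if n < 2:
        raise ValidationError(
            f"need at least 2 eligible diseases for a {kind} matrix, found {n}"
        )
    values = np.zeros((n, n))
    for i in range(n):
        if i and i % 200 == 0:
            logger.info("%s matrix: %d/%d rows", kind, i, n)
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pair(ids[i], ids[j])
    return DistanceMatrix(ids=list(ids), values=values, kind=kind, metadata=meta)
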