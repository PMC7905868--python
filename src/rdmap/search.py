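"""Phenotype-driven disease ranking.

Three scoring methods, all reported on a distance-like scale in [0, 1] where
smaller means more similar:

* ``similarity`` (default) — one-way best-match average from the query to the
  disease: each query term is matched to its closest disease term, the
  distance is multiplied by the matched term's frequency weight, and the
  contributions are averaged over the query.  Robust to partial queries: a
  query that is a subset of the disease's annotation scores 0.
* ``similarity_avg`` — symmetric two-way best-match average, i.e. the disease
  phenotype distance with the query treated as a pseudo-disease whose terms
  all carry weight 1.
* ``jaccard`` — direct term-overlap baseline, reported as distance 1 - J
  (the raw similarity is kept alongside).

Ranks are tie-aware: a disease's rank is 1 plus the number of diseases with a
strictly smaller score, so ties never worsen the rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .annotations import DiseaseRecord, KnowledgeBase
from .distances import _best_match, disease_phenotype_distance, jaccard_similarity
from .errors import ValidationError
from .ontology import OntologyDAG

__all__ = [
    "Query",
    "SearchHit",
    "score_one_way",
    "score_similarity_avg",
    "search",
    "rank_of_target",
    "NOT_RETRIEVED",
]

METHODS = ("similarity", "similarity_avg", "jaccard")

#: Sentinel rank for a target that was filtered out of the hit list.
NOT_RETRIEVED = None


@dataclass(frozen=True)
class Query:
    """A phenotype query plus method and result filters."""

    terms: Tuple[str, ...]
    method: str = "similarity"
    max_score_threshold: Optional[float] = None
    prevalence_filter: Optional[frozenset] = None

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("query must contain at least one term")
        if self.method not in METHODS:
            raise ValidationError(f"unknown search method {self.method!r}")
        t = self.max_score_threshold
        if t is not None and not 0.0 <= t <= 1.0:
            raise ValidationError(f"score threshold {t} outside [0, 1]")


@dataclass(frozen=True)
class SearchHit:
    """One ranked disease: distance-like score (smaller = more similar)."""

    disease_id: str
    score: float
    rank: int
    name: str = ""
    jaccard: Optional[float] = None  # raw similarity, kept for the baseline


def score_one_way(
    dag: OntologyDAG,
    query_terms: Sequence[str],
    disease: DiseaseRecord,
    use_weights: bool = True,
) -> float:
    """Query->disease best-match average distance (the default search score)."""
    if not query_terms:
        raise ValidationError("empty query")
    if not disease.phenotypes:
        raise ValidationError(f"disease {disease.disease_id!r} has no phenotypes")
    terms = disease.term_ids
    weights = disease.weights if use_weights else tuple(1.0 for _ in terms)
    total = 0.0
    for q in query_terms:
        dist, w_star = _best_match(dag, q, terms, weights)
        total += dist * (w_star if use_weights else 1.0)
    return total / len(query_terms)


def score_similarity_avg(
    dag: OntologyDAG,
    query_terms: Sequence[str],
    disease: DiseaseRecord,
    use_weights: bool = True,
) -> float:
    """Two-way best-match average with the query as a unit-weight pseudo-disease."""
    from .annotations import WeightedPhenotype  # local import avoids cycle at module load

    if not query_terms:
        raise ValidationError("empty query")
    pseudo = DiseaseRecord(
        disease_id="__query__",
        name="query",
        phenotypes=tuple(
            WeightedPhenotype(t, 1.0) for t in dict.fromkeys(query_terms)
        ),
    )
    target = disease
    if not use_weights:
        from dataclasses import replace

        target = replace(
            disease,
            phenotypes=tuple(
                WeightedPhenotype(p.term_id, 1.0) for p in disease.phenotypes
            ),
        )
    return disease_phenotype_distance(dag, pseudo, target)


def search(
    kb: KnowledgeBase,
    query: Query,
    use_weights: bool = True,
    cap: Optional[int] = 100,
) -> List[SearchHit]:
    """Rank every phenotype-annotated disease against the query.

    Hits are sorted by (score, disease id) with tie-aware ranks computed
    before the threshold/prevalence filters and the result cap are applied,
    so a reported rank always refers to the full candidate list.  Ties at the
    cap boundary are all included.
    """
    dag = kb.phenotype_dag
    unresolved = []
    resolved = []
    for t in query.terms:
        try:
            resolved.append(dag.resolve(t))
        except Exception:
            unresolved.append(t)
    if unresolved:
        raise ValidationError(f"query terms do not resolve: {unresolved}")

    scored: List[Tuple[str, float, Optional[float]]] = []
    for did in kb.phenotype_disease_ids():
        rec = kb.diseases[did]
        jac = None
        if query.method == "similarity":
            s = score_one_way(dag, resolved, rec, use_weights=use_weights)
        elif query.method == "similarity_avg":
            s = score_similarity_avg(dag, resolved, rec, use_weights=use_weights)
        else:
            jac = jaccard_similarity(resolved, rec.term_ids, dag=dag)
            s = 1.0 - jac
        scored.append((did, s, jac))

    scored.sort(key=lambda x: (x[1], x[0]))
    # tie-aware ranks on the sorted list: 1 + count of strictly smaller scores
    ranks: List[int] = []
    group_start, prev = 1, None
    for pos, (_, s, _) in enumerate(scored, start=1):
        if prev is None or s > prev + 1e-12:
            group_start, prev = pos, s
        ranks.append(group_start)
    hits = []
    for (did, s, jac), rank in zip(scored, ranks):
        rec = kb.diseases[did]
        if query.max_score_threshold is not None and s > query.max_score_threshold + 1e-12:
            continue
        if query.prevalence_filter is not None and rec.prevalence_class not in query.prevalence_filter:
            continue
        hits.append(SearchHit(disease_id=did, score=s, rank=rank, name=rec.name, jaccard=jac))

    if cap is not None and len(hits) > cap:
        cutoff = hits[cap - 1].score
        hits = [h for h in hits if h.score <= cutoff + 1e-12]
    return hits


def rank_of_target(hits: Sequence[SearchHit], target_disease_id: str):
    """Tie-aware rank of the target, or :data:`NOT_RETRIEVED` if filtered out."""
    for h in hits:
        if h.disease_id == target_disease_id:
            return h.rank
    return NOT_RETRIEVED
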