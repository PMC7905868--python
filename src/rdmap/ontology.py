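"""Ontology DAGs and the normalized common-ancestor-path distance.

An ontology (HPO, or one GO aspect) is a rooted directed acyclic graph whose
terms are linked to their parents by ``is_a`` edges.  The distance between two
terms is the length of the shortest route that climbs from both terms to a
shared ancestor,

    Dist(t1, t2) = min over common ancestors a of (d(t1, a) + d(t2, a)) / d_max,

where ``d(t, a)`` is the smallest number of child->parent edges from ``t`` up
to ``a`` and ``d_max`` normalizes the result into [0, 1].  The route must pass
through a common *ancestor*: common descendants do not count.  Terms living in
disjoint components (multi-root OBO files) have no common ancestor; their
distance is defined as the maximum, 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set, Tuple

import networkx as nx
import obonet

from .errors import InputError, ObsoleteTermError, UnknownTermError, ValidationError

__all__ = [
    "Term",
    "OntologyDAG",
    "load_obo",
    "term_distance",
    "compute_d_max",
    "neighbors_for_imprecision",
]


@dataclass(frozen=True)
class Term:
    """One ontology term: accession, label, and its ``is_a`` parents."""

    id: str
    name: str
    parent_ids: Tuple[str, ...] = ()


@dataclass
class OntologyDAG:
    """A validated rooted DAG of terms with child->parent ``is_a`` edges.

    ``aliases`` maps alternative (``alt_id``) accessions to canonical ids;
    ``obsolete`` records accessions that were dropped at load time so queries
    against them fail with a specific error rather than "unknown id".
    ``d_max`` is the normalization constant of the term distance; it is
    computed lazily (see :func:`compute_d_max`) and cached together with the
    mode that produced it.
    """

    terms: Dict[str, Term]
    aliases: Dict[str, str] = field(default_factory=dict)
    obsolete: Set[str] = field(default_factory=set)
    name: str = "ontology"

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t in self.terms.values():
            for p in t.parent_ids:
                if p not in self.terms:
                    raise ValidationError(
                        f"{self.name}: term {t.id!r} has is_a parent {p!r} "
                        "which is not defined"
                    )
                g.add_edge(t.id, p)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValidationError(
                f"{self.name}: is_a cycle detected involving term {cycle[0][0]!r}"
            )
        self._graph = g
        self._ancestor_cache: Dict[str, Dict[str, int]] = {}
        self._pair_cache: Dict[Tuple[str, str], int | None] = {}
        self._d_max: Optional[int] = None
        self._d_max_mode: Optional[str] = None

    # -- basic structure ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.aliases

    @property
    def graph(self) -> nx.DiGraph:
        """Child->parent edge view (networkx DiGraph)."""
        return self._graph

    @property
    def roots(self) -> List[str]:
        return sorted(t for t in self.terms if not self.terms[t].parent_ids)

    @property
    def depth(self) -> Dict[str, int]:
        """Shortest edge count from any root, per term."""
        rev = self._graph.reverse(copy=False)  # parent -> child
        depths: Dict[str, int] = {}
        for lengths in (nx.single_source_shortest_path_length(rev, r) for r in self.roots):
            for node, d in lengths.items():
                if node not in depths or d < depths[node]:
                    depths[node] = d
        return depths

    def resolve(self, term_id: str) -> str:
        """Resolve an accession (canonical or alt_id) to its canonical id."""
        if term_id in self.terms:
            return term_id
        if term_id in self.aliases:
            return self.aliases[term_id]
        if term_id in self.obsolete:
            raise ObsoleteTermError(term_id)
        raise UnknownTermError(term_id, self.name)

    # -- distances ---------------------------------------------------------

    def ancestor_distances(self, term_id: str) -> Dict[str, int]:
        """Map ancestor id -> shortest child->ancestor edge count (self at 0)."""
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            cached = nx.single_source_shortest_path_length(self._graph, term_id)
            self._ancestor_cache[term_id] = cached
        return cached

    def path_length(self, t1: str, t2: str) -> Optional[int]:
        """Unnormalized common-ancestor-path length, or None if no common ancestor."""
        a, b = self.resolve(t1), self.resolve(t2)
        if a == b:
            return 0
        key = (a, b) if a < b else (b, a)
        if key in self._pair_cache:
            return self._pair_cache[key]
        da, db = self.ancestor_distances(a), self.ancestor_distances(b)
        if len(db) < len(da):
            da, db = db, da
        best: Optional[int] = None
        for anc, d1 in da.items():
            d2 = db.get(anc)
            if d2 is not None and (best is None or d1 + d2 < best):
                best = d1 + d2
        self._pair_cache[key] = best
        return best

    @property
    def d_max(self) -> int:
        """Cached normalization constant; computed with ``depth_bound`` on first use."""
        if self._d_max is None:
            compute_d_max(self, mode="depth_bound")
        return self._d_max  # type: ignore[return-value]

    @property
    def d_max_mode(self) -> Optional[str]:
        return self._d_max_mode


def load_obo(path, name: str = "ontology") -> OntologyDAG:
    """Load an OBO flat file into a validated :class:`OntologyDAG`.

    Only ``is_a`` edges are honored; other relationship types are ignored.
    Obsolete terms are skipped (and recorded), ``alt_id`` accessions resolve
    as aliases of their canonical term.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=False)
    except OSError as exc:
        raise InputError(f"cannot read OBO file {path!r}: {exc}") from exc
    except ValueError as exc:
        raise InputError(f"cannot parse OBO file {path!r}: {exc}") from exc

    obsolete = {
        n for n, data in graph.nodes(data=True)
        if str(data.get("is_obsolete", "")).lower() == "true"
    }
    terms: Dict[str, Term] = {}
    aliases: Dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        if node in obsolete:
            continue
        parents = tuple(
            sorted(
                v for _, v, key in graph.out_edges(node, keys=True)
                if key == "is_a" and v not in obsolete
            )
        )
        terms[node] = Term(id=node, name=data.get("name", node), parent_ids=parents)
        for alt in data.get("alt_id", []):
            aliases[alt] = node
    dag = OntologyDAG(terms=terms, aliases=aliases, obsolete=obsolete, name=name)
    return dag


def compute_d_max(dag: OntologyDAG, mode: str = "exact") -> int:
    """Compute and cache the normalization constant of the term distance.

    mode="exact"
        Maximum over all term pairs of the unnormalized common-ancestor-path
        distance (pairs with no common ancestor are excluded: their distance
        is defined as 1.0 after normalization).  Quadratic; meant for small
        and test-sized DAGs.
    mode="depth_bound"
        ``2 * max depth`` — an upper bound on the exact value (any
        common-ancestor route climbs at most ``depth`` edges on each side),
        cheap enough for real HPO/GO ontologies.

    A single-term DAG yields 0; the distance denominator is guarded so the
    normalized distance stays defined.
    """
    if not dag.terms:
        raise ValidationError("cannot compute d_max of an empty ontology")
    if mode not in ("exact", "depth_bound"):
        raise ValidationError(f"unknown d_max mode {mode!r}")
    if mode == "depth_bound":
        value = 2 * max(dag.depth.values())
    else:
        ids = sorted(dag.terms)
        value = 0
        for i, a in enumerate(ids):
            da = dag.ancestor_distances(a)
            for b in ids[i + 1:]:
                db = dag.ancestor_distances(b)
                best = None
                small, big = (da, db) if len(da) <= len(db) else (db, da)
                for anc, d1 in small.items():
                    d2 = big.get(anc)
                    if d2 is not None and (best is None or d1 + d2 < best):
                        best = d1 + d2
                if best is not None and best > value:
                    value = best
    dag._d_max = value
    dag._d_max_mode = mode
    return value


def term_distance(dag: OntologyDAG, t1: str, t2: str) -> float:
    """Normalized common-ancestor-path distance between two terms, in [0, 1].

    Symmetric; 0 iff the two ids resolve to the same term; 1.0 for terms in
    disjoint components.  Uses the DAG's cached ``d_max`` (computing the
    ``depth_bound`` value on first use if none was set explicitly).
    """
    raw = dag.path_length(t1, t2)
    if raw is None:
        return 1.0
    if raw == 0:
        return 0.0
    d_max = dag.d_max
    if d_max == 0:  # degenerate single-component trivia; distance undefined
        return 1.0
    return min(raw / d_max, 1.0)


def neighbors_for_imprecision(dag: OntologyDAG, t: str) -> Set[str]:
    """Graph-adjacent terms of ``t``: its parents plus its children.

    These are the candidate replacements when simulating an imprecisely
    described phenotype.  Empty only for an isolated root with no children.
    """
    tid = dag.resolve(t)
    g = dag.graph
    out = set(g.successors(tid)) | set(g.predecessors(tid))
    out.discard(tid)
    return out


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialize a DAG back to a minimal OBO flat file (id/name/is_a tags)."""
    lines = ["format-version: 1.2", f"ontology: {dag.name}", ""]
    for tid in sorted(dag.terms):
        term = dag.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        for alt, canon in sorted(dag.aliases.items()):
            if canon == tid:
                lines.append(f"alt_id: {alt}")
        for p in term.parent_ids:
            lines.append(f"is_a: {p} ! {dag.terms[p].name}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
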