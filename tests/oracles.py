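"""Independent brute-force reference implementations used only by tests.

Everything here is written against plain dict/list structures (a parent map,
term/weight lists) and deliberately shares no code with the package: BFS over
an adjacency dict instead of networkx, explicit double loops instead of the
package's cached best-match helpers.
"""

from collections import deque
from typing import Dict, List, Optional, Sequence, Tuple


def ancestor_distances(parents: Dict[str, Sequence[str]], term: str) -> Dict[str, int]:
    """BFS up the parent map: ancestor -> shortest edge count (self at 0)."""
    out = {term: 0}
    queue = deque([term])
    while queue:
        cur = queue.popleft()
        for p in parents.get(cur, ()):
            if p not in out:
                out[p] = out[cur] + 1
                queue.append(p)
    return out


def pair_distance(parents: Dict[str, Sequence[str]], t1: str, t2: str) -> Optional[int]:
    """Min over common ancestors a of d(t1,a) + d(t2,a); None if no common ancestor."""
    d1 = ancestor_distances(parents, t1)
    d2 = ancestor_distances(parents, t2)
    common = set(d1) & set(d2)
    if not common:
        return None
    return min(d1[a] + d2[a] for a in common)


def exact_d_max(parents: Dict[str, Sequence[str]]) -> int:
    terms = sorted(parents)
    best = 0
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            d = pair_distance(parents, a, b)
            if d is not None and d > best:
                best = d
    return best


def normalized_distance(parents, t1, t2, d_max) -> float:
    raw = pair_distance(parents, t1, t2)
    if raw is None:
        return 1.0
    if raw == 0:
        return 0.0
    return min(raw / d_max, 1.0)


def weighted_disease_distance(
    parents: Dict[str, Sequence[str]],
    d_max: int,
    terms1: Sequence[str],
    weights1: Sequence[float],
    terms2: Sequence[str],
    weights2: Sequence[float],
) -> float:
    """Direct transcription of the weighted two-way best-match average.

    For each term of one disease, all cross-pair distances are enumerated,
    the minimum taken, ties broken toward the larger opposing weight.
    """

    def direction(ts, ws, other_ts, other_ws):
        total = 0.0
        for t, w in zip(ts, ws):
            pairs = [
                (normalized_distance(parents, t, o, d_max), ow)
                for o, ow in zip(other_ts, other_ws)
            ]
            dmin = min(p[0] for p in pairs)
            wstar = max(ow for dd, ow in pairs if abs(dd - dmin) <= 1e-15)
            total += dmin * w * wstar
        return total / len(ts)

    return 0.5 * (
        direction(terms1, weights1, terms2, weights2)
        + direction(terms2, weights2, terms1, weights1)
    )


def unweighted_two_way_best_match(matrix: List[List[float]]) -> float:
    """1/2 (mean of row minima + mean of column minima) of a cost matrix."""
    row_min = [min(row) for row in matrix]
    col_min = [min(matrix[i][j] for i in range(len(matrix))) for j in range(len(matrix[0]))]
    return 0.5 * (sum(row_min) / len(row_min) + sum(col_min) / len(col_min))


def gene_pair_distance(
    go_parents: Dict[str, Dict[str, Sequence[str]]],
    go_d_max: Dict[str, int],
    ann1: Dict[str, Sequence[str]],
    ann2: Dict[str, Sequence[str]],
) -> float:
    """Mean over aspects of the minimum cross-pair term distance; 1.0 if absent."""
    parts = []
    for aspect in ("cc", "mf", "bp"):
        t1, t2 = ann1.get(aspect, ()), ann2.get(aspect, ())
        if not t1 or not t2:
            parts.append(1.0)
            continue
        parts.append(min(
            normalized_distance(go_parents[aspect], a, b, go_d_max[aspect])
            for a in t1 for b in t2
        ))
    return sum(parts) / 3.0


def parents_of_dag(dag) -> Dict[str, Tuple[str, ...]]:
    """Extract a plain parent map from an OntologyDAG (fixture convenience)."""
    return {t.id: tuple(t.parent_ids) for t in dag.terms.values()}
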