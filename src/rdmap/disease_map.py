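"""From a distance matrix to a navigable 2-D disease map.

The embedding is classical (Torgerson) multidimensional scaling: square the
distances, double-center, eigendecompose, and scale the leading eigenvectors
by the square roots of their eigenvalues.  Disease distances built from
weighted best-match averages are not Euclidean, so negative eigenvalues are
expected; they are clamped to zero and their mass is reported as a
map-quality diagnostic.

Clusters come from k-means on the 2-D coordinates.  The number of clusters k
is chosen by bootstrap stability: for each candidate k, the data are
resampled with replacement B times and re-clustered, and each original
cluster's stability is the mean, over replicates, of its best Jaccard overlap
with the bootstrap clusters (computed on the unique resampled points).  The
selected k is the largest candidate whose least stable cluster still reaches
the stability threshold; when no candidate does, the k with the highest mean
stability is returned and flagged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .distances import DistanceMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MapEmbedding",
    "ClusterOverlap",
    "classical_mds",
    "kmeans_cluster",
    "select_k_bootstrap",
    "cluster_overlap",
    "build_map",
]

# With the "largest k whose least stable cluster still passes" rule, the
# threshold must sit at the conventional "highly stable" mark: bootstrap
# Jaccard stability of an arbitrary split of homogeneous data already hovers
# around 0.6-0.75, so a lower bar over-segments every structured dataset.
DEFAULT_STABILITY_THRESHOLD = 0.85


@dataclass
class MapEmbedding:
    """2-D coordinates plus cluster labels and their bootstrap stabilities."""

    ids: List[str]
    coords: np.ndarray
    cluster_labels: np.ndarray
    k: int
    stability: Dict[int, float]
    eigenvalues: np.ndarray
    negative_eigenvalue_mass: float = 0.0
    k_selection_fallback: bool = False
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
        n = len(self.ids)
        if self.coords.shape[0] != n or self.cluster_labels.shape[0] != n:
            raise ValidationError("ids, coords and labels must have equal length")
        occupied = set(np.unique(self.cluster_labels).tolist())
        if occupied != set(range(self.k)):
            raise ValidationError(
                f"cluster labels {sorted(occupied)} do not occupy 0..{self.k - 1}"
            )

    def to_json(self, path, diseases=None) -> None:
        """Serialize per-disease points and the per-cluster stability table."""
        points = []
        for i, did in enumerate(self.ids):
            rec = diseases.get(did) if diseases else None
            points.append({
                "id": did,
                "name": rec.name if rec else did,
                "x": float(self.coords[i, 0]),
                "y": float(self.coords[i, 1]),
                "cluster": int(self.cluster_labels[i]),
                "prevalence_class": rec.prevalence_class if rec else "unknown",
            })
        sizes = np.bincount(self.cluster_labels, minlength=self.k)
        clusters = [
            {"cluster": c, "size": int(sizes[c]), "stability": self.stability.get(c)}
            for c in range(self.k)
        ]
        payload = {
            "points": points,
            "clusters": clusters,
            "k": self.k,
            "k_selection_fallback": self.k_selection_fallback,
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "negative_eigenvalue_mass": self.negative_eigenvalue_mass,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class ClusterOverlap:
    """Cross-tabulation of cluster labels over diseases shared by two maps."""

    flows: List[Tuple[int, int, int]]

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.flows)


# ---------------------------------------------------------------------------
# classical multidimensional scaling
# ---------------------------------------------------------------------------

def classical_mds(
    dm, dims: int = 2
) -> Tuple[np.ndarray, np.ndarray, float]:
    """Torgerson scaling of a distance matrix.

    Returns ``(coords, eigenvalues, negative_mass)`` where ``coords`` is
    ``n x dims``, ``eigenvalues`` holds all n eigenvalues of the
    double-centered matrix in descending order, and ``negative_mass`` is
    ``sum(|negative eigenvalues|) / sum(|eigenvalues|)`` — 0 for exactly
    Euclidean input, growing as the distances deviate from embeddability.

    Deterministic up to reflection; the sign of each axis is fixed so that
    the coordinate of largest magnitude on that axis is positive.
    """
    D = np.asarray(dm.values if isinstance(dm, DistanceMatrix) else dm, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    if not np.allclose(D, D.T) or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    if dims < 1:
        raise ValidationError("dims must be >= 1")

    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0  # symmetrize against round-off
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    total = np.abs(eigvals).sum()
    negative_mass = float(np.abs(eigvals[eigvals < 0]).sum() / total) if total > 0 else 0.0

    if total == 0:
        logger.warning("all-zero distance matrix: degenerate embedding at the origin")
        return np.zeros((n, dims)), eigvals, 0.0

    positive = eigvals > 1e-12
    rank = int(positive.sum())
    if dims > rank:
        logger.warning(
            "requested %d dimensions but positive rank is %d; padding with zeros",
            dims, rank,
        )
    coords = np.zeros((n, dims))
    use = min(dims, rank)
    coords[:, :use] = eigvecs[:, :use] * np.sqrt(eigvals[:use])
    for j in range(use):  # reflection-invariant sign convention
        col = coords[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, j] = -col
    return coords, eigvals, negative_mass


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def kmeans_cluster(
    coords: np.ndarray, k: int, seed: int = 0, restarts: int = 10
) -> np.ndarray:
    """Best-of-``restarts`` k-means labels; deterministic given the seed."""
    coords = np.asarray(coords, dtype=float)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > coords.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of points {coords.shape[0]}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(coords)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def select_k_bootstrap(
    coords: np.ndarray,
    k_range: Sequence[int],
    B: int = 20,
    seed: int = 0,
    restarts: int = 10,
    threshold: float = DEFAULT_STABILITY_THRESHOLD,
) -> Tuple[int, pd.DataFrame, bool]:
    """Bootstrap-stability selection of the cluster count.

    Returns ``(selected_k, table, fallback)``; ``table`` has one row per
    (k, cluster) with the cluster's mean bootstrap Jaccard stability, and
    ``fallback`` is True when no candidate k met the threshold and the k
    with the highest mean stability was returned instead.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValidationError("empty k range")
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValidationError(f"k range {k_range} outside [2, {n - 1}]")
    if B < 2:
        raise ValidationError("need at least 2 bootstrap replicates")

    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        base_seed = int(rng.integers(0, 2**31 - 1))
        orig = kmeans_cluster(coords, k, seed=base_seed, restarts=restarts)
        orig_sets = [set(np.flatnonzero(orig == c).tolist()) for c in range(k)]
        sums = np.zeros(k)
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            uniq = set(idx.tolist())
            boot_seed = int(rng.integers(0, 2**31 - 1))
            boot = kmeans_cluster(coords[idx], k, seed=boot_seed, restarts=restarts)
            boot_sets = [
                {int(idx[i]) for i in np.flatnonzero(boot == c)} for c in range(k)
            ]
            for c in range(k):
                restricted = orig_sets[c] & uniq
                sums[c] += max(_jaccard(restricted, bs) for bs in boot_sets)
        for c in range(k):
            rows.append({"k": k, "cluster": c, "stability": sums[c] / B})

    table = pd.DataFrame(rows)
    per_k = table.groupby("k")["stability"]
    passing = [k for k in k_range if per_k.min()[k] >= threshold]
    if passing:
        selected, fallback = max(passing), False
    else:
        selected, fallback = int(per_k.mean().idxmax()), True
        logger.warning(
            "no k in %s reaches min stability %.2f; falling back to k=%d "
            "(highest mean stability)", k_range, threshold, selected,
        )
    return selected, table, fallback


def cluster_overlap(map_p: MapEmbedding, map_g: MapEmbedding) -> ClusterOverlap:
    """Contingency flows between two maps' clusters over their shared diseases."""
    shared = sorted(set(map_p.ids) & set(map_g.ids))
    if not shared:
        raise ValidationError("the two maps share no disease ids")
    lp = {d: int(map_p.cluster_labels[map_p.ids.index(d)]) for d in shared}
    lg = {d: int(map_g.cluster_labels[map_g.ids.index(d)]) for d in shared}
    tab = pd.crosstab(
        pd.Series([lp[d] for d in shared], name="cluster_p"),
        pd.Series([lg[d] for d in shared], name="cluster_g"),
    )
    flows = [
        (int(a), int(b), int(tab.loc[a, b]))
        for a in tab.index for b in tab.columns
        if tab.loc[a, b] > 0
    ]
    return ClusterOverlap(flows=flows)


def build_map(
    dm: DistanceMatrix,
    k_range: Sequence[int] = range(2, 9),
    B: int = 20,
    seed: int = 0,
    restarts: int = 10,
    threshold: float = DEFAULT_STABILITY_THRESHOLD,
    k: Optional[int] = None,
) -> MapEmbedding:
    """Distance matrix -> 2-D embedding with stability-selected clusters.

    Pass ``k`` to skip selection and cluster with a fixed count (its
    stability is still estimated by the bootstrap for the report).
    """
    coords, eigvals, neg_mass = classical_mds(dm, dims=2)
    rng = np.random.default_rng(seed)
    sel_seed = int(rng.integers(0, 2**31 - 1))
    km_seed = int(rng.integers(0, 2**31 - 1))
    if k is None:
        k_sel, table, fallback = select_k_bootstrap(
            coords, k_range, B=B, seed=sel_seed, restarts=restarts, threshold=threshold
        )
    else:
        k_sel, fallback = int(k), False
        _, table, _ = select_k_bootstrap(
            coords, [k_sel], B=B, seed=sel_seed, restarts=restarts, threshold=threshold
        )
    labels = kmeans_cluster(coords, k_sel, seed=km_seed, restarts=restarts)
    stab = (
        table[table["k"] == k_sel].set_index("cluster")["stability"].to_dict()
    )
    return MapEmbedding(
        ids=list(dm.ids),
        coords=coords,
        cluster_labels=labels,
        k=k_sel,
        stability={int(c): float(s) for c, s in stab.items()},
        eigenvalues=eigvals,
        negative_eigenvalue_mass=neg_mass,
        k_selection_fallback=fallback,
        seed=seed,
    )
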