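"""Pearson-distance UPGMA clustering of RSCU vectors.

Genomes are compared by the Pearson correlation r of their 59-dimensional
RSCU vectors and placed in a distance matrix d = (1 - r) * 100, so d ranges
over [0, 200] with d = 0 iff perfectly correlated usage. The matrix is
clustered by UPGMA (unweighted pair group method with arithmetic mean):
repeatedly merge the closest pair of clusters, with inter-cluster distance
the size-weighted arithmetic mean of cross-pair leaf distances, and merge
height half the merging distance (so cophenetic distance = 2 * height and
the tree is ultrametric).

Agreement between the tree cut into k groups and externally supplied
genomic cluster labels is scored with the Fowlkes-Mallows index.

UPGMA is written out here rather than delegated because deterministic
tie-breaking (lexicographically smallest id pair) is part of the contract;
tests cross-check it against scipy's average linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import fowlkes_mallows_score

from .codon_metrics import RscuVector

MIN_SHARED_POSITIONS = 3


@dataclass
class DistanceMatrix:
    """Symmetric d = (1 - r) * 100 matrix over genome RSCU vectors."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal not zero")


@dataclass
class Dendrogram:
    """UPGMA tree as an ordered merge list.

    Nodes 0..n-1 are the leaves (in ``leaves`` order); node n+i is the
    cluster created by ``merges[i] = (left, right, height)``. Heights are
    half-distances and non-decreasing along the merge order.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValueError(f"{n} leaves need {n - 1} merges, got {len(self.merges)}")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights not non-decreasing (not ultrametric)")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def members(self) -> list[list[int]]:
        """Leaf indices under every node (leaves first, then merge order)."""
        out: list[list[int]] = [[i] for i in range(self.n_leaves)]
        for left, right, _ in self.merges:
            out.append(out[left] + out[right])
        return out


def pearson_r(u: RscuVector, v: RscuVector) -> float:
    """Pearson correlation over positions defined in both vectors.

    Positions undefined in either vector (absent amino acid) are dropped
    pairwise-complete; at least 3 shared positions are required. A vector
    with zero variance over the shared positions raises, naming both ids.
    """
    shared = ~(u.undefined_mask | v.undefined_mask)
    if shared.sum() < MIN_SHARED_POSITIONS:
        raise ValueError(
            f"fewer than {MIN_SHARED_POSITIONS} shared defined RSCU positions "
            f"between {u.source_id!r} and {v.source_id!r}"
        )
    a = u.values[shared]
    b = v.values[shared]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError(
            f"zero RSCU variance in pair ({u.source_id!r}, {v.source_id!r})"
        )
    r = float(np.corrcoef(a, b)[0, 1])
    return min(max(r, -1.0), 1.0)


def distance_matrix(cohort: list[RscuVector]) -> DistanceMatrix:
    """Pairwise d = (1 - r) * 100 over a cohort of RSCU vectors."""
    if len(cohort) < 2:
        raise ValueError("need at least 2 genomes for a distance matrix")
    ids = [v.source_id for v in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate source ids in cohort")
    n = len(cohort)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                r = pearson_r(cohort[i], cohort[j])
            except ValueError as exc:
                raise ValueError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            d[i, j] = d[j, i] = (1.0 - r) * 100.0
    return DistanceMatrix(ids=ids, d=d)


def upgma(m: DistanceMatrix) -> Dendrogram:
    """Classical UPGMA with deterministic lexicographic tie-breaking.

    Among equal minimal inter-cluster distances the pair whose
    (lexicographically smallest member ids) sort first is merged. Merge
    height is half the merging distance.
    """
    n = len(m.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    # active cluster state: node index -> (size, representative id)
    active: dict[int, tuple[int, str]] = {
        i: (1, m.ids[i]) for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = m.d[i, j]
    merges: list[tuple[int, int, float]] = []
    next_node = n
    while len(active) > 1:
        best: tuple[int, int] | None = None
        best_d = np.inf
        for (i, j), dij in dist.items():
            if dij < best_d - 1e-12:
                best, best_d = (i, j), dij
            elif abs(dij - best_d) <= 1e-12 and best is not None:
                key_new = tuple(sorted((active[i][1], active[j][1])))
                key_old = tuple(sorted((active[best[0]][1], active[best[1]][1])))
                if key_new < key_old:
                    best = (i, j)
        assert best is not None
        i, j = best
        size_i, rep_i = active[i]
        size_j, rep_j = active[j]
        merges.append((i, j, best_d / 2.0))
        new = next_node
        next_node += 1
        # size-weighted average distance to every other active cluster
        for k in active:
            if k in (i, j):
                continue
            d_ik = dist[tuple(sorted((i, k)))]
            d_jk = dist[tuple(sorted((j, k)))]
            dist[(k, new) if k < new else (new, k)] = (
                size_i * d_ik + size_j * d_jk
            ) / (size_i + size_j)
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        del active[i], active[j]
        active[new] = (size_i + size_j, min(rep_i, rep_j))
    return Dendrogram(leaves=list(m.ids), merges=merges)


def node_heights(t: Dendrogram) -> list[float]:
    """Height of every node (0 for leaves, merge height for internal)."""
    return [0.0] * t.n_leaves + [h for _, _, h in t.merges]


def to_newick(t: Dendrogram) -> str:
    """Newick string with branch lengths; root-to-leaf path = top height."""
    heights = node_heights(t)

    def render(node: int, parent_height: float) -> str:
        if node < t.n_leaves:
            return f"{t.leaves[node]}:{parent_height - 0.0:g}"
        left, right, h = t.merges[node - t.n_leaves]
        inner = f"({render(left, h)},{render(right, h)})"
        return f"{inner}:{parent_height - h:g}"

    root = t.n_leaves + len(t.merges) - 1
    left, right, h = t.merges[-1]
    return f"({render(left, h)},{render(right, h)});"


def cophenetic(t: Dendrogram) -> DistanceMatrix:
    """Tree-implied leaf distances: 2x the height of the lowest common merge."""
    n = t.n_leaves
    d = np.zeros((n, n))
    members = t.members()
    for left, right, h in t.merges:
        for a in members[left]:
            for b in members[right]:
                d[a, b] = d[b, a] = 2.0 * h
    return DistanceMatrix(ids=list(t.leaves), d=d)


def cut_tree(t: Dendrogram, k: int) -> dict[str, int]:
    """Partition leaves into k groups by undoing the last k-1 merges."""
    n = t.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(n + len(t.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (left, right, _) in enumerate(t.merges[: n - k]):
        node = n + idx
        parent[find(left)] = node
        parent[find(right)] = node
    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in range(n):
        root = find(leaf)
        labels[t.leaves[leaf]] = roots.setdefault(root, len(roots))
    return labels


def concordance(t: Dendrogram, labels: dict[str, str], k: int) -> float:
    """Fowlkes-Mallows index between a k-cut of the tree and external labels."""
    missing = [leaf for leaf in t.leaves if leaf not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing[:5]}")
    if not (2 <= k <= t.n_leaves):
        raise ValueError(f"k must be in [2, {t.n_leaves}], got {k}")
    cut = cut_tree(t, k)
    true = [labels[leaf] for leaf in t.leaves]
    pred = [cut[leaf] for leaf in t.leaves]
    return float(fowlkes_mallows_score(true, pred))
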