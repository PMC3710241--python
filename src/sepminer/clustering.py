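"""Grouping side-effect terms into Term Clusters (TCs).

Terms are compared with the structural semantic similarity of
:mod:`sepminer.hierarchy`, agglomerated with Ward's method on the distance
1 - similarity, and the dendrogram is cut at the level selected by the
Kelley-Gardner-Sutcliffe penalty.  Each resulting cluster is named
``{index}_{representative label}`` where the representative is the cluster
medoid.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, leaves_list, linkage
from scipy.spatial.distance import squareform

from .hierarchy import TermHierarchy, similarity_matrix


class ClusteringError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TermCluster:
    index: int
    representative: str  # term id
    representative_label: str
    members: frozenset[str]

    @property
    def size(self) -> int:
        """Cluster size k_i — drives the association threshold n_i."""
        return len(self.members)

    @property
    def name(self) -> str:
        return f"{self.index}_{self.representative_label}"


@dataclasses.dataclass
class TermClustering:
    """Partition of a term set into indexed, named term clusters."""

    clusters: list[TermCluster]
    hierarchy: TermHierarchy | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if c.members & seen:
                raise ClusteringError("clusters are not pairwise disjoint")
            seen |= c.members
        self._by_index = {c.index: c for c in self.clusters}
        self._term_to_cluster = {t: c.index for c in self.clusters for t in c.members}

    @property
    def term_universe(self) -> set[str]:
        return set(self._term_to_cluster)

    def __len__(self) -> int:
        return len(self.clusters)

    def __getitem__(self, index: int) -> TermCluster:
        return self._by_index[index]

    def cluster_of(self, term: str) -> int | None:
        return self._term_to_cluster.get(term)

    @classmethod
    def from_plan(
        cls,
        member_sets: Sequence[Iterable[str]],
        representatives: Sequence[str] | None = None,
        hierarchy: TermHierarchy | None = None,
    ) -> "TermClustering":
        """Build a clustering directly from given member sets (1-based indices)."""
        clusters = []
        for i, members in enumerate(member_sets, start=1):
            members = frozenset(members)
            rep = representatives[i - 1] if representatives else min(members)
            label = hierarchy.label(rep) if hierarchy else rep
            clusters.append(TermCluster(i, rep, label, members))
        return cls(clusters, hierarchy)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("tc_index\trepresentative\tmember_term\n")
            for c in self.clusters:
                for t in sorted(c.members):
                    fh.write(f"{c.index}\t{c.representative}\t{t}\n")

    @classmethod
    def from_tsv(cls, path: str, hierarchy: TermHierarchy | None = None) -> "TermClustering":
        members: dict[int, set[str]] = {}
        reps: dict[int, str] = {}
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                idx, rep, term = line.split("\t")
                members.setdefault(int(idx), set()).add(term)
                reps[int(idx)] = rep
        clusters = []
        for idx in sorted(members):
            rep = reps[idx]
            label = hierarchy.label(rep) if hierarchy else rep
            clusters.append(TermCluster(idx, rep, label, frozenset(members[idx])))
        return cls(clusters, hierarchy)


# ------------------------------------------------------------------ clustering
def ward_cluster(dist: np.ndarray) -> np.ndarray:
    """Ward agglomeration of a symmetric distance matrix.

    Returns the scipy linkage matrix (ordered merges with non-decreasing
    heights, Lance-Williams recurrence on squared distances).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ClusteringError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ClusteringError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ClusteringError("distance matrix must have a zero diagonal")
    return linkage(squareform(dist, checks=False), method="ward")


def kgs_penalties(Z: np.ndarray, dist: np.ndarray) -> dict[int, float]:
    """Kelley-Gardner-Sutcliffe penalty at every interior cut level.

    At the level with k clusters the spread is the mean, over clusters of
    size >= 2, of the average within-cluster pairwise distance.  Spreads are
    min-max normalized onto [1, n-2] across levels and k is added.
    """
    n = dist.shape[0]
    if n < 3:
        raise ClusteringError("need at least 3 points to select a cut level")
    ks = list(range(2, n))
    cuts = cut_tree(Z, n_clusters=ks)  # shape (n, len(ks))
    spreads = []
    for col, k in enumerate(ks):
        labels = cuts[:, col]
        vals = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            if len(idx) < 2:
                continue
            sub = dist[np.ix_(idx, idx)]
            m = len(idx)
            vals.append(sub.sum() / (m * (m - 1)))
        spreads.append(float(np.mean(vals)) if vals else 0.0)
    spreads = np.asarray(spreads)
    lo, hi = spreads.min(), spreads.max()
    if hi > lo:
        norm = (n - 3) * (spreads - lo) / (hi - lo) + 1.0
    else:
        norm = np.ones_like(spreads)
    return {k: float(norm[i] + k) for i, k in enumerate(ks)}


def select_k(Z: np.ndarray, dist: np.ndarray) -> int:
    """Cut level minimizing the KGS penalty; ties resolved toward smaller k."""
    pen = kgs_penalties(Z, dist)
    best = min(pen.items(), key=lambda kv: (kv[1], kv[0]))
    return best[0]


def build_term_clusters(
    terms: Sequence[str],
    h: TermHierarchy,
    k: int | None = None,
) -> TermClustering:
    """Cluster ``terms`` with Ward on 1 - similarity and cut at k (or auto).

    Cluster indices 1..k follow dendrogram leaf order; the representative of
    each cluster is its medoid (maximal average similarity to co-members,
    ties to the lexicographically smallest label).
    """
    terms = list(terms)
    unknown = [t for t in terms if t not in h.labels]
    if unknown:
        raise ClusteringError(f"terms not in the hierarchy: {unknown[:5]}")
    n = len(terms)
    if k is not None and not (1 <= k <= n):
        raise ClusteringError(f"k={k} outside 1..{n}")
    if k == n or n == 1:
        clusters = [
            TermCluster(i, t, h.label(t), frozenset([t]))
            for i, t in enumerate(terms, start=1)
        ]
        return TermClustering(clusters, h)
    sim = similarity_matrix(h, terms)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = ward_cluster(dist)
    if k is None:
        k = select_k(Z, dist)
    labels = cut_tree(Z, n_clusters=k).ravel()
    # order clusters by first appearance in the dendrogram leaf order
    order = leaves_list(Z)
    seen: list[int] = []
    for leaf in order:
        lab = labels[leaf]
        if lab not in seen:
            seen.append(lab)
    clusters = []
    for new_index, lab in enumerate(seen, start=1):
        idx = np.flatnonzero(labels == lab)
        members = [terms[i] for i in idx]
        if len(idx) == 1:
            rep = members[0]
        else:
            sub = sim[np.ix_(idx, idx)]
            avg = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
            best = max(
                range(len(idx)),
                key=lambda i: (avg[i], ),
            )
            # break exact ties toward the lexicographically smallest label
            best_avg = avg[best]
            tied = [i for i in range(len(idx)) if np.isclose(avg[i], best_avg)]
            rep = min((h.label(members[i]), members[i]) for i in tied)[1]
        clusters.append(TermCluster(new_index, rep, h.label(rep), frozenset(members)))
    return TermClustering(clusters, h)
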