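"""DAG-shaped side-effect term hierarchy (MedDRA-like).

Terms are arranged in a rooted directed acyclic graph whose edges carry an
``is_a`` or ``part_of`` label.  Depth of a term is the shortest edge count to
the nearest root; the structural semantic similarity used for term clustering
is computed from these depths.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict, deque
from typing import Iterable

RELATION_TYPES = frozenset({"is_a", "part_of"})


class HierarchyError(ValueError):
    pass


@dataclasses.dataclass
class TermHierarchy:
    """Term set plus (child, parent, relation_type) edges."""

    labels: dict[str, str]
    edges: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        self._parents: dict[str, list[str]] = defaultdict(list)
        self._children: dict[str, list[str]] = defaultdict(list)
        for child, parent, rel in self.edges:
            if rel not in RELATION_TYPES:
                raise HierarchyError(f"invalid relation type {rel!r}")
            for t in (child, parent):
                if t not in self.labels:
                    raise HierarchyError(f"edge mentions unknown term {t!r}")
            self._parents[child].append(parent)
            self._children[parent].append(child)
        self._check_acyclic()
        self._depth = self._compute_depths()
        self._anc_cache: dict[str, frozenset[str]] = {}

    # ------------------------------------------------------------- structure
    @property
    def terms(self) -> set[str]:
        return set(self.labels)

    @property
    def roots(self) -> list[str]:
        return sorted(t for t in self.labels if not self._parents.get(t))

    def label(self, term: str) -> str:
        return self.labels[term]

    def parents(self, term: str) -> list[str]:
        return list(self._parents.get(term, ()))

    def children(self, term: str) -> list[str]:
        return list(self._children.get(term, ()))

    def leaves(self) -> list[str]:
        return sorted(t for t in self.labels if not self._children.get(t))

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def dfs(node: str) -> None:
            state[node] = 1
            for p in self._parents.get(node, ()):
                if state.get(p) == 1:
                    raise HierarchyError(f"hierarchy has a cycle through {p!r}")
                if p not in state:
                    dfs(p)
            state[node] = 2

        for t in self.labels:
            if t not in state:
                dfs(t)

    def _compute_depths(self) -> dict[str, int]:
        # BFS from the roots over child edges: shortest distance to any root
        depth = {r: 0 for r in self.roots}
        if not depth:
            raise HierarchyError("hierarchy has no root")
        queue = deque(depth)
        while queue:
            node = queue.popleft()
            for c in self._children.get(node, ()):
                if c not in depth:
                    depth[c] = depth[node] + 1
                    queue.append(c)
        missing = set(self.labels) - set(depth)
        if missing:
            raise HierarchyError(f"terms unreachable from any root: {sorted(missing)[:5]}")
        return depth

    def depth(self, term: str) -> int:
        """Shortest edge count from the nearest root."""
        self._require(term)
        return self._depth[term]

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable via parent edges, including the term itself."""
        self._require(term)
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        stack = [term]
        while stack:
            for p in self._parents.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        result = frozenset(out)
        self._anc_cache[term] = result
        return result

    def _require(self, term: str) -> None:
        if term not in self.labels:
            raise HierarchyError(f"unknown term {term!r}")

    # -------------------------------------------------------------------- IO
    @classmethod
    def from_tsv(cls, path: str, labels: dict[str, str] | None = None) -> "TermHierarchy":
        """Read (child_id, parent_id, relation_type) rows; header required."""
        edges = []
        term_ids: set[str] = set()
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                child, parent, rel = line.split("\t")
                edges.append((child, parent, rel))
                term_ids.update((child, parent))
        lab = dict(labels) if labels else {}
        for t in term_ids:
            lab.setdefault(t, t)
        return cls(labels=lab, edges=edges)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("child_id\tparent_id\trelation_type\n")
            for child, parent, rel in self.edges:
                fh.write(f"{child}\t{parent}\t{rel}\n")

    @classmethod
    def from_obo(cls, path: str) -> "TermHierarchy":
        """Read an OBO ontology (is_a and part_of edges) via obonet."""
        import obonet  # optional reader

        graph = obonet.read_obo(path)
        labels = {n: d.get("name", n) for n, d in graph.nodes(data=True)}
        edges = []
        for child, parent, key in graph.edges(keys=True):
            rel = "is_a" if key == "is_a" else ("part_of" if key == "part_of" else None)
            if rel:
                edges.append((child, parent, rel))
        return cls(labels=labels, edges=edges)


def semantic_similarity(h: TermHierarchy, a: str, b: str) -> float:
    """Structural similarity in [0, 1] (Wu–Palmer generalized to a DAG).

    sim(a, b) = 2 d(c*) / (d(a) + d(b)) where c* is the common ancestor with
    maximal depth and d is the shortest edge count to the nearest root.
    sim(t, t) = 1 by convention (covers the root/root case).
    """
    h._require(a)
    h._require(b)
    if a == b:
        return 1.0
    common = h.ancestors(a) & h.ancestors(b)
    denom = h.depth(a) + h.depth(b)
    if not common or denom == 0:
        return 0.0
    best = max(h.depth(c) for c in common)
    return 2.0 * best / denom


def similarity_matrix(h: TermHierarchy, terms: Iterable[str]):
    """Dense pairwise similarity matrix over ``terms`` (given order)."""
    import numpy as np

    terms = list(terms)
    n = len(terms)
    depths = np.array([h.depth(t) for t in terms], dtype=float)
    anc = [h.ancestors(t) for t in terms]
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            common = anc[i] & anc[j]
            denom = depths[i] + depths[j]
            if common and denom > 0:
                best = max(h._depth[c] for c in common)
                sim[i, j] = sim[j, i] = 2.0 * best / denom
    return sim
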