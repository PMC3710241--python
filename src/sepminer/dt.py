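"""Binary-split decision trees over single-table drug descriptors.

Each drug in a learning set is encoded as a row of nominal/binary attributes:
one indicator per drug category, three per target (activation, inhibition,
other) and one per structural-cluster membership.  Trees are grown top-down
with the gain-ratio criterion restricted to binary (value vs rest) tests,
children below ``min_leaf`` rows are not considered, and the grown tree is
simplified by bottom-up pessimistic-error pruning at confidence ``cf``.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kb import KnowledgeBase

POS, NEG = "pos", "neg"


@dataclasses.dataclass
class AttributeTable:
    """Rows = learning-set drugs; one class column plus nominal attributes."""

    frame: pd.DataFrame
    class_col: str = "class"

    def __post_init__(self) -> None:
        if self.class_col not in self.frame.columns:
            raise ValueError(f"missing class column {self.class_col!r}")
        if self.frame[self.class_col].isna().any():
            raise ValueError("missing class labels")

    @property
    def attributes(self) -> list[str]:
        return [c for c in self.frame.columns if c != self.class_col]

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index_label="drug_id")

    def to_arff(self, path: str, relation: str = "sep_dataset") -> None:
        """Write the table in plain-text ARFF (all attributes nominal)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"@relation {relation}\n\n")
            for col in self.frame.columns:
                values = sorted(map(str, pd.unique(self.frame[col])))
                fh.write(f"@attribute {col} {{{','.join(values)}}}\n")
            fh.write("\n@data\n")
            for _, row in self.frame.iterrows():
                fh.write(",".join(map(str, row.tolist())) + "\n")


def build_attribute_table(
    kb: KnowledgeBase,
    positives: Sequence[str],
    negatives: Sequence[str],
) -> AttributeTable:
    """Single-table encoding of a learning set from the knowledge base."""
    drugs = list(positives) + list(negatives)
    missing = [d for d in drugs if d not in kb.drugs]
    if missing:
        raise ValueError(f"drugs absent from the knowledge base: {missing[:5]}")
    categories = sorted(kb.categories)
    targets = sorted({a.args[1] for a in kb.facts if a.predicate == "drug_has_target"})
    clusters = sorted(kb.clusters)

    cat_of: dict[str, set[str]] = {}
    act_of: dict[str, set[tuple[str, str]]] = {}
    clu_of: dict[str, set[tuple[str, str]]] = {}
    for a in kb.facts:
        if a.predicate == "category":
            cat_of.setdefault(a.args[0], set()).add(a.args[1])
        elif a.predicate == "drug_has_target":
            act_of.setdefault(a.args[0], set()).add((a.args[1], a.args[2]))
        elif a.predicate == "drug_cluster":
            clu_of.setdefault(a.args[0], set()).add((a.args[1], a.args[2]))

    columns = (
        [f"cat_{c}" for c in categories]
        + [f"{t}_{suffix}" for t in targets
           for suffix in ("activation", "inhibition", "other")]
        + [f"clu_{src}_{lab}" for lab, src in clusters]
    )
    action_map = {"activation": "activator", "inhibition": "inhibitor", "other": "other"}
    data = np.zeros((len(drugs), len(columns)), dtype="int8")
    col_idx = {c: i for i, c in enumerate(columns)}
    for r, d in enumerate(drugs):
        for c in cat_of.get(d, ()):
            data[r, col_idx[f"cat_{c}"]] = 1
        for t, action in act_of.get(d, ()):
            for suffix, act in action_map.items():
                if action == act:
                    data[r, col_idx[f"{t}_{suffix}"]] = 1
        for lab, src in clu_of.get(d, ()):
            data[r, col_idx[f"clu_{src}_{lab}"]] = 1
    frame = pd.DataFrame(data, index=drugs, columns=columns)
    frame.insert(0, "class", [POS] * len(positives) + [NEG] * len(negatives))
    return AttributeTable(frame)


# ------------------------------------------------------------------ tree model
@dataclasses.dataclass
class Node:
    """Internal binary test (attribute == value vs rest) or leaf."""

    counts: dict[str, int]
    attribute: str | None = None
    value: object | None = None
    eq_branch: "Node | None" = None
    ne_branch: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    @property
    def prediction(self) -> str:
        # majority class; deterministic tie-break toward NEG
        return max(sorted(self.counts), key=lambda c: (self.counts[c], c == NEG))

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.eq_branch.n_nodes() + self.ne_branch.n_nodes()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.prediction, "counts": self.counts}
        return {
            "attribute": self.attribute,
            "value": self.value,
            "counts": self.counts,
            "eq": self.eq_branch.to_dict(),
            "ne": self.ne_branch.to_dict(),
        }

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        if self.is_leaf:
            return f"{pad}-> {self.prediction} {self.counts}"
        return "\n".join([
            f"{pad}{self.attribute} == {self.value}?",
            self.eq_branch.render(indent + 1),
            f"{pad}{self.attribute} != {self.value}?",
            self.ne_branch.render(indent + 1),
        ])


@dataclasses.dataclass
class DecisionTree:
    root: Node
    min_leaf: int = 5
    cf: float = 0.25

    def predict(self, row: Mapping[str, object]) -> str:
        node = self.root
        while not node.is_leaf:
            if row.get(node.attribute) == node.value:
                node = node.eq_branch
            else:
                node = node.ne_branch  # missing attribute falls through here
        return node.prediction

    def predict_frame(self, frame: pd.DataFrame) -> list[str]:
        return [self.predict(row) for _, row in frame.iterrows()]

    def n_nodes(self) -> int:
        return self.root.n_nodes()

    def render(self) -> str:
        return self.root.render()

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.root.to_dict(), fh, indent=1)


def _entropy(counts: Sequence[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    ent = 0.0
    for c in counts:
        if c:
            p = c / total
            ent -= p * math.log2(p)
    return ent


def gain_ratio(labels: Sequence[str], mask: Sequence[bool]) -> float:
    """Information gain ratio of the binary partition given by ``mask``."""
    labels = list(labels)
    mask = list(mask)
    n = len(labels)
    classes = sorted(set(labels))
    parent = _entropy([labels.count(c) for c in classes])
    eq = [l for l, m in zip(labels, mask) if m]
    ne = [l for l, m in zip(labels, mask) if not m]
    child = 0.0
    for part in (eq, ne):
        child += len(part) / n * _entropy([part.count(c) for c in classes])
    gain = parent - child
    split_info = _entropy([len(eq), len(ne)])
    if split_info <= 0:
        return 0.0
    return gain / split_info


def _pessimistic_errors(errors: int, n: int, z: float) -> float:
    """Upper confidence limit on the error count (normal approximation)."""
    if n == 0:
        return 0.0
    f = errors / n
    ucl = (f + z * z / (2 * n)
           + z * math.sqrt(f * (1 - f) / n + z * z / (4 * n * n))) / (1 + z * z / n)
    return n * ucl


def learn_tree(
    table: AttributeTable,
    min_leaf: int = 5,
    cf: float = 0.25,
    prune: bool = True,
) -> DecisionTree:
    """Grow a binary-split gain-ratio tree, then prune pessimistically."""
    frame = table.frame
    labels = frame[table.class_col].tolist()
    attrs = table.attributes
    data = {a: frame[a].tolist() for a in attrs}

    def grow(idx: list[int]) -> Node:
        counts = {}
        for i in idx:
            counts[labels[i]] = counts.get(labels[i], 0) + 1
        node = Node(counts=counts)
        if len(counts) <= 1 or len(idx) < 2:
            return node
        best = None  # (ratio, attr position, value position)
        for a_pos, attr in enumerate(attrs):
            col = data[attr]
            values = sorted({col[i] for i in idx}, key=str)
            if len(values) < 2:
                continue
            if len(values) == 2:
                values = values[-1:]  # both tests give the same partition
            for v_pos, v in enumerate(values):
                mask = [col[i] == v for i in idx]
                n_eq = sum(mask)
                if n_eq < min_leaf or len(idx) - n_eq < min_leaf:
                    continue
                ratio = gain_ratio([labels[i] for i in idx], mask)
                if ratio > 0 and (best is None or ratio > best[0] + 1e-12):
                    best = (ratio, a_pos, v_pos, v)
        if best is None:
            return node
        _, a_pos, _, v = best
        attr = attrs[a_pos]
        eq_idx = [i for i in idx if data[attr][i] == v]
        ne_idx = [i for i in idx if data[attr][i] != v]
        node.attribute = attr
        node.value = v
        node.eq_branch = grow(eq_idx)
        node.ne_branch = grow(ne_idx)
        return node

    root = grow(list(range(len(labels))))
    if prune:
        z = float(norm.isf(cf))

        def prune_node(node: Node) -> float:
            leaf_err = _pessimistic_errors(
                node.n - node.counts.get(node.prediction, 0), node.n, z
            )
            if node.is_leaf:
                return leaf_err
            subtree_err = prune_node(node.eq_branch) + prune_node(node.ne_branch)
            if leaf_err <= subtree_err + 1e-12:
                node.attribute = None
                node.value = None
                node.eq_branch = None
                node.ne_branch = None
                return leaf_err
            return subtree_err

        prune_node(root)
    return DecisionTree(root, min_leaf=min_leaf, cf=cf)
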