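"""Drug x term-cluster binary fingerprints.

A drug is associated with term cluster TC_i when it is annotated with at
least n_i of the cluster's k_i member terms, where n_i grows with the cluster
size: k_i values are grouped into 5-term intervals and n_i ranges from 1 to 5
(1-5 -> 1, 6-10 -> 2, 11-15 -> 3, 16-20 -> 4, >= 21 -> 5 with the defaults).
Term clusters covering more than half of the drugs are dropped before itemset
mining.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import pandas as pd

from .clustering import TermClustering


@dataclasses.dataclass(frozen=True)
class AssociationConfig:
    """Size-dependent association threshold: n_i = min(n_max, ceil(k_i / interval_width))."""

    interval_width: int = 5
    n_max: int = 5

    def __post_init__(self) -> None:
        if self.interval_width < 1 or self.n_max < 1:
            raise ValueError("interval_width and n_max must be >= 1")


def min_se_count(k_i: int, cfg: AssociationConfig = AssociationConfig()) -> int:
    """Minimal number of member side effects required to assign a TC of size k_i."""
    if k_i < 1:
        raise ValueError(f"cluster size must be >= 1, got {k_i}")
    return min(cfg.n_max, math.ceil(k_i / cfg.interval_width))


@dataclasses.dataclass
class FingerprintTable:
    """Binary drug x TC table (rows: drug ids, columns: TC indices)."""

    frame: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)
    skipped_terms: int = 0

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates or self.frame.columns.has_duplicates:
            raise ValueError("duplicate row or column labels")
        vals = set(pd.unique(self.frame.values.ravel())) if self.frame.size else set()
        if not vals <= {0, 1}:
            raise ValueError("fingerprint entries must be 0/1")

    @property
    def drugs(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tcs(self) -> list:
        return list(self.frame.columns)

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index_label="drug_id")

    @classmethod
    def from_tsv(cls, path: str) -> "FingerprintTable":
        frame = pd.read_csv(path, sep="\t", index_col="drug_id")
        frame.columns = [int(c) if str(c).isdigit() else c for c in frame.columns]
        return cls(frame.astype("int8"))


def build_fingerprints(
    side_effects: Mapping[str, set],
    clustering: TermClustering,
    cfg: AssociationConfig = AssociationConfig(),
) -> FingerprintTable:
    """Apply the n_i-of-k_i association heuristic to every drug and TC.

    Annotation terms outside the clustering's term universe are ignored; the
    number skipped is recorded on the returned table.
    """
    if len(clustering) == 0:
        raise ValueError("empty clustering")
    universe = clustering.term_universe
    thresholds = {c.index: min_se_count(c.size, cfg) for c in clustering.clusters}
    drugs = list(side_effects)
    cols = [c.index for c in clustering.clusters]
    data = []
    skipped = 0
    for d in drugs:
        terms = set(side_effects[d])
        skipped += len(terms - universe)
        terms &= universe
        row = [
            1 if len(terms & clustering[i].members) >= thresholds[i] else 0
            for i in cols
        ]
        data.append(row)
    frame = pd.DataFrame(data, index=drugs, columns=cols, dtype="int8")
    prov = {"clustering_size": len(clustering), "config": dataclasses.asdict(cfg)}
    return FingerprintTable(frame, prov, skipped)


def filter_prevalent(table: FingerprintTable, fraction: float = 0.5) -> FingerprintTable:
    """Drop TC columns covering strictly more than ``fraction`` of the drugs."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(table.frame)
    keep = [c for c in table.frame.columns if table.frame[c].sum() <= fraction * n]
    prov = dict(table.provenance)
    prov["prevalence_fraction"] = fraction
    return FingerprintTable(table.frame[keep].copy(), prov, table.skipped_terms)
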