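"""Side-effect profiles as maximal frequent itemsets of term clusters.

A side-effect profile (SEP) is a maximal frequent itemset (MFI) over the
binary drug x TC table: a set of TCs shared by at least ``min_support`` drugs
none of whose proper supersets is frequent.  A direct consequence of
maximality is that two distinct MFIs cannot be jointly contained in more
drugs than the support threshold allows.

The miner is a vertical depth-first search on row bitsets with support
pruning; ``brute_force_mfis`` enumerates all itemsets and serves as the
exhaustive oracle on small tables.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from collections import Counter
from itertools import combinations
from typing import Sequence

from .fingerprints import FingerprintTable


@dataclasses.dataclass(frozen=True)
class MinerConfig:
    """Support threshold: absolute ``min_support`` wins over ``support_fraction``."""

    min_support: int | None = None
    support_fraction: float = 0.2
    prevalence_cutoff: float = 0.5

    def resolve_support(self, n_rows: int) -> int:
        if self.min_support is not None:
            if self.min_support < 1:
                raise ValueError("min_support must be >= 1")
            return self.min_support
        return max(1, math.ceil(self.support_fraction * n_rows))


@dataclasses.dataclass(frozen=True)
class SEP:
    """A side-effect profile: TC itemset, support, covered drug set."""

    id: str
    tcs: tuple
    support: int
    covered: frozenset[str] | None = None

    @property
    def length(self) -> int:
        return len(self.tcs)


def _sorted_seps(raw: list[tuple[tuple, frozenset]]) -> list[SEP]:
    """Fix output order (support desc, then lexicographic itemset) and id."""
    raw = sorted(raw, key=lambda it: (-len(it[1]), tuple(map(str, it[0]))))
    return [
        SEP(id=f"SEP_{i}", tcs=tcs, support=len(cov), covered=cov)
        for i, (tcs, cov) in enumerate(raw, start=1)
    ]


def mine_mfis(table: FingerprintTable, cfg: MinerConfig = MinerConfig()) -> list[SEP]:
    """Extract exactly the maximal frequent itemsets from the binary table."""
    frame = table.frame
    n, m = frame.shape
    if n == 0 or m == 0:
        return []
    minsup = cfg.resolve_support(n)
    if minsup > n:
        raise ValueError(f"min_support {minsup} exceeds the {n} rows")
    cols = list(frame.columns)
    mat = frame.to_numpy()
    bits = []
    for j in range(m):
        b = 0
        col = mat[:, j]
        for i in range(n):
            if col[i]:
                b |= 1 << i
        bits.append(b)
    rows = list(frame.index)
    full = (1 << n) - 1
    results: list[tuple[tuple, frozenset]] = []

    def is_maximal(itemset: tuple[int, ...], tid: int) -> bool:
        inset = set(itemset)
        for j in range(m):
            if j in inset:
                continue
            if (tid & bits[j]).bit_count() >= minsup:
                return False
        return True

    def dfs(start: int, itemset: tuple[int, ...], tid: int) -> None:
        if itemset and is_maximal(itemset, tid):
            cov = frozenset(rows[i] for i in range(n) if tid >> i & 1)
            results.append((tuple(cols[j] for j in itemset), cov))
        for j in range(start, m):
            t = tid & bits[j]
            if t.bit_count() >= minsup:
                dfs(j + 1, itemset + (j,), t)

    dfs(0, (), full)
    return _sorted_seps(results)


def brute_force_mfis(table: FingerprintTable, cfg: MinerConfig = MinerConfig()) -> list[SEP]:
    """Exhaustive MFI enumeration over all 2^m itemsets (oracle; m <= 20)."""
    frame = table.frame
    n, m = frame.shape
    if m > 20:
        raise ValueError(f"brute force limited to 20 columns, got {m}")
    if n == 0 or m == 0:
        return []
    minsup = cfg.resolve_support(n)
    cols = list(frame.columns)
    mat = frame.to_numpy().astype(bool)
    rows = list(frame.index)
    frequent: dict[frozenset, frozenset] = {}
    for size in range(1, m + 1):
        for combo in combinations(range(m), size):
            mask = mat[:, combo].all(axis=1)
            if int(mask.sum()) >= minsup:
                cov = frozenset(rows[i] for i in range(n) if mask[i])
                frequent[frozenset(combo)] = cov
    maximal = [
        (tuple(cols[j] for j in sorted(s)), cov)
        for s, cov in frequent.items()
        if not any(s < other for other in frequent)
    ]
    return _sorted_seps(maximal)


def sep_statistics(seps: Sequence[SEP]) -> dict:
    """Summary of a SEP list: counts, length histogram, TC usage, supports.

    Joint coverage of a SEP pair (drugs containing the union of both itemsets,
    i.e. the intersection of the covered sets) is reported only when covered
    drug sets are available.
    """
    if not seps:
        return {
            "n_seps": 0,
            "n_distinct_tcs": 0,
            "length_histogram": {},
            "tc_frequency": {},
            "min_support": None,
            "max_support": None,
            "max_pairwise_joint_coverage": None,
        }
    tc_freq = Counter(tc for s in seps for tc in s.tcs)
    hist = Counter(s.length for s in seps)
    joint = None
    if all(s.covered is not None for s in seps) and len(seps) > 1:
        joint = max(
            len(a.covered & b.covered) for a, b in combinations(seps, 2)
        )
    return {
        "n_seps": len(seps),
        "n_distinct_tcs": len(tc_freq),
        "length_histogram": dict(sorted(hist.items())),
        "tc_frequency": dict(tc_freq.most_common()),
        "min_support": min(s.support for s in seps),
        "max_support": max(s.support for s in seps),
        "max_pairwise_joint_coverage": joint,
    }


# ------------------------------------------------------------------ fixture IO
def seps_to_tsv(seps: Sequence[SEP], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sep_id\tcomposition\tsupport\n")
        for s in seps:
            comp = ", ".join(map(str, s.tcs))
            fh.write(f"{s.id}\t{comp}\t{s.support}\n")


def seps_from_tsv(path: str) -> list[SEP]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = next(fh).rstrip("\n").split("\t")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = dict(zip(header, line.split("\t")))
            tcs = tuple(t.strip() for t in fields["composition"].split(","))
            out.append(SEP(fields["sep_id"], tcs, int(fields["support"])))
    return out


def load_table1_fixture() -> list[SEP]:
    """The packaged 26-profile reference table (composition + support)."""
    ref = importlib.resources.files("sepminer") / "data" / "table1_seps.tsv"
    with importlib.resources.as_file(ref) as path:
        return seps_from_tsv(str(path))
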