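"""Relational knowledge base of drugs, targets and target annotations.

The store holds ground facts over a fixed predicate vocabulary describing the
chemical space (drug categories, structural-cluster memberships), the
biological space (drug-target actions, protein-protein interactions, GO-style
functional annotations and their is_a/part_of relations, pathway memberships,
protein domains) plus per-drug side-effect term lists.  A small backtracking
engine answers conjunctive queries with variables, which is what the
relational rule learner needs to evaluate rule bodies.
"""

from __future__ import annotations

import dataclasses
import os
from collections import defaultdict
from typing import Iterable, Iterator, Mapping, Sequence

#: predicate name -> arity
PREDICATES: dict[str, int] = {
    "category": 2,
    "drug_cluster": 3,
    "drug_has_target": 3,
    "goterm": 2,
    "go_relation": 3,
    "interact": 2,
    "pathway": 3,
    "domain": 2,
}

ACTIONS = frozenset({"activator", "inhibitor", "other"})
GO_RELATION_TYPES = frozenset({"is_a", "part_of"})

#: column headers used in the TSV dialect, one file per predicate
TSV_HEADERS: dict[str, tuple[str, ...]] = {
    "category": ("drug_id", "category"),
    "drug_cluster": ("drug_id", "cluster", "source"),
    "drug_has_target": ("drug_id", "protein_id", "action"),
    "goterm": ("protein_id", "go_term"),
    "go_relation": ("go_term", "relation_type", "parent_term"),
    "interact": ("protein_id", "protein_id_2"),
    "pathway": ("protein_id", "pathway", "source"),
    "domain": ("protein_id", "domain"),
}


class KBError(ValueError):
    """Malformed fact, file, or query."""


class QueryCapExceeded(RuntimeError):
    """A conjunctive query produced more bindings than the configured cap."""


@dataclasses.dataclass(frozen=True)
class Var:
    """A logical variable occurring in a query or rule body."""

    name: str

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return self.name


@dataclasses.dataclass(frozen=True)
class Atom:
    """A ground fact or a query literal (args may contain Var)."""

    predicate: str
    args: tuple

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise KBError(f"unknown predicate {self.predicate!r}")
        if len(self.args) != PREDICATES[self.predicate]:
            raise KBError(
                f"{self.predicate}/{PREDICATES[self.predicate]} got "
                f"{len(self.args)} arguments"
            )

    @property
    def is_ground(self) -> bool:
        return not any(isinstance(a, Var) for a in self.args)

    def __str__(self) -> str:
        return f"{self.predicate}({', '.join(map(str, self.args))})"


@dataclasses.dataclass
class DrugRecord:
    """Flat per-drug view assembled from the fact store."""

    id: str
    name: str
    categories: tuple[str, ...]
    clusters: tuple[tuple[str, str], ...]  # (cluster label, method/source)
    targets: tuple[tuple[str, str], ...]  # (protein, action)
    side_effects: frozenset[str]


class KnowledgeBase:
    """Indexed store of ground facts with entity registries.

    ``interact`` facts are symmetrized at insertion so rule bodies traverse
    interactions directionlessly.  Facts keep insertion order, which fixes the
    enumeration order of :meth:`match`.
    """

    def __init__(self) -> None:
        self.facts: list[Atom] = []
        self._fact_set: set[Atom] = set()
        self._by_pred: dict[str, list[int]] = defaultdict(list)
        self._index: dict[tuple[str, int, object], list[int]] = defaultdict(list)
        # entity registries
        self.drugs: set[str] = set()
        self.proteins: set[str] = set()
        self.go_terms: set[str] = set()
        self.pathways: set[str] = set()
        self.domains: set[str] = set()
        self.clusters: set[tuple[str, str]] = set()  # (label, source)
        self.categories: set[str] = set()
        self.side_effects: dict[str, set[str]] = {}
        self.load_report: dict[str, int] = {}

    # ------------------------------------------------------------------ facts
    def __len__(self) -> int:
        return len(self.facts)

    def add_fact(self, predicate: str, *args) -> None:
        atom = Atom(predicate, tuple(args))
        if not atom.is_ground:
            raise KBError(f"cannot assert non-ground fact {atom}")
        self._validate_domains(atom)
        self._insert(atom)
        self._register(atom)
        if predicate == "interact" and args[0] != args[1]:
            self._insert(Atom("interact", (args[1], args[0])))

    def _insert(self, atom: Atom) -> None:
        if atom in self._fact_set:
            return
        idx = len(self.facts)
        self.facts.append(atom)
        self._fact_set.add(atom)
        self._by_pred[atom.predicate].append(idx)
        for pos, value in enumerate(atom.args):
            self._index[(atom.predicate, pos, value)].append(idx)

    @staticmethod
    def _validate_domains(atom: Atom) -> None:
        if atom.predicate == "drug_has_target" and atom.args[2] not in ACTIONS:
            raise KBError(f"invalid action {atom.args[2]!r} in {atom}")
        if atom.predicate == "go_relation" and atom.args[1] not in GO_RELATION_TYPES:
            raise KBError(f"invalid relation type {atom.args[1]!r} in {atom}")

    def _register(self, atom: Atom) -> None:
        p, a = atom.predicate, atom.args
        if p == "category":
            self.drugs.add(a[0])
            self.categories.add(a[1])
        elif p == "drug_cluster":
            self.drugs.add(a[0])
            self.clusters.add((a[1], a[2]))
        elif p == "drug_has_target":
            self.drugs.add(a[0])
            self.proteins.add(a[1])
        elif p == "goterm":
            self.proteins.add(a[0])
            self.go_terms.add(a[1])
        elif p == "go_relation":
            self.go_terms.add(a[0])
            self.go_terms.add(a[2])
        elif p == "interact":
            self.proteins.update(a)
        elif p == "pathway":
            self.proteins.add(a[0])
            self.pathways.add(a[1])
        elif p == "domain":
            self.proteins.add(a[0])
            self.domains.add(a[1])

    def set_side_effects(self, drug: str, terms: Iterable[str]) -> None:
        self.drugs.add(drug)
        self.side_effects.setdefault(drug, set()).update(terms)

    def register_drug(self, drug: str) -> None:
        self.drugs.add(drug)

    def drug_record(self, drug: str) -> DrugRecord:
        if drug not in self.drugs:
            raise KBError(f"drug {drug!r} is not registered")
        cats = sorted(a.args[1] for a in self.facts
                      if a.predicate == "category" and a.args[0] == drug)
        clus = sorted((a.args[1], a.args[2]) for a in self.facts
                      if a.predicate == "drug_cluster" and a.args[0] == drug)
        tgts = sorted((a.args[1], a.args[2]) for a in self.facts
                      if a.predicate == "drug_has_target" and a.args[0] == drug)
        return DrugRecord(
            id=drug, name=drug,
            categories=tuple(cats), clusters=tuple(clus), targets=tuple(tgts),
            side_effects=frozenset(self.side_effects.get(drug, set())),
        )

    def validate(self) -> None:
        """Check structural invariants (go_relation acyclicity per type)."""
        for rel in GO_RELATION_TYPES:
            succ: dict[str, list[str]] = defaultdict(list)
            for a in self.facts:
                if a.predicate == "go_relation" and a.args[1] == rel:
                    succ[a.args[0]].append(a.args[2])
            state: dict[str, int] = {}

            def dfs(node: str) -> None:
                state[node] = 1
                for nxt in succ.get(node, ()):
                    if state.get(nxt) == 1:
                        raise KBError(f"go_relation/{rel} graph has a cycle at {nxt!r}")
                    if nxt not in state:
                        dfs(nxt)
                state[node] = 2

            for n in list(succ):
                if n not in state:
                    dfs(n)

    # ---------------------------------------------------------------- queries
    def match(
        self,
        query: Sequence[Atom],
        seed_binding: Mapping[Var, object] | None = None,
        cap: int = 1_000_000,
    ) -> Iterator[dict[Var, object]]:
        """Yield every binding under which all literals are ground facts.

        Literals are evaluated left to right; within a literal candidate facts
        are visited in insertion order, so the binding stream is deterministic.
        More than ``cap`` results raise :class:`QueryCapExceeded`.
        """
        for lit in query:
            if lit.predicate not in PREDICATES:
                raise KBError(f"unknown predicate in query literal {lit}")
        binding: dict[Var, object] = dict(seed_binding or {})
        count = 0

        def candidates(lit: Atom, bnd: dict) -> Iterable[Atom]:
            best: list[int] | None = None
            for pos, arg in enumerate(lit.args):
                value = bnd.get(arg) if isinstance(arg, Var) else arg
                if value is not None or not isinstance(arg, Var):
                    idxs = self._index.get((lit.predicate, pos, value), [])
                    if best is None or len(idxs) < len(best):
                        best = idxs
            if best is None:
                best = self._by_pred.get(lit.predicate, [])
            return (self.facts[i] for i in best)

        def unify(lit: Atom, fact: Atom, bnd: dict) -> dict | None:
            new = bnd
            for arg, val in zip(lit.args, fact.args):
                if isinstance(arg, Var):
                    bound = new.get(arg)
                    if bound is None:
                        if new is bnd:
                            new = dict(bnd)
                        new[arg] = val
                    elif bound != val:
                        return None
                elif arg != val:
                    return None
            return new if new is not bnd else dict(bnd)

        def solve(i: int, bnd: dict) -> Iterator[dict]:
            nonlocal count
            if i == len(query):
                count += 1
                if count > cap:
                    raise QueryCapExceeded(
                        f"query exceeded {cap} bindings while evaluating "
                        f"literal {query[-1]}"
                    )
                yield dict(bnd)
                return
            lit = query[i]
            for fact in candidates(lit, bnd):
                new = unify(lit, fact, bnd)
                if new is not None:
                    yield from solve(i + 1, new)

        yield from solve(0, binding)

    def ask(
        self,
        query: Sequence[Atom],
        seed_binding: Mapping[Var, object] | None = None,
    ) -> bool:
        """True iff the conjunction has at least one satisfying binding."""
        return next(self.match(query, seed_binding), None) is not None


# --------------------------------------------------------------------- TSV IO
def _read_tsv(path: str) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                rows.append(line.split("\t"))
    return rows


def load_kb(
    fact_dir: str,
    side_effect_file: str | None = None,
    hierarchy_terms: Iterable[str] | None = None,
    strict: bool = False,
) -> KnowledgeBase:
    """Load a knowledge base from one TSV per predicate plus side effects.

    ``hierarchy_terms``, when given, is the side-effect term vocabulary;
    annotation terms outside it are skipped and counted in ``kb.load_report``
    (or rejected when ``strict``).
    """
    kb = KnowledgeBase()
    for fname in sorted(os.listdir(fact_dir)):
        if not fname.endswith(".tsv"):
            continue
        pred = fname[:-4]
        if pred in ("side_effects", "hierarchy"):
            continue
        if pred not in PREDICATES:
            raise KBError(f"unknown predicate file {fname!r}")
        rows = _read_tsv(os.path.join(fact_dir, fname))
        for lineno, row in enumerate(rows[1:], start=2):
            if len(row) != PREDICATES[pred]:
                raise KBError(f"{fname}:{lineno}: expected "
                              f"{PREDICATES[pred]} columns, got {len(row)}")
            kb.add_fact(pred, *row)
    skipped = 0
    if side_effect_file is not None:
        vocab = set(hierarchy_terms) if hierarchy_terms is not None else None
        rows = _read_tsv(side_effect_file)
        for lineno, row in enumerate(rows[1:], start=2):
            if len(row) != 2:
                raise KBError(f"{side_effect_file}:{lineno}: expected 2 columns")
            drug, term = row
            if vocab is not None and term not in vocab:
                if strict:
                    raise KBError(
                        f"{side_effect_file}:{lineno}: term {term!r} "
                        "not in the hierarchy"
                    )
                skipped += 1
                kb.register_drug(drug)
                continue
            kb.set_side_effects(drug, [term])
    kb.load_report["skipped_terms"] = skipped
    kb.validate()
    return kb


def export_kb(kb: KnowledgeBase, out_dir: str) -> None:
    """Write the TSV dialect read by :func:`load_kb` (round-trip safe)."""
    os.makedirs(out_dir, exist_ok=True)
    by_pred: dict[str, list[Atom]] = defaultdict(list)
    for atom in kb.facts:
        by_pred[atom.predicate].append(atom)
    for pred, header in TSV_HEADERS.items():
        with open(os.path.join(out_dir, f"{pred}.tsv"), "w", encoding="utf-8") as fh:
            fh.write("\t".join(header) + "\n")
            for atom in by_pred.get(pred, ()):
                fh.write("\t".join(map(str, atom.args)) + "\n")
    with open(os.path.join(out_dir, "side_effects.tsv"), "w", encoding="utf-8") as fh:
        fh.write("drug_id\tterm_id\n")
        for drug in sorted(kb.side_effects):
            for term in sorted(kb.side_effects[drug]):
                fh.write(f"{drug}\t{term}\n")


def kb_equal(a: KnowledgeBase, b: KnowledgeBase) -> bool:
    """Equality on fact sets, side effects and entity registries."""
    return (
        a._fact_set == b._fact_set
        and a.side_effects == b.side_effects
        and a.drugs == b.drugs
        and a.proteins == b.proteins
    )
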