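"""Synthetic relational knowledge bases with planted ground truth.

The generator emulates the joint structure of the real inputs the pipeline
was designed for: a DAG-shaped side-effect term hierarchy, drugs annotated
with side-effect terms, multi-target drugs (about four targets per drug on
average) and annotation-rich targets (GO-style terms with is_a/part_of
relations, pathways, domains, protein-protein interactions).  Relational
rules of the pipeline's rule language are planted together with the term
clusters of their side-effect profile, so that every stage — fingerprinting,
itemset mining, tree and rule learning, cross-validation, report checking —
has a known answer.

Planted entities (proteins, annotation labels, categories) are reserved: they
appear only in the facts that realize a planted rule, so a drug satisfies the
rule body iff it is a carrier.
"""

from __future__ import annotations

import dataclasses
import json
import os

import numpy as np

from .clustering import TermClustering
from .evaluation import FaersReport, FaersReportSet
from .fingerprints import AssociationConfig, min_se_count
from .hierarchy import TermHierarchy
from .ilp import parse_body
from .kb import ACTIONS, Atom, KnowledgeBase, Var, export_kb

#: argument entity types per predicate (mirrors the default mode declarations)
PRED_TYPES: dict[str, tuple[str, ...]] = {
    "category": ("drug", "category"),
    "drug_cluster": ("drug", "cluster", "source"),
    "drug_has_target": ("drug", "protein", "action"),
    "goterm": ("protein", "go_term"),
    "go_relation": ("go_term", "relation_type", "go_term"),
    "interact": ("protein", "protein"),
    "pathway": ("protein", "pathway", "source"),
    "domain": ("protein", "domain"),
}


@dataclasses.dataclass(frozen=True)
class PlantedRuleSpec:
    """A rule body template, the SEP it should produce, and its prevalence."""

    name: str
    body: str
    sep_tcs: tuple[int, ...]
    carrier_fraction: float = 0.25


def default_planted_rules() -> tuple[PlantedRuleSpec, ...]:
    return (
        PlantedRuleSpec(
            "r1",
            "drug_has_target(A,B,inhibitor), pathway(B,'pw_planted_r1',kegg)",
            (1, 2),
            0.25,
        ),
        PlantedRuleSpec("r2", "category(A,'cat_planted_r2')", (3, 4), 0.25),
    )


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 300
    n_targets: int = 120
    n_interactants: int = 60
    n_go_terms: int = 60
    n_pathways: int = 30
    n_domains: int = 25
    n_categories: int = 12
    n_clusters: int = 15
    cluster_methods: tuple[str, ...] = ("tanimoto", "hpcc")
    hierarchy_branching: int = 6
    hierarchy_depth: int = 3
    second_parent_rate: float = 0.1
    targets_per_drug_mean: float = 4.0
    planted_rules: tuple[PlantedRuleSpec, ...] = dataclasses.field(
        default_factory=default_planted_rules
    )
    fn: float = 0.0  # carrier fails to show its SEP terms
    fp: float = 0.0  # non-carrier shows the SEP terms anyway
    background_rate: float = 0.1
    faers_fraction: float = 1.0
    faers_decoy_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.fn, self.fp, self.background_rate,
                  self.faers_fraction, self.faers_decoy_rate,
                  self.second_parent_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if min(self.n_drugs, self.n_targets, self.n_categories) < 1:
            raise ValueError("entity counts must be >= 1")


@dataclasses.dataclass(frozen=True)
class PlantedRule:
    name: str
    body: tuple[Atom, ...]
    sep_tcs: tuple[int, ...]
    carriers: frozenset[str]


@dataclasses.dataclass
class GroundTruth:
    planted: list[PlantedRule]

    def rule(self, name: str) -> PlantedRule:
        return next(r for r in self.planted if r.name == name)

    def to_json(self, path: str) -> None:
        from .ilp import body_to_str

        payload = [
            {
                "name": r.name,
                "body": body_to_str(r.body),
                "sep_tcs": list(r.sep_tcs),
                "carriers": sorted(r.carriers),
            }
            for r in self.planted
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ------------------------------------------------------------------- hierarchy
def generate_hierarchy(cfg: SynthConfig, rng: np.random.Generator | None = None) -> TermHierarchy:
    """Rooted DAG: a complete b-ary tree plus ~10% extra second parents."""
    if cfg.hierarchy_depth < 2:
        raise ValueError("hierarchy depth must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    b, depth = cfg.hierarchy_branching, cfg.hierarchy_depth
    labels: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    levels: list[list[str]] = [["se_0"]]
    labels["se_0"] = "se_0"
    counter = 1
    for d in range(1, depth + 1):
        level: list[str] = []
        for parent in levels[d - 1]:
            for _ in range(b):
                term = f"se_{counter}"
                counter += 1
                labels[term] = term
                rel = "is_a" if rng.random() < 0.8 else "part_of"
                edges.append((term, parent, rel))
                level.append(term)
        levels.append(level)
    # second parents keep the DAG shape: always one level up
    for d in range(2, depth + 1):
        for term in levels[d]:
            if rng.random() < cfg.second_parent_rate:
                first_parent = next(p for c, p, _ in edges if c == term)
                options = [p for p in levels[d - 1] if p != first_parent]
                if options:
                    extra = options[int(rng.integers(len(options)))]
                    edges.append((term, extra, "is_a"))
    return TermHierarchy(labels=labels, edges=edges)


def make_clustering_plan(h: TermHierarchy, cfg: SynthConfig) -> TermClustering:
    """One term cluster per deepest internal node: its primary leaf children.

    Leaves with two parents are assigned to their lexicographically smallest
    parent so the clusters partition the leaf set.
    """
    depth = cfg.hierarchy_depth
    internals = sorted(t for t in h.terms if h.depth(t) == depth - 1 and h.children(t))
    leaf_owner: dict[str, str] = {}
    for leaf in h.leaves():
        parents = [p for p in h.parents(leaf) if p in internals]
        if parents:
            leaf_owner[leaf] = min(parents)
    member_sets = []
    for node in internals:
        members = sorted(l for l, o in leaf_owner.items() if o == node)
        if members:
            member_sets.append(members)
    return TermClustering.from_plan(member_sets, hierarchy=h)


# ------------------------------------------------------------------------- kb
def generate_kb(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[KnowledgeBase, GroundTruth]:
    """Drug/target facts with each planted rule satisfied exactly by its carriers."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    kb = KnowledgeBase()
    drugs = [f"d{i:03d}" for i in range(cfg.n_drugs)]
    targets = [f"p{i:03d}" for i in range(cfg.n_targets)]
    interactants = [f"q{i:03d}" for i in range(cfg.n_interactants)]
    go_terms = [f"go_{i}" for i in range(cfg.n_go_terms)]
    pathways = [f"pw_{i}" for i in range(cfg.n_pathways)]
    domains = [f"dom_{i}" for i in range(cfg.n_domains)]
    categories = [f"cat_{i}" for i in range(cfg.n_categories)]
    sources = ("kegg", "pid")
    actions = sorted(ACTIONS)

    # GO-relation DAG: edges always point to a smaller index, hence acyclic
    for i in range(1, cfg.n_go_terms):
        for parent in rng.choice(i, size=min(i, int(rng.integers(1, 3))), replace=False):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            kb.add_fact("go_relation", go_terms[i], rel, go_terms[int(parent)])

    def annotate(protein: str, n_go: int, n_pw: int, n_dom: int) -> None:
        for g in rng.choice(cfg.n_go_terms, size=n_go, replace=False):
            kb.add_fact("goterm", protein, go_terms[int(g)])
        for p in rng.choice(cfg.n_pathways, size=n_pw, replace=False):
            kb.add_fact("pathway", protein, pathways[int(p)],
                        sources[int(rng.integers(2))])
        for dm in rng.choice(cfg.n_domains, size=n_dom, replace=False):
            kb.add_fact("domain", protein, domains[int(dm)])

    for t in targets:
        annotate(t, 3, int(rng.integers(1, 3)), int(rng.integers(1, 3)))
        for q in rng.choice(cfg.n_interactants, size=int(rng.integers(0, 3)),
                            replace=False):
            kb.add_fact("interact", t, interactants[int(q)])
    for q in interactants:
        annotate(q, 2, 1, 1)

    for d in drugs:
        kb.register_drug(d)
        n_t = 1 + int(rng.poisson(cfg.targets_per_drug_mean - 1.0))
        n_t = min(n_t, cfg.n_targets)
        for t in rng.choice(cfg.n_targets, size=n_t, replace=False):
            kb.add_fact("drug_has_target", d, targets[int(t)],
                        actions[int(rng.integers(3))])
        for c in rng.choice(cfg.n_categories, size=int(rng.integers(1, 3)),
                            replace=False):
            kb.add_fact("category", d, categories[int(c)])
        for method in cfg.cluster_methods:
            label = f"cl{int(rng.integers(cfg.n_clusters))}"
            kb.add_fact("drug_cluster", d, label, method)

    # ---------------------------------------------------------- rule planting
    planted: list[PlantedRule] = []
    for spec in cfg.planted_rules:
        body = parse_body(spec.body)
        for lit in body:
            if lit.predicate not in PRED_TYPES:
                raise ValueError(f"planted rule uses unknown predicate {lit.predicate}")
        n_carriers = int(round(spec.carrier_fraction * cfg.n_drugs))
        carriers = sorted(
            drugs[int(i)]
            for i in rng.choice(cfg.n_drugs, size=n_carriers, replace=False)
        )
        # reserved entity per non-head variable
        const_of: dict[Var, str] = {}
        for lit in body:
            for pos, arg in enumerate(lit.args):
                if isinstance(arg, Var) and arg != Var("A"):
                    const_of.setdefault(
                        arg, f"planted_{spec.name}_{arg.name.lower()}"
                    )

        def ground(lit: Atom, drug: str | None) -> tuple:
            out = []
            for arg in lit.args:
                if isinstance(arg, Var):
                    out.append(drug if arg == Var("A") else const_of[arg])
                else:
                    out.append(arg)
            return tuple(out)

        drug_lits = [l for l in body if Var("A") in l.args]
        bg_lits = [l for l in body if Var("A") not in l.args]
        for lit in bg_lits:
            kb.add_fact(lit.predicate, *ground(lit, None))
        for carrier in carriers:
            for lit in drug_lits:
                kb.add_fact(lit.predicate, *ground(lit, carrier))
        planted.append(PlantedRule(spec.name, body, spec.sep_tcs, frozenset(carriers)))

    kb.validate()
    return kb, GroundTruth(planted)


# ----------------------------------------------------------------- annotations
def generate_side_effects(
    kb: KnowledgeBase,
    truth: GroundTruth,
    clustering: TermClustering,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    assoc: AssociationConfig = AssociationConfig(),
) -> dict[str, set[str]]:
    """Per-drug side-effect term sets realizing the planted SEPs.

    Carriers receive at least n_i member terms of every TC of their rule's
    SEP with probability 1 - fn; non-carriers with probability fp.
    Background terms are added per drug and TC at ``background_rate`` but
    always below the association threshold n_i, so they never flip a
    fingerprint cell on their own.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    drugs = sorted(kb.drugs)
    out: dict[str, set[str]] = {d: set() for d in drugs}

    def sample_members(tc_index: int, count: int) -> list[str]:
        members = sorted(clustering[tc_index].members)
        count = min(count, len(members))
        picks = rng.choice(len(members), size=count, replace=False)
        return [members[int(i)] for i in picks]

    for rule in truth.planted:
        for d in drugs:
            p = (1.0 - cfg.fn) if d in rule.carriers else cfg.fp
            if rng.random() < p:
                for tc in rule.sep_tcs:
                    n_i = min_se_count(clustering[tc].size, assoc)
                    extra = int(rng.integers(0, 2))
                    out[d].update(sample_members(tc, n_i + extra))
    for d in drugs:
        for c in clustering.clusters:
            if rng.random() < cfg.background_rate:
                n_i = min_se_count(c.size, assoc)
                if n_i > 1:
                    out[d].update(sample_members(c.index, int(rng.integers(1, n_i))))
    return out


def generate_faers(
    kb: KnowledgeBase,
    truth: GroundTruth,
    clustering: TermClustering,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> FaersReportSet:
    """Primary-suspect reports for a fraction of carriers, plus decoys."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    records: list[FaersReport] = []
    for rule in truth.planted:
        carriers = sorted(rule.carriers)
        n_sel = int(round(cfg.faers_fraction * len(carriers)))
        chosen = sorted(
            carriers[int(i)]
            for i in rng.choice(len(carriers), size=n_sel, replace=False)
        ) if carriers else []
        for d in chosen:
            for tc in rule.sep_tcs:
                members = sorted(clustering[tc].members)
                term = members[int(rng.integers(len(members)))]
                records.append(FaersReport(d, term, "primary_suspect"))
    universe = sorted(clustering.term_universe)
    for d in sorted(kb.drugs):
        if rng.random() < cfg.faers_decoy_rate:
            term = universe[int(rng.integers(len(universe)))]
            records.append(FaersReport(d, term, "other"))
    return FaersReportSet(records)


# ---------------------------------------------------------------- orchestration
@dataclasses.dataclass
class SynthDataset:
    config: SynthConfig
    hierarchy: TermHierarchy
    clustering: TermClustering
    kb: KnowledgeBase
    truth: GroundTruth
    side_effects: dict[str, set[str]]
    faers: FaersReportSet

    def export(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        export_kb(self.kb, os.path.join(out_dir, "kb"))
        self.hierarchy.to_tsv(os.path.join(out_dir, "hierarchy.tsv"))
        self.clustering.to_tsv(os.path.join(out_dir, "clustering_plan.tsv"))
        self.faers.to_tsv(os.path.join(out_dir, "faers_reports.tsv"))
        self.truth.to_json(os.path.join(out_dir, "ground_truth.json"))


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Full synthetic study: hierarchy, term-cluster plan, KB, annotations, reports."""
    rng = np.random.default_rng(cfg.seed)
    hierarchy = generate_hierarchy(cfg, rng)
    clustering = make_clustering_plan(hierarchy, cfg)
    max_tc = max((tc for r in cfg.planted_rules for tc in r.sep_tcs), default=0)
    if max_tc > len(clustering):
        raise ValueError(
            f"planted SEP uses TC {max_tc} but the plan has {len(clustering)} clusters"
        )
    kb, truth = generate_kb(cfg, rng)
    side_effects = generate_side_effects(kb, truth, clustering, cfg, rng)
    for d, terms in side_effects.items():
        if terms:
            kb.set_side_effects(d, terms)
    faers = generate_faers(kb, truth, clustering, cfg, rng)
    return SynthDataset(cfg, hierarchy, clustering, kb, truth, side_effects, faers)
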