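"""Saturation, rule coverage, beam search and the induce-cover loop."""

import itertools

import pytest

from sepminer.ilp import (
    HEAD_VAR,
    ILPConfig,
    Rule,
    Theory,
    covers,
    coverage,
    induce_cover,
    parse_body,
    parse_literal,
    predict_theory,
    saturate,
    search_rule,
)
from sepminer.kb import Atom, KnowledgeBase, Var


# ------------------------------------------------------------ surface syntax
def test_parse_literal_variables_and_constants():
    lit = parse_literal("drug_has_target(A,B,inhibitor)")
    assert lit == Atom("drug_has_target", (Var("A"), Var("B"), "inhibitor"))
    lit = parse_literal("pathway(B,'BCR signaling pathway',pid)")
    assert lit.args[1] == "BCR signaling pathway"


def test_parse_body_splits_on_top_level_commas():
    body = parse_body(
        "drug_has_target(A,B,inhibitor), pathway(B,'Endocytosis',kegg)"
    )
    assert len(body) == 2
    assert body[1].predicate == "pathway"


# ----------------------------------------------------------------- saturation
def test_saturate_single_category_fact():
    kb = KnowledgeBase()
    kb.add_fact("category", "d1", "X")
    bottom = saturate("d1", kb)
    assert [bl.literal for bl in bottom] == [Atom("category", (HEAD_VAR, "X"))]


def test_saturate_two_step_chain_with_both_goterm_modes():
    kb = KnowledgeBase()
    kb.add_fact("drug_has_target", "d1", "p1", "inhibitor")
    kb.add_fact("goterm", "p1", "g1")
    bottom = saturate("d1", kb)
    lits = [bl.literal for bl in bottom]
    dht = [l for l in lits if l.predicate == "drug_has_target"]
    assert len(dht) == 1
    target_var = dht[0].args[1]
    assert isinstance(target_var, Var)
    # constant form and variable (chaining) form of the annotation
    assert Atom("goterm", (target_var, "g1")) in lits
    assert any(
        l.predicate == "goterm" and l.args[0] == target_var
        and isinstance(l.args[1], Var)
        for l in lits
    )


def test_depth_cap_excludes_interactant_literals():
    kb = KnowledgeBase()
    kb.add_fact("drug_has_target", "d1", "p1", "inhibitor")
    kb.add_fact("interact", "p1", "p2")
    kb.add_fact("goterm", "p2", "g1")
    shallow = saturate("d1", kb, cfg=ILPConfig(max_chain_depth=1))
    assert all(bl.literal.predicate != "interact" for bl in shallow)
    deep = saturate("d1", kb, cfg=ILPConfig(max_chain_depth=2))
    assert any(bl.literal.predicate == "interact" for bl in deep)


def test_saturate_empty_for_factless_seed():
    kb = KnowledgeBase()
    kb.register_drug("d1")
    assert saturate("d1", kb) == []


# ------------------------------------------------------------------- coverage
def test_empty_body_covers_everything(pathway_kb):
    assert covers((), "d1", pathway_kb)
    assert covers((), "d2", pathway_kb)


def test_pathway_rule_coverage(pathway_kb):
    body = parse_body(
        "drug_has_target(A,B,inhibitor), pathway(B,'Endocytosis',kegg)"
    )
    assert covers(body, "d1", pathway_kb)
    assert not covers(body, "d2", pathway_kb)  # wrong pathway
    assert not covers(body, "d3", pathway_kb)  # wrong action


def test_go_chain_coverage_equals_brute_force_enumeration():
    kb = KnowledgeBase()
    kb.add_fact("drug_has_target", "d1", "p1", "inhibitor")
    kb.add_fact("drug_has_target", "d2", "p2", "inhibitor")
    kb.add_fact("goterm", "p1", "g1")
    kb.add_fact("goterm", "p2", "g3")
    kb.add_fact("go_relation", "g1", "is_a", "g2")
    kb.add_fact("go_relation", "g2", "is_a", "g4")
    kb.add_fact("go_relation", "g3", "part_of", "g4")
    body = parse_body(
        "drug_has_target(A,B,inhibitor), goterm(B,C), "
        "go_relation(C,is_a,D), go_relation(D,is_a,g4)"
    )
    got = coverage(body, ["d1", "d2"], kb)
    # exhaustive binding enumeration over all constants
    consts = sorted({a for f in kb.facts for a in f.args})
    expected = set()
    for drug in ("d1", "d2"):
        for vals in itertools.product(consts, repeat=3):
            bnd = dict(zip((Var("B"), Var("C"), Var("D")), vals))
            bnd[HEAD_VAR] = drug
            if all(
                Atom(l.predicate, tuple(
                    bnd.get(a, a) if isinstance(a, Var) else a for a in l.args
                )) in kb._fact_set
                for l in body
            ):
                expected.add(drug)
    assert got == expected


# ---------------------------------------------------------------- rule search
def _category_kb(pos, neg, label="X"):
    kb = KnowledgeBase()
    for d in pos:
        kb.add_fact("category", d, label)
    for d in neg:
        kb.add_fact("category", d, "Y")
    return kb


def test_search_finds_shared_category_rule():
    pos = [f"p{i}" for i in range(6)]
    neg = [f"n{i}" for i in range(6)]
    kb = _category_kb(pos, neg)
    rule = search_rule(pos[0], pos, neg, kb)
    assert rule is not None
    assert rule.body == (Atom("category", (HEAD_VAR, "X")),)
    assert rule.p == 6 and rule.n == 0


def test_search_returns_none_for_empty_bottom_clause():
    kb = KnowledgeBase()
    for d in ("a", "b", "c", "d", "e"):
        kb.register_drug(d)
    assert search_rule("a", list("abcde"), [], kb) is None


def test_planted_two_literal_rule_recovered(synth_ds):
    truth = synth_ds.truth.rule("r1")
    pos = sorted(truth.carriers)
    neg = sorted(synth_ds.kb.drugs - truth.carriers)
    rule = search_rule(pos[0], pos, neg, synth_ds.kb)
    assert rule is not None
    assert rule.n <= 1
    # logically equivalent to the planted rule: identical coverage on all drugs
    assert coverage(rule, sorted(synth_ds.kb.drugs), synth_ds.kb) == truth.carriers


# --------------------------------------------------------------- induce-cover
def test_min_pos_larger_than_positives_gives_empty_theory():
    kb = _category_kb(["a", "b"], ["c", "d"])
    theory = induce_cover(["a", "b"], ["c", "d"], kb, ILPConfig(min_pos=5))
    assert len(theory) == 0
    assert set(theory.uncovered_positives) == {"a", "b"}


def test_two_subpopulations_yield_two_rules_covering_all():
    kb = KnowledgeBase()
    grp1 = [f"a{i}" for i in range(6)]
    grp2 = [f"b{i}" for i in range(6)]
    neg = [f"n{i}" for i in range(8)]
    for d in grp1:
        kb.add_fact("category", d, "G1")
    for d in grp2:
        kb.add_fact("category", d, "G2")
    for d in neg:
        kb.add_fact("category", d, "N")
    theory = induce_cover(grp1 + grp2, neg, kb, ILPConfig(min_pos=5, noise=0))
    assert len(theory.rules) >= 2
    covered = set().union(*(r.pos_covered for r in theory.rules))
    assert covered == set(grp1 + grp2)
    assert theory.uncovered_positives == ()


def test_overlapping_rules_are_both_retained():
    kb = KnowledgeBase()
    grp1 = [f"a{i}" for i in range(6)]
    grp2 = [f"b{i}" for i in range(6)]
    neg = [f"n{i}" for i in range(8)]
    for d in grp1 + ["b0"]:          # b0 carries both categories
        kb.add_fact("category", d, "G1")
    for d in grp2:
        kb.add_fact("category", d, "G2")
    for d in neg:
        kb.add_fact("category", d, "N")
    theory = induce_cover(grp1 + grp2, neg, kb, ILPConfig(min_pos=5, noise=0))
    hit = [r for r in theory.rules if covers(r, "b0", kb)]
    assert len(hit) >= 2


def test_accepted_rules_satisfy_thresholds_post_hoc(synth_ds, synth_fp):
    from sepminer import build_learning_set, mine_mfis

    seps = mine_mfis(synth_fp)
    ls = build_learning_set(synth_fp, seps[0])
    cfg = ILPConfig()
    theory = induce_cover(ls.positives, ls.negatives, synth_ds.kb, cfg)
    assert len(theory.rules) >= 1
    for r in theory.rules:
        pos_cov = coverage(r, ls.positives, synth_ds.kb)
        neg_cov = coverage(r, ls.negatives, synth_ds.kb)
        assert len(pos_cov) == r.p >= cfg.min_pos
        assert len(neg_cov) == r.n <= cfg.noise


def test_rule_bodies_are_connected_to_head_variable(synth_ds):
    truth = synth_ds.truth.rule("r1")
    pos = sorted(truth.carriers)
    neg = sorted(synth_ds.kb.drugs - truth.carriers)
    rule = search_rule(pos[0], pos, neg, synth_ds.kb)
    bound = {HEAD_VAR}
    for lit in rule.body:
        in_vars = {a for a in lit.args if isinstance(a, Var) and a in bound}
        assert in_vars, f"literal {lit} disconnected from the head variable"
        bound |= {a for a in lit.args if isinstance(a, Var)}


# ----------------------------------------------------------------- prediction
def test_empty_theory_predicts_negative(pathway_kb):
    theory = Theory("s", [], ILPConfig())
    assert not predict_theory(theory, "d1", pathway_kb)


def test_any_single_rule_suffices(pathway_kb):
    never = Rule((Atom("category", (HEAD_VAR, "nope")),), 0, 0)
    hits = Rule(parse_body("drug_has_target(A,B,inhibitor)"), 1, 0)
    theory = Theory("s", [never, hits, never], ILPConfig())
    assert predict_theory(theory, "d1", pathway_kb)
    assert not predict_theory(theory, "dX", pathway_kb)
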