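"""Mode-directed relational rule induction for side-effect profiles.

A theory for a SEP is a set of first-order rules ``sep(A) :- body`` whose
bodies chain through the knowledge base (drug -> target -> interactant ->
annotation).  Induction is Progol-style: a seed positive example is saturated
into a bottom clause under mode declarations, and a beam search grows
connected sub-bodies of that clause, accepting rules that cover at least
``min_pos`` positives and at most ``noise`` negatives, both measured on the
full example sets.  The ``induce_cover`` loop keeps accepted rules even when
their coverage overlaps, removing covered positives from seed selection only.
"""

from __future__ import annotations

import dataclasses
import json
import re
from collections import deque
from typing import Iterable, Sequence

from .kb import PREDICATES, Atom, KnowledgeBase, Var

HEAD_VAR = Var("A")

_VAR_NAMES = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + [
    f"V{i}" for i in range(1, 200)
]


@dataclasses.dataclass(frozen=True)
class ModeDecl:
    """Per-argument roles: '+' input variable, '-' output variable, '#' constant."""

    predicate: str
    roles: tuple[str, ...]
    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise ValueError(f"unknown predicate {self.predicate!r}")
        if len(self.roles) != PREDICATES[self.predicate]:
            raise ValueError(f"arity mismatch in mode for {self.predicate}")
        if "+" not in self.roles:
            raise ValueError("a body mode needs at least one input argument")


#: the rule vocabulary: drug and protein arguments are always variablized,
#: labels (actions, sources, categories, clusters, annotations) may be
#: constants; goterm/go_relation each get a constant form and a chaining form.
DEFAULT_MODES: tuple[ModeDecl, ...] = (
    ModeDecl("category", ("+", "#"), ("drug", "category")),
    ModeDecl("drug_cluster", ("+", "#", "#"), ("drug", "cluster", "source")),
    ModeDecl("drug_has_target", ("+", "-", "#"), ("drug", "protein", "action")),
    ModeDecl("goterm", ("+", "#"), ("protein", "go_term")),
    ModeDecl("goterm", ("+", "-"), ("protein", "go_term")),
    ModeDecl("go_relation", ("+", "#", "#"), ("go_term", "relation_type", "go_term")),
    ModeDecl("go_relation", ("+", "#", "-"), ("go_term", "relation_type", "go_term")),
    ModeDecl("interact", ("+", "-"), ("protein", "protein")),
    ModeDecl("pathway", ("+", "#", "#"), ("protein", "pathway", "source")),
    ModeDecl("domain", ("+", "#"), ("protein", "domain")),
)


@dataclasses.dataclass(frozen=True)
class ILPConfig:
    min_pos: int = 5
    noise: int = 1
    induce_type: str = "induce_cover"
    max_body_literals: int = 6
    max_chain_depth: int = 3
    beam_width: int = 20
    saturation_cap: int = 200

    def __post_init__(self) -> None:
        if self.min_pos < 1 or self.noise < 0:
            raise ValueError("min_pos >= 1 and noise >= 0 required")


@dataclasses.dataclass(frozen=True)
class BottomLiteral:
    literal: Atom
    in_vars: frozenset[Var]
    out_vars: frozenset[Var]


@dataclasses.dataclass(frozen=True)
class Rule:
    """``sep(A) :- body`` with its (P, N) coverage on the training sets."""

    body: tuple[Atom, ...]
    p: int
    n: int
    pos_covered: frozenset[str] = frozenset()

    def __str__(self) -> str:
        return f"{body_to_str(self.body)}  P={self.p} N={self.n}"


@dataclasses.dataclass
class Theory:
    sep_id: str
    rules: list[Rule]
    config: ILPConfig
    uncovered_positives: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.rules)

    def to_text(self) -> str:
        lines = [f"theory {self.sep_id}: {len(self.rules)} rules"]
        for i, r in enumerate(self.rules, start=1):
            lines.append(f"{i}\t{body_to_str(r.body)}\t{r.p}\t{r.n}")
        return "\n".join(lines)

    def to_json(self, path: str) -> None:
        payload = {
            "sep_id": self.sep_id,
            "config": dataclasses.asdict(self.config),
            "rules": [
                {"body": [literal_to_str(l) for l in r.body], "P": r.p, "N": r.n}
                for r in self.rules
            ],
            "uncovered_positives": list(self.uncovered_positives),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


# ------------------------------------------------------------ surface syntax
_PLAIN = re.compile(r"^[a-z][A-Za-z0-9_:.\-]*$")
_VAR_TOKEN = re.compile(r"^[A-Z][A-Za-z0-9_]*$")


def _fmt_arg(arg) -> str:
    if isinstance(arg, Var):
        return arg.name
    s = str(arg)
    return s if _PLAIN.match(s) else f"'{s}'"


def literal_to_str(lit: Atom) -> str:
    return f"{lit.predicate}({','.join(_fmt_arg(a) for a in lit.args)})"


def body_to_str(body: Sequence[Atom]) -> str:
    return ", ".join(literal_to_str(l) for l in body)


def parse_literal(text: str) -> Atom:
    """Parse Prolog-style surface syntax: capitalized bare tokens are variables."""
    m = re.match(r"^\s*([a-z_][A-Za-z0-9_]*)\s*\((.*)\)\s*$", text)
    if not m:
        raise ValueError(f"cannot parse literal {text!r}")
    pred, argstr = m.group(1), m.group(2)
    args: list = []
    for token in _split_args(argstr):
        token = token.strip()
        if token.startswith("'") and token.endswith("'"):
            args.append(token[1:-1])
        elif _VAR_TOKEN.match(token):
            args.append(Var(token))
        else:
            args.append(token)
    return Atom(pred, tuple(args))


def _split_args(argstr: str) -> list[str]:
    out, depth, quoted, cur = [], 0, False, []
    for ch in argstr:
        if ch == "'":
            quoted = not quoted
            cur.append(ch)
        elif ch == "," and not quoted and depth == 0:
            out.append("".join(cur))
            cur = []
        else:
            if ch == "(" and not quoted:
                depth += 1
            elif ch == ")" and not quoted:
                depth -= 1
            cur.append(ch)
    if cur:
        out.append("".join(cur))
    return out


def parse_body(text: str) -> tuple[Atom, ...]:
    """Parse a comma-separated conjunction of literals."""
    lits, depth, quoted, cur = [], 0, False, []
    for ch in text:
        if ch == "'":
            quoted = not quoted
        elif not quoted:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
        if ch == "," and depth == 0 and not quoted:
            lits.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if "".join(cur).strip():
        lits.append("".join(cur))
    return tuple(parse_literal(l) for l in lits)


# ------------------------------------------------------------------ saturation
def saturate(
    seed: str,
    kb: KnowledgeBase,
    modes: Sequence[ModeDecl] = DEFAULT_MODES,
    cfg: ILPConfig = ILPConfig(),
) -> list[BottomLiteral]:
    """Most specific body derivable from the seed drug's facts.

    Breadth-first instantiation of the mode declarations starting from the
    head variable: entity constants reached through output roles are lifted
    to typed variables (one variable per constant), labels at constant roles
    are kept verbatim.  New variables are only introduced up to
    ``max_chain_depth`` steps from the drug; each mode contributes at most
    ``saturation_cap`` literals.
    """
    var_of: dict[tuple[str, str], Var] = {("drug", seed): HEAD_VAR}
    depth_of: dict[Var, int] = {HEAD_VAR: 0}
    name_iter = iter(_VAR_NAMES[1:])
    agenda: deque[tuple[Var, str, str]] = deque([(HEAD_VAR, seed, "drug")])
    literals: list[BottomLiteral] = []
    seen: set[Atom] = set()
    mode_count = {i: 0 for i in range(len(modes))}

    while agenda:
        var, const, typ = agenda.popleft()
        d = depth_of[var]
        for mi, mode in enumerate(modes):
            ipos = mode.roles.index("+")
            if mode.types[ipos] != typ:
                continue
            fact_idx = kb._index.get((mode.predicate, ipos, const), [])
            for fi in fact_idx:
                if mode_count[mi] >= cfg.saturation_cap:
                    break
                fact = kb.facts[fi]
                args: list = []
                in_vars: set[Var] = set()
                out_vars: set[Var] = set()
                pending: list[tuple[str, str]] = []  # new (type, const) to lift
                feasible = True
                for role, atype, value in zip(mode.roles, mode.types, fact.args):
                    if role == "+":
                        args.append(var)
                        in_vars.add(var)
                    elif role == "#":
                        args.append(value)
                    else:  # output variable
                        existing = var_of.get((atype, value))
                        if existing is not None:
                            args.append(existing)
                            out_vars.add(existing)
                        else:
                            if d + 1 > cfg.max_chain_depth:
                                feasible = False
                                break
                            args.append(("NEW", atype, value))
                            pending.append((atype, value))
                if not feasible:
                    continue
                final_args: list = []
                new_entries: list[tuple[tuple[str, str], Var]] = []
                for a in args:
                    if isinstance(a, tuple) and a and a[0] == "NEW":
                        key = (a[1], a[2])
                        made = dict(new_entries).get(key)
                        if made is None:
                            made = Var(next(name_iter))
                            new_entries.append((key, made))
                        final_args.append(made)
                        out_vars.add(made)
                    else:
                        final_args.append(a)
                lit = Atom(mode.predicate, tuple(final_args))
                if lit in seen:
                    continue
                seen.add(lit)
                for key, v in new_entries:
                    var_of[key] = v
                    depth_of[v] = d + 1
                    agenda.append((v, key[1], key[0]))
                literals.append(
                    BottomLiteral(lit, frozenset(in_vars), frozenset(out_vars))
                )
                mode_count[mi] += 1
    return literals


# -------------------------------------------------------------------- coverage
def covers(rule: Rule | Sequence[Atom], drug: str, kb: KnowledgeBase) -> bool:
    """True iff the rule body has a satisfying binding with A bound to the drug."""
    body = rule.body if isinstance(rule, Rule) else tuple(rule)
    return kb.ask(body, {HEAD_VAR: drug})


def coverage(rule: Rule | Sequence[Atom], drugs: Iterable[str], kb: KnowledgeBase) -> frozenset[str]:
    return frozenset(d for d in drugs if covers(rule, d, kb))


# ------------------------------------------------------------------ rule search
@dataclasses.dataclass(frozen=True)
class _State:
    body: tuple[int, ...]
    avail: frozenset[Var]
    pos_cov: frozenset[str]
    neg_cov: frozenset[str]


def search_rule(
    seed: str,
    pos: Sequence[str],
    neg: Sequence[str],
    kb: KnowledgeBase,
    cfg: ILPConfig = ILPConfig(),
    modes: Sequence[ModeDecl] = DEFAULT_MODES,
) -> Rule | None:
    """Beam search over connected sub-bodies of the seed's bottom clause.

    Returns the rule maximizing P subject to P >= min_pos and N <= noise
    (ties: fewer literals, then discovery order), or None.
    """
    if seed not in pos:
        raise ValueError("seed must be a positive example")
    bottom = saturate(seed, kb, modes, cfg)
    if not bottom:
        return None
    pos_all = frozenset(pos)
    neg_all = frozenset(neg)
    init = _State((), frozenset({HEAD_VAR}), pos_all, neg_all)
    beam: list[tuple[float, int, _State]] = [(0.0, 0, init)]
    best: tuple[tuple[int, int, int], Rule] | None = None
    seen_bodies: set[frozenset[int]] = set()
    order = 0

    for _ in range(cfg.max_body_literals):
        pool: list[tuple[float, int, _State]] = []
        for _, _, state in beam:
            for bi, bl in enumerate(bottom):
                if bi in state.body or not bl.in_vars <= state.avail:
                    continue
                key = frozenset(state.body) | {bi}
                if key in seen_bodies:
                    continue
                seen_bodies.add(key)
                body_lits = tuple(bottom[j].literal for j in state.body) + (bl.literal,)
                pos_cov = frozenset(
                    d for d in state.pos_cov if kb.ask(body_lits, {HEAD_VAR: d})
                )
                if len(pos_cov) < cfg.min_pos:
                    continue
                neg_cov = frozenset(
                    d for d in state.neg_cov if kb.ask(body_lits, {HEAD_VAR: d})
                )
                order += 1
                new = _State(
                    state.body + (bi,), state.avail | bl.out_vars, pos_cov, neg_cov
                )
                if len(neg_cov) <= cfg.noise:
                    cand_key = (len(pos_cov), -len(new.body), -order)
                    if best is None or cand_key > best[0]:
                        best = (
                            cand_key,
                            Rule(body_lits, len(pos_cov), len(neg_cov), pos_cov),
                        )
                pool.append((float(len(pos_cov) - len(neg_cov)), order, new))
        pool.sort(key=lambda t: (-t[0], t[1]))
        beam = pool[: cfg.beam_width]
        if not beam:
            break
    return best[1] if best else None


def induce_cover(
    pos: Sequence[str],
    neg: Sequence[str],
    kb: KnowledgeBase,
    cfg: ILPConfig = ILPConfig(),
    modes: Sequence[ModeDecl] = DEFAULT_MODES,
    sep_id: str = "sep",
) -> Theory:
    """Greedy covering loop with overlapping rules.

    Seeds are taken in fixed input order among positives not yet covered by
    any accepted rule; each accepted rule's P and N are measured against the
    full example sets, so coverage overlap between rules is allowed.
    """
    pos = list(pos)
    neg = list(neg)
    if set(pos) & set(neg):
        raise ValueError("positive and negative sets overlap")
    rules: list[Rule] = []
    covered: set[str] = set()
    if cfg.min_pos <= len(pos):
        for seed in pos:
            if seed in covered:
                continue
            rule = search_rule(seed, pos, neg, kb, cfg, modes)
            if rule is None:
                continue
            rules.append(rule)
            covered |= rule.pos_covered
            if len(covered) == len(pos):
                break
    uncovered = tuple(d for d in pos if d not in covered)
    return Theory(sep_id, rules, cfg, uncovered)


def predict_theory(theory: Theory, drug: str, kb: KnowledgeBase) -> bool:
    """Positive iff the drug is covered by at least one rule."""
    return any(covers(r, drug, kb) for r in theory.rules)
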