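# Methods

This note records the scientific and numerical choices behind `sepminer`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the known limitations.

## Relational knowledge base

Ground facts range over a fixed vocabulary —
`category/2, drug_cluster/3, drug_has_target/3, goterm/2, go_relation/3,
interact/2, pathway/3, domain/2` — with constrained label arguments
(`drug_has_target` actions in {activator, inhibitor, other}; `go_relation`
types in {is_a, part_of}; `drug_cluster` and `pathway` carry a
source/method label). Facts are stored one TSV per predicate (UTF-8, header
row), deduplicated, and indexed by predicate and by every argument position.

`interact` is symmetrized at load time because rule bodies traverse
interactions directionlessly. The `go_relation` graph restricted to each
relation type is checked to be acyclic.

Conjunctive queries with variables are answered by depth-first backtracking
with per-argument indexing, literals evaluated left to right and candidate
facts visited in insertion order, which makes the binding stream
deterministic. A result cap (default 10^6 bindings) guards degenerate
queries. The knowledge bases here are desk-scale; the engine favors
correctness and reproducibility over join optimization.

## Term clustering

**Similarity.** Terms live in a rooted DAG with `is_a`/`part_of` edges (both
treated alike). `depth(t)` is the shortest edge count to the nearest root.
The similarity is Wu–Palmer generalized to a DAG:

    sim(a, b) = 2 · depth(c*) / (depth(a) + depth(b)),

`c*` the common ancestor maximizing the ratio (equivalently the deepest
common ancestor), `sim(t, t) = 1` by convention (this also covers the
root/root case where the denominator vanishes). The measure is purely
structural; no corpus frequencies are needed.

**Agglomeration.** Distance is `1 − sim`; Ward's method is applied through
`scipy.cluster.hierarchy.linkage` (Lance–Williams recurrence on squared
distances). The test suite cross-checks the merge sequence against an
independent hand-rolled Lance–Williams implementation.

**Cut selection.** The Kelley–Gardner–Sutcliffe penalty: at every level with
`k` clusters (`2 ≤ k ≤ n−1`), the spread is the mean over clusters of size
≥ 2 of their average within-cluster pairwise distance; spreads are min-max
normalized onto `[1, n−2]` across levels and `k` is added; the level with
minimal penalty wins, ties resolved toward smaller `k` (coarser clusterings
are easier to interpret). Note the normalization stretches whatever spread
variation exists onto the full range, so the automatic cut reflects
*relative* tightening between levels; when every level is equally tight the
tie-break returns `k = 2`.

**Naming.** Cluster indices 1..k follow dendrogram leaf order. The
representative is the cluster medoid (maximal average similarity to
co-members); exact ties go to the lexicographically smallest label. The
display name is `{index}_{representative}`.

The number of clusters is data-driven (or user-overridden); no particular
count is privileged.

## Drug × TC fingerprints

With `k_i` the size of `TC_i`, the minimal number of member side effects
required to associate the TC with a drug is

    n_i = min(n_max, ⌈k_i / interval_width⌉),   defaults interval_width = 5, n_max = 5,

i.e. sizes 1–5 require 1 term, 6–10 require 2, …, ≥ 21 require 5. This is
the trade-off between `n_i = 1` (tables too dense to mine) and `n_i = k_i`
(so stringent that real associations are missed). Annotation terms missing
from the clustering's vocabulary are skipped and counted, not errors — real
vocabularies drift.

TC columns covering strictly more than 50% of the drugs are removed before
mining ("more than" is read strictly: exactly 50% is retained).

## Side-effect profiles (maximal frequent itemsets)

The default support threshold is `⌈0.2 · n_drugs⌉`; an absolute override is
provided. The miner is a vertical depth-first search on row bitsets with
support pruning; an itemset is emitted iff no single-item extension stays
frequent, which by anti-monotonicity characterizes maximality exactly. An
exhaustive `2^m` enumerator (`brute_force_mfis`, m ≤ 20) is kept in the
package as the oracle; the two are asserted equal on randomized tables.

Output order is fixed — support descending, then lexicographic itemset — so
SEP identifiers are reproducible. A direct consequence of maximality, used
as an acceptance property: at threshold `s`, two distinct MFIs are jointly
contained in at most `s − 1` objects.

## Decision trees

Single-table encoding: one indicator per drug category, three per target
(activation / inhibition / other), one per structural-cluster membership;
the class column is `pos`/`neg` for the SEP. Trees are grown top-down with
the gain-ratio criterion over binary value-vs-rest tests; candidate splits
leaving a child below `min_leaf = 5` rows are not considered; ties on gain
ratio go to the earlier column, making induction deterministic. Pruning is
bottom-up pessimistic-error pruning at confidence `cf = 0.25`, with the
upper confidence limit of the binomial error computed by the standard
normal approximation. Subtree raising is omitted: its effect is marginal at
this scale and it complicates the implementation substantially. Inputs are
complete binary tables, so fractional (missing-value) splits are not
implemented; at prediction time a missing attribute follows the
not-equals branch. Tables export to ARFF (a small plain-text writer lives
in the module) and TSV.

## Relational rule induction

**Modes.** Each predicate argument is declared input (`+`), output (`-`) or
constant (`#`) with an entity type. Action types, pathway/cluster sources,
relation types, category labels, cluster labels and annotation labels may
surface as constants in rules; drug and protein arguments are always
variablized. `goterm` and `go_relation` each carry two modes — a constant
form and a chaining form — so rules can either name an annotation or chain
through it (`goterm(B,C), go_relation(C,is_a,D), go_relation(D,is_a,…)`);
with the default depth budget, relation chains reach length 2.

**Saturation.** The bottom clause of a seed drug is built breadth-first from
its facts: entity constants reached through output roles are lifted to typed
variables (one variable per constant), up to `max_chain_depth = 3` steps
from the drug (drug → target → interactant → annotation), capped at
`saturation_cap = 200` literals per mode.

**Search.** Beam search (width 20) over connected sub-bodies of the bottom
clause, grown one literal at a time; a literal is addable when its input
variables are already bound. Branches whose positive coverage drops below
`min_pos` are pruned (coverage is anti-monotone in the body). A rule is
acceptable when `P ≥ min_pos = 5` and `N ≤ noise = 1`, both measured on the
**full** training sets; among acceptable rules the search keeps the one
maximizing `P`, ties to fewer literals, then discovery order. The beam is
ranked by `P − N`. Scoring by coverage rather than a compression heuristic
is deliberate: rule quality is reported as the (P, N) pair and nothing else.

**Covering loop.** `induce_cover` iterates seeds in fixed input order over
positives not yet covered by an accepted rule; accepted rules are kept even
when their coverage overlaps (a drug may be covered by several rules), and
covered positives are removed from seed selection only — they still count
in every later rule's P. The loop stops when all positives are covered or
no remaining seed yields a rule. Prediction is the disjunction of the
rules. The noise allowance reflects that absence of a side-effect
annotation is weak evidence of absence.

## Evaluation

For a SEP, positives are the fingerprint rows with all its TCs set,
negatives the rows with none set; partial matches are excluded from both
classes. Stratified cross-validation (default 10 folds × 10 runs = 100
assays) shuffles each class with a run-specific seeded generator and deals
remainder drugs to the first folds; both learners are retrained inside
every fold. Accuracy, specificity and sensitivity are reported per assay
and aggregated as mean ± sd; undefined ratios (zero denominators) are
reported as absent, never as zero.

The report-checking rule: a predicted false positive is confirmed when for
*every* TC of the SEP at least one primary-suspect report names a
side-effect term belonging to that TC. Non-primary reports never confirm.

## Synthetic data

The generator emulates the joint structure of the real-world inputs the
pipeline targets: a DAG term hierarchy (complete b-ary tree, default
branching 6 and depth 3, plus a second parent for ~10% of deeper terms),
drugs with `1 + Poisson(3)` targets (mean 4), targets annotated with GO-like
terms (with an acyclic relation graph), pathways, domains and interactions,
categories and structural-cluster labels. Term clusters used for planting
are the leaf sets under the deepest internal nodes (size 6 by default, so
`n_i = 2`).

Planted rules are restricted to the learner's own rule grammar (chains of
depth ≤ 3, ≤ 6 literals). Planting reserves dedicated entities: the planted
protein/annotation/category constants appear in no background fact, so a
drug satisfies a planted body iff it is a carrier. Carriers receive at
least `n_i` member terms of every TC of their rule's SEP with probability
`1 − fn`; non-carriers with probability `fp`; background annotation noise
is added per drug and TC but always *below* the association threshold, so
the noise floor never flips a fingerprint cell by itself. Report generation
emits primary-suspect reports across all SEP TCs for a configurable
fraction of carriers, plus non-primary decoys.

What this does **not** emulate: realistic pharmacology, GO/pathway size
distributions (background facts are uniform), correlated side-effect
co-occurrence beyond the planted profiles, or the entity counts of real
drug databases. Passing tests therefore demonstrate correctness of the
machinery under controlled ground truth, not predictive performance on
real annotation data.

## Problem sizes and numerical choices

- Default synthetic study: 300 drugs, 120 targets, 2 planted rules (one
  relational two-literal rule, one category rule), no label noise; chosen
  so that mining, both learners and cross-validation all run in seconds to
  a few minutes on one core.
- Miner/oracle equivalence is asserted on 200 random 100-row tables with up
  to 12 columns and densities 0.1–0.6; the overlap bound on 554 × 99
  Bernoulli(0.25) tables at absolute support 101.
- Ward heights and the KGS scan use exact double arithmetic; gain-ratio
  ties break by column order; similarity ties for the medoid break
  lexicographically; all stochastic procedures take explicit integer seeds
  and are bitwise reproducible.
- Degenerate inputs: a constant-class attribute table yields a single leaf
  (not an error); a seed drug with no facts yields an empty bottom clause
  and no rule; an empty fingerprint table mines to an empty SEP list;
  `min_pos > |positives|` yields an empty theory.

## Limitations

- The semantic similarity is a structural stand-in for measures defined on
  the five-level MedDRA hierarchy; cluster contents on real vocabularies
  will differ from expert-validated groupings.
- The tree learner reimplements the C4.5 family's behavior (binary splits,
  gain ratio, pessimistic pruning) but does not bit-reproduce J48's pruning
  decisions (no subtree raising, normal-approximation confidence bound).
- The rule learner searches a Progol-style bounded space; it does not offer
  randomized restarts, user-defined cost functions or per-mode recall
  bounds beyond the saturation cap.
- The `Avg overlap` column of the packaged reference profile table is
  carried through parsing but its defining formula is not part of the
  package's computations.
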