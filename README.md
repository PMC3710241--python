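# sepminer

Mining and relational characterization of drug **side-effect profiles**.

Most computational pharmacovigilance treats side effects one at a time, yet a
drug's label rarely lists a single adverse event: side effects co-occur.
`sepminer` implements an integrative pipeline that makes the co-occurrence
structure itself the object of study, for researchers working with
drug/target knowledge bases (drug categories, structural clusters,
drug–target actions, protein–protein interactions, GO-style annotations,
pathways, domains) and per-drug side-effect term lists drawn from a
MedDRA-like term hierarchy.

## The method

1. **Term clusters (TCs).** Side-effect terms are compared with a structural
   semantic similarity on the term hierarchy (Wu–Palmer generalized to a DAG:
   `sim(a,b) = 2·depth(c*) / (depth(a)+depth(b))` with `c*` the deepest common
   ancestor), agglomerated by Ward's method on `1 − sim`, and the dendrogram
   is cut at the level selected by the Kelley–Gardner–Sutcliffe penalty. A
   cluster is named `{index}_{representative}`, the representative being its
   medoid.
2. **Fingerprints.** A drug is associated with `TC_i` (of size `k_i`) when it
   is annotated with at least `n_i = min(5, ⌈k_i/5⌉)` of the cluster's member
   terms, giving a binary drug × TC table. TCs covering more than 50% of the
   drugs are dropped.
3. **Side-effect profiles (SEPs).** SEPs are the *maximal frequent itemsets*
   (MFIs) of that table: the longest TC combinations shared by at least the
   support threshold of drugs (default: 20% of the drug set). Maximality
   implies that two distinct SEPs can never be jointly carried by more drugs
   than the threshold allows.
4. **Characterization.** For each SEP, positives are the drugs carrying all
   its TCs and negatives the drugs carrying none. Two explicit models are
   learned per SEP: a binary-split gain-ratio decision tree (`minNumObj = 5`)
   over single-table descriptors, and a relational theory induced
   Progol-style (bottom-clause saturation + beam search, `min-pos = 5`,
   `noise = 1`, overlapping *induce-cover* loop) whose rules chain
   drug → target → interactant → annotation, e.g.

   ```
   sep(A) :- drug_has_target(A,B,inhibitor), pathway(B,'Endocytosis',kegg)
   ```

5. **Evaluation.** 10 × 10 stratified cross-validation (accuracy,
   specificity, sensitivity), direct testing on held-out drugs, and a
   checking rule against an adverse-event report table: a predicted false
   positive is *confirmed* when, for every TC of the SEP, some
   primary-suspect report names a side effect in that TC.

A first-class synthetic-data module generates the whole relational world —
hierarchy, knowledge base, annotations, reports — with planted SEPs and
planted relational rules, so every stage can be tested against ground truth.

## Worked example

```bash
sepminer simulate --seed 1 --out-dir demo     # 300 drugs, 2 planted rules
sepminer fingerprint --out-dir demo
sepminer mine --out-dir demo
sepminer learn-ilp --out-dir demo
```

which logs

```
[simulate] seed=1 drugs=300 facts=3651 planted_rules=2 out=demo wall=0.05s
[fingerprint] drugs=300 tcs=36 kept_tcs=36 skipped_terms=0 wall=0.03s
[mine] min_support=60 seps=2 wall=0.01s
[learn-ilp] seps=2 rules=2 min_pos=5 noise=1 wall=10.02s
```

`demo/seps.tsv` holds the two mined profiles — exactly the planted ones
(TC pairs `{1,2}` and `{3,4}`, each carried by 75 of the 300 drugs):

```
sep_id  composition  support
SEP_1   1, 2         75
SEP_2   3, 4         75
```

and `demo/ilp_theories/SEP_1.rules` contains the induced theory, which
recovers the planted relational mechanism with perfect coverage (P = 75
positives, N = 0 negatives):

```
theory SEP_1: 1 rules
1  drug_has_target(A,G,inhibitor), pathway(G,pw_planted_r1,kegg)  75  0
```

The package also ships a 26-profile reference table;
`sepminer stats --out-dir demo` summarizes it:

```
n_seps             26
n_distinct_tcs     18
length_histogram   {"1": 3, "2": 13, "3": 9, "4": 1}
max_tc_frequency   8
min_support        110
```

i.e. 26 profiles over 18 distinct TCs, three singleton profiles, thirteen
pairs, nine triples and one quadruple, the busiest TCs appearing in 8
profiles, all profiles supported by at least 110 drugs.

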