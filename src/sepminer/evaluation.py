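"""Learning sets, stratified cross-validation, direct testing and the
pharmacovigilance checking rule.

For a given SEP, positives are the drugs whose fingerprint contains every TC
of the profile and negatives are the drugs associated with none of them;
drugs matching only part of the profile belong to neither class.  Models are
scored by accuracy, specificity and sensitivity over 10 runs of 10-fold
stratified cross-validation, and predicted false positives can be checked
against an adverse-event report table: a drug is confirmed when, for every TC
of the SEP, at least one primary-suspect report names a side effect belonging
to that TC.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np

from .clustering import TermClustering
from .fingerprints import FingerprintTable
from .kb import KnowledgeBase
from .mining import SEP

#: trainer(pos_train, neg_train) -> predict(drug_id) -> bool
Trainer = Callable[[Sequence[str], Sequence[str]], Callable[[str], bool]]


@dataclasses.dataclass(frozen=True)
class LearningSet:
    sep_id: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...]
    excluded: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def metrics(cm: ConfusionMatrix) -> tuple[float | None, float | None, float | None]:
    """(accuracy, specificity, sensitivity); undefined ratios are None."""
    return cm.accuracy, cm.specificity, cm.sensitivity


def build_learning_set(table: FingerprintTable, sep: SEP) -> LearningSet:
    """Split the fingerprint rows into positives / negatives / excluded."""
    missing = [tc for tc in sep.tcs if tc not in table.frame.columns]
    if missing:
        raise ValueError(f"SEP TCs missing from the table: {missing}")
    sub = table.frame[list(sep.tcs)]
    hits = sub.sum(axis=1)
    pos, neg, exc = [], [], []
    for drug, h in hits.items():
        if h == len(sep.tcs):
            pos.append(drug)
        elif h == 0:
            neg.append(drug)
        else:
            exc.append(drug)
    return LearningSet(sep.id, tuple(pos), tuple(neg), tuple(exc))


def _stratified_folds(
    items: Sequence[str], folds: int, rng: np.random.Generator
) -> list[list[str]]:
    items = list(items)
    rng.shuffle(items)
    base, rem = divmod(len(items), folds)
    out, start = [], 0
    for f in range(folds):
        size = base + (1 if f < rem else 0)
        out.append(items[start:start + size])
        start += size
    return out


def stratified_cv(
    learning_set: LearningSet,
    trainer: Trainer,
    folds: int = 10,
    runs: int = 10,
    seed: int = 0,
) -> list[ConfusionMatrix]:
    """runs x folds stratified cross-validation; one confusion matrix per assay.

    Folds preserve the class ratio within one drug: remainders go to the
    first folds.  The fold assignment is fully determined by ``seed``.
    """
    pos, neg = list(learning_set.positives), list(learning_set.negatives)
    for name, cls in (("positive", pos), ("negative", neg)):
        if len(cls) < folds:
            raise ValueError(
                f"{name} class has {len(cls)} members < {folds} folds; "
                "use fewer folds"
            )
    assays: list[ConfusionMatrix] = []
    for run in range(runs):
        rng = np.random.default_rng([seed, run])
        pos_folds = _stratified_folds(pos, folds, rng)
        neg_folds = _stratified_folds(neg, folds, rng)
        for f in range(folds):
            test_pos, test_neg = pos_folds[f], neg_folds[f]
            train_pos = [d for g in range(folds) if g != f for d in pos_folds[g]]
            train_neg = [d for g in range(folds) if g != f for d in neg_folds[g]]
            predict = trainer(train_pos, train_neg)
            tp = sum(1 for d in test_pos if predict(d))
            fn = len(test_pos) - tp
            fp = sum(1 for d in test_neg if predict(d))
            tn = len(test_neg) - fp
            assays.append(ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn))
    return assays


def summarize_cv(assays: Sequence[ConfusionMatrix]) -> dict:
    """Mean and standard deviation of the three metrics over the assays."""
    out = {}
    for name in ("accuracy", "specificity", "sensitivity"):
        vals = [getattr(cm, name) for cm in assays if getattr(cm, name) is not None]
        out[name] = float(np.mean(vals)) if vals else None
        out[name + "_sd"] = float(np.std(vals)) if vals else None
    return out


def direct_test(
    predict: Callable[[str], bool],
    test_drugs: Sequence[str],
    kb: KnowledgeBase,
    table: FingerprintTable,
    sep: SEP,
) -> tuple[ConfusionMatrix, list[str], list[str]]:
    """Evaluate a model on held-out drugs labelled by the learning-set rule.

    Returns the confusion matrix, the false-positive drug list (candidates
    for report checking) and the drugs skipped (absent from the knowledge
    base or only partially matching the profile).
    """
    tp = fp = tn = fn = 0
    fps: list[str] = []
    skipped: list[str] = []
    sub = table.frame[list(sep.tcs)]
    for d in test_drugs:
        if d not in kb.drugs or d not in table.frame.index:
            skipped.append(d)
            continue
        hits = int(sub.loc[d].sum())
        if 0 < hits < len(sep.tcs):
            skipped.append(d)
            continue
        label = hits == len(sep.tcs)
        pred = predict(d)
        if pred and label:
            tp += 1
        elif pred and not label:
            fp += 1
            fps.append(d)
        elif not pred and label:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn), fps, skipped


# ------------------------------------------------------------- report checking
@dataclasses.dataclass(frozen=True)
class FaersReport:
    drug: str
    term: str
    role: str  # 'primary_suspect' or 'other'


@dataclasses.dataclass
class FaersReportSet:
    records: list[FaersReport]

    def __len__(self) -> int:
        return len(self.records)

    def primary_terms(self, drug: str) -> set[str]:
        return {
            r.term for r in self.records
            if r.drug == drug and r.role == "primary_suspect"
        }

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("drug_id\tterm_id\trole\n")
            for r in self.records:
                fh.write(f"{r.drug}\t{r.term}\t{r.role}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "FaersReportSet":
        records = []
        with open(path, encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                line = line.rstrip("\n")
                if line:
                    drug, term, role = line.split("\t")
                    records.append(FaersReport(drug, term, role))
        return cls(records)


def faers_check(
    fp_drugs: Iterable[str],
    sep: SEP,
    reports: FaersReportSet,
    clustering: TermClustering,
) -> list[str]:
    """Confirm predicted false positives against the report table.

    A drug is confirmed iff for every TC of the SEP there is at least one
    primary-suspect report whose side-effect term belongs to that TC.
    """
    confirmed = []
    for d in fp_drugs:
        terms = reports.primary_terms(d)
        tc_members = []
        for tc in sep.tcs:
            idx = tc if isinstance(tc, int) else None
            if idx is None:
                # named TC ("12_Label") -> index before the first underscore
                idx = int(str(tc).split("_", 1)[0])
            tc_members.append(clustering[idx].members)
        if all(terms & members for members in tc_members):
            confirmed.append(d)
    return confirmed
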