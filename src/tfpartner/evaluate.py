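"""Cross-validation and hold-out evaluation with accuracy / sensitivity / specificity.

Fold assignment is stratified by class label and depends only on the set of
pairs and the seed — never on input file order — so reports are reproducible
and order-insensitive.  Rates are aggregated by pooling confusion counts
across folds (micro-averaging) and recompute exactly from the stored counts
using rational arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from typing import IO, Mapping, Sequence

import numpy as np

from .features import FeatureVector, Task, TASK_TARGETS
from .models import (
    DEFAULT_THRESHOLD,
    DualModel,
    Hyperparameters,
    ScoringMode,
    predict_pair,
    train_dual_model,
)
from .sequences import InteractionPair

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "FoldResult",
    "EvalReport",
    "metrics_from_counts",
    "assign_folds",
    "cross_validate",
    "split_evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    """Accuracy, sensitivity (TPR) and specificity (TNR).

    A rate whose denominator is zero is ``None`` (undefined), never silently 0.
    """

    accuracy: float
    sensitivity: float | None
    specificity: float | None


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """sensitivity = tp/(tp+fn), specificity = tn/(tn+fp), accuracy = (tp+tn)/total.

    Computed with exact rational arithmetic before the final float conversion.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero confusion counts")
    accuracy = float(Fraction(c.tp + c.tn, c.total))
    sensitivity = float(Fraction(c.tp, c.tp + c.fn)) if (c.tp + c.fn) > 0 else None
    specificity = float(Fraction(c.tn, c.tn + c.fp)) if (c.tn + c.fp) > 0 else None
    return Metrics(accuracy, sensitivity, specificity)


@dataclass(frozen=True)
class FoldResult:
    """Confusion counts of one evaluation fold, for the combined dual-model
    score and for each sub-model alone."""

    counts: ConfusionCounts
    counts_forward: ConfusionCounts
    counts_reverse: ConfusionCounts
    class_balance: dict[str, int]
    n_train: int
    n_test: int


@dataclass
class EvalReport:
    task: Task
    scheme: str
    seed: int
    threshold: float
    scoring_mode: ScoringMode
    folds: list[FoldResult] = field(default_factory=list)

    def _pooled(self, attr: str) -> ConfusionCounts:
        total = ConfusionCounts()
        for f in self.folds:
            total = total + getattr(f, attr)
        return total

    @property
    def aggregate_counts(self) -> ConfusionCounts:
        return self._pooled("counts")

    @property
    def metrics(self) -> Metrics:
        return metrics_from_counts(self.aggregate_counts)

    @property
    def metrics_forward(self) -> Metrics:
        return metrics_from_counts(self._pooled("counts_forward"))

    @property
    def metrics_reverse(self) -> Metrics:
        return metrics_from_counts(self._pooled("counts_reverse"))

    def to_dict(self) -> dict:
        agg = self.aggregate_counts
        m = self.metrics
        return {
            "task": self.task.value,
            "scheme": self.scheme,
            "seed": self.seed,
            "threshold": self.threshold,
            "scoring_mode": self.scoring_mode.value,
            "aggregate": {
                "tp": agg.tp, "fp": agg.fp, "tn": agg.tn, "fn": agg.fn,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
            },
            "folds": [
                {
                    "tp": f.counts.tp, "fp": f.counts.fp,
                    "tn": f.counts.tn, "fn": f.counts.fn,
                    "class_balance": f.class_balance,
                    "n_train": f.n_train, "n_test": f.n_test,
                }
                for f in self.folds
            ],
        }

    def write_json(self, stream: IO[str]) -> None:
        json.dump(self.to_dict(), stream, indent=2)
        stream.write("\n")

    def tsv_row(self) -> str:
        m = self.metrics

        def fmt(x: float | None) -> str:
            return "NA" if x is None else f"{x:.6f}"

        return "\t".join([
            self.task.value, self.scheme, str(self.seed),
            fmt(m.accuracy), fmt(m.sensitivity), fmt(m.specificity),
        ])

    TSV_HEADER = "task\tscheme\tseed\taccuracy\tsensitivity\tspecificity"


def _labeled_subset(pairs: Sequence[InteractionPair], task: Task) -> list[InteractionPair]:
    targets = TASK_TARGETS[task]
    for p in pairs:
        if p.label is None:
            raise ValueError(f"pair ({p.tf_id}, {p.partner_id}) is unlabeled")
    return [p for p in pairs if p.label in targets]


def _canonical_class_order(pairs: Sequence[InteractionPair]) -> list[tuple[str, list[int]]]:
    """Group pair positions by label, classes and members in a canonical sorted
    order so the result is independent of input ordering."""
    by_label: dict[str, list[int]] = {}
    for i, p in enumerate(pairs):
        by_label.setdefault(p.label, []).append(i)
    out = []
    for label in sorted(by_label):
        members = sorted(by_label[label], key=lambda i: (pairs[i].tf_id, pairs[i].partner_id))
        out.append((label, members))
    return out


def assign_folds(pairs: Sequence[InteractionPair], k: int, seed: int) -> np.ndarray:
    """Stratified fold assignment: per class, members are shuffled (seeded per
    class) and dealt round-robin, keeping class proportions within +-1 per fold.

    Depends only on the identities and labels of the pairs and on the seed.
    """
    n = len(pairs)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of pairs ({n}); use a smaller k")
    folds = np.empty(n, dtype=int)
    offset = 0  # rolling offset balances fold sizes across classes (k = n works)
    for ci, (label, members) in enumerate(_canonical_class_order(pairs)):
        if len(members) < 2:
            raise ValueError(
                f"class {label!r} has {len(members)} pair(s); at least 2 per class "
                "are required for cross-validation (use a smaller k or more data)"
            )
        rng = np.random.default_rng([seed, ci])
        perm = rng.permutation(len(members))
        for j, pos in enumerate(perm):
            folds[members[pos]] = (offset + j) % k
        offset = (offset + len(members)) % k
    return folds


def _evaluate_fold(
    train_pairs: list[InteractionPair],
    test_pairs: list[InteractionPair],
    features: Mapping[str, FeatureVector],
    task: Task,
    hyperparameters: Hyperparameters,
    seeds: tuple[int, int],
    scoring_mode: ScoringMode,
    threshold: float,
) -> FoldResult:
    model: DualModel = train_dual_model(
        train_pairs, features, task, hyperparameters, seeds, scoring_mode
    )
    targets = TASK_TARGETS[task]
    counts = {"combined": [0, 0, 0, 0], "forward": [0, 0, 0, 0], "reverse": [0, 0, 0, 0]}

    def tally(key: str, truth: int, called_pos: bool) -> None:
        # order: tp, fp, tn, fn
        if truth == 1:
            counts[key][0 if called_pos else 3] += 1
        else:
            counts[key][2 if not called_pos else 1] += 1

    balance: dict[str, int] = {}
    for pair in test_pairs:
        truth = targets[pair.label]
        balance[pair.label] = balance.get(pair.label, 0) + 1
        pred = predict_pair(model, pair, features, scoring_mode, threshold)
        tally("combined", truth, pred.score >= threshold)
        tally("forward", truth, pred.sub_scores["forward"] >= threshold)
        tally("reverse", truth, pred.sub_scores["reverse"] >= threshold)
    return FoldResult(
        counts=ConfusionCounts(*counts["combined"]),
        counts_forward=ConfusionCounts(*counts["forward"]),
        counts_reverse=ConfusionCounts(*counts["reverse"]),
        class_balance=balance,
        n_train=len(train_pairs),
        n_test=len(test_pairs),
    )


def cross_validate(
    pairs: Sequence[InteractionPair],
    features: Mapping[str, FeatureVector],
    task: Task | str,
    k: int = 10,
    hyperparameters: Hyperparameters | None = None,
    seed: int = 0,
    seeds: tuple[int, int] = (1, 2),
    scoring_mode: ScoringMode | str = ScoringMode.DUAL_AVERAGE,
    threshold: float = DEFAULT_THRESHOLD,
) -> EvalReport:
    """Stratified k-fold cross-validation of one task's dual model.

    Each pair is tested exactly once; the dual model (both sub-models) is
    retrained for every fold.  Per-protein featurization is label-free and
    computed once up front, so there is no train/test leakage.
    """
    task = Task(task)
    hp = hyperparameters or Hyperparameters()
    scoring_mode = ScoringMode(scoring_mode)
    # canonical ordering makes the whole report independent of input file order
    usable = sorted(
        _labeled_subset(pairs, task), key=lambda p: (p.label, p.tf_id, p.partner_id)
    )
    folds = assign_folds(usable, k, seed)
    report = EvalReport(task, f"{k}-fold", seed, threshold, scoring_mode)
    for f in range(k):
        test_idx = np.flatnonzero(folds == f)
        train_pairs = [usable[i] for i in np.flatnonzero(folds != f)]
        test_pairs = [usable[i] for i in test_idx]
        report.folds.append(
            _evaluate_fold(train_pairs, test_pairs, features, task, hp,
                           seeds, scoring_mode, threshold)
        )
    return report


def _stratified_split(
    pairs: Sequence[InteractionPair], train_fraction: float, seed: int
) -> tuple[list[InteractionPair], list[InteractionPair]]:
    """Deterministic stratified split via per-class largest-remainder rounding,
    so that the total train size is round(n * fraction)."""
    n = len(pairs)
    target_train = round(n * train_fraction)
    classes = _canonical_class_order(pairs)
    quotas, remainders = [], []
    for _, members in classes:
        exact = len(members) * train_fraction
        quotas.append(int(np.floor(exact)))
        remainders.append(exact - np.floor(exact))
    shortfall = target_train - sum(quotas)
    for pos in sorted(range(len(classes)), key=lambda i: -remainders[i])[: int(shortfall)]:
        quotas[pos] += 1
    train, test = [], []
    for (label, members), quota in zip(classes, quotas):
        rng = np.random.default_rng([seed, hashlib_stable(label)])
        perm = rng.permutation(len(members))
        for j, pos in enumerate(perm):
            (train if j < quota else test).append(pairs[members[pos]])
        if quota == 0 or quota == len(members):
            raise ValueError(
                f"class {label!r} would be absent from the "
                f"{'train' if quota == 0 else 'test'} subset; adjust the fraction"
            )
    return train, test


def hashlib_stable(label: str) -> int:
    """Small stable integer from a class label, for per-class rng streams."""
    import hashlib

    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "big") % (2**31)


def split_evaluate(
    pairs: Sequence[InteractionPair],
    features: Mapping[str, FeatureVector],
    task: Task | str,
    train_fraction: float = 2 / 3,
    hyperparameters: Hyperparameters | None = None,
    seed: int = 0,
    seeds: tuple[int, int] = (1, 2),
    scoring_mode: ScoringMode | str = ScoringMode.DUAL_AVERAGE,
    threshold: float = DEFAULT_THRESHOLD,
) -> EvalReport:
    """Single stratified train/test split (e.g. 2/3-1/3 or 90%-10%).

    The split preserves class proportions; train and test are disjoint and
    their union is the input.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be strictly between 0 and 1")
    task = Task(task)
    hp = hyperparameters or Hyperparameters()
    scoring_mode = ScoringMode(scoring_mode)
    usable = _labeled_subset(pairs, task)
    train_pairs, test_pairs = _stratified_split(usable, train_fraction, seed)
    report = EvalReport(task, f"split-{train_fraction:.4g}", seed, threshold, scoring_mode)
    report.folds.append(
        _evaluate_fold(train_pairs, test_pairs, features, task, hp,
                       seeds, scoring_mode, threshold)
    )
    return report
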