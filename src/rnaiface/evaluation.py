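"""Evaluation: confusion counts, ACC/Sn/Sp/MCC, ROC AUC, and chain-level
k-fold cross-validation.

Cross-validation is chain-level: fold membership is assigned to whole protein
chains, never to individual residues, so no chain contributes residues to
both the training and test side of any fold.  Folds are balanced greedily on
residue counts to be of almost equal size.

Metric conventions: with a degenerate MCC denominator (any factor zero) MCC
is reported as 0; sensitivity or specificity with a zero denominator is
reported as NaN (undefined) and excluded from averages.  AUC is the
probability that a randomly chosen interface residue is ranked above a
randomly chosen non-interface residue, with ties counted half.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .encoding import LabeledDataset, assemble
from .learning import InterfaceClassifier, ModelSpec, classify, train

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "CVResult",
    "confusion",
    "metrics",
    "roc_auc",
    "roc_points",
    "make_folds",
    "cross_validate",
    "evaluate_predictions",
    "read_fold_file",
    "write_fold_file",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

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


@dataclass
class EvalReport:
    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, allow_nan=True)


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Count TP/FP/TN/FN; the positive class is label 1 (interface)."""
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    for arr in (t, p):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def metrics(counts: ConfusionCounts) -> tuple[float, float, float, float]:
    """(ACC, Sn, Sp, MCC) from confusion counts.

    ACC = (TP+TN)/N, Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    MCC = (TP·TN − FP·FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP)).
    """
    if counts.total < 1:
        raise ValueError("metrics need at least one counted example")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    acc = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn else math.nan
    sp = tn / (tn + fp) if tn + fp else math.nan
    denom = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return acc, sn, sp, mcc


def roc_auc(true_labels, scores) -> float:
    """Area under the ROC curve (rank-sum formulation, ties half-credit)."""
    t = np.asarray(true_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if len(np.unique(t)) < 2:
        raise ValueError("AUC is undefined when only one class is present")
    return float(roc_auc_score(t, s))


def roc_points(true_labels, scores) -> np.ndarray:
    """(FPR, TPR, threshold) triples over all thresholds, for plotting."""
    fpr, tpr, thr = roc_curve(true_labels, scores)
    return np.column_stack([fpr, tpr, thr])


def make_folds(
    chains: list[tuple[str, int]], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Assign chains to ``k`` folds of almost equal residue totals.

    Greedy balance: after a seeded shuffle, chains are placed longest-first
    into the currently lightest fold.  Every chain lands in exactly one fold
    (indices 1..k); the assignment is a pure function of the input and seed.
    """
    if len(chains) < k:
        raise ValueError(f"need at least {k} chains for {k} folds")
    ids = [cid for cid, _ in chains]
    if len(set(ids)) != len(ids):
        raise ValueError("chain ids must be unique")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(chains)))
    order.sort(key=lambda i: -chains[i][1])  # stable: shuffle breaks ties
    totals = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for i in order:
        cid, length = chains[i]
        f = int(np.argmin(totals))
        totals[f] += length
        assignment[cid] = f + 1
    return assignment


def evaluate_predictions(
    true_labels, probabilities, threshold: float = 0.5
) -> EvalReport:
    """Threshold the probabilities and compute the full report."""
    predicted = classify(probabilities, threshold)
    counts = confusion(true_labels, predicted)
    acc, sn, sp, mcc = metrics(counts)
    t = np.asarray(true_labels, dtype=int)
    auc = roc_auc(t, probabilities) if len(np.unique(t)) == 2 else None
    return EvalReport(counts, acc, sn, sp, mcc, auc)


@dataclass
class CVResult:
    fold_reports: dict[int, EvalReport]
    pooled: EvalReport
    mean_auc: float | None
    single_class_folds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "folds": {str(f): r.to_dict() for f, r in self.fold_reports.items()},
            "pooled": self.pooled.to_dict(),
            "mean_auc": self.mean_auc,
            "single_class_folds": self.single_class_folds,
        }


def cross_validate(
    datasets_by_chain: dict[str, LabeledDataset],
    spec: ModelSpec,
    folds: dict[str, int],
    threshold: float = 0.5,
) -> CVResult:
    """Chain-level k-fold cross-validation.

    For each fold f: train on every chain not assigned to f, predict on the
    chains in f.  Per-fold reports and a pooled report over the concatenated
    test predictions are both returned; the pooled report is the headline
    number, the fold-mean AUC is reported alongside.  A fold whose test
    residues are single-class gets no AUC and is flagged.
    """
    missing = set(datasets_by_chain) - set(folds)
    if missing:
        raise ValueError(f"chains without a fold assignment: {sorted(missing)}")
    fold_ids = sorted(set(folds[c] for c in datasets_by_chain))
    fold_reports: dict[int, EvalReport] = {}
    single_class: list[int] = []
    pooled_truth, pooled_probs = [], []
    for f in fold_ids:
        test_chains = {c for c in datasets_by_chain if folds[c] == f}
        train_chains = set(datasets_by_chain) - test_chains
        train_set = assemble([datasets_by_chain[c] for c in sorted(train_chains)])
        test_set = assemble([datasets_by_chain[c] for c in sorted(test_chains)])
        model = train(train_set, spec)
        probs = model.predict_interface_proba(test_set.vectors)
        predicted = classify(probs, threshold)
        counts = confusion(test_set.labels, predicted)
        acc, sn, sp, mcc = metrics(counts)
        if len(np.unique(test_set.labels)) == 2:
            auc = roc_auc(test_set.labels, probs)
        else:
            auc = None
            single_class.append(f)
        fold_reports[f] = EvalReport(counts, acc, sn, sp, mcc, auc)
        pooled_truth.append(test_set.labels)
        pooled_probs.append(probs)
    pooled = evaluate_predictions(
        np.concatenate(pooled_truth), np.concatenate(pooled_probs), threshold
    )
    aucs = [r.auc for r in fold_reports.values() if r.auc is not None]
    mean_auc = float(np.mean(aucs)) if aucs else None
    return CVResult(fold_reports, pooled, mean_auc, single_class)


def write_fold_file(folds: dict[str, int]) -> str:
    return "".join(f"{cid}\t{f}\n" for cid, f in folds.items())


def read_fold_file(text: str) -> dict[str, int]:
    folds: dict[str, int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'chain<TAB>fold'")
        folds[parts[0]] = int(parts[1])
    return folds
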