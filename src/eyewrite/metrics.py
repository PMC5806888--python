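"""Evaluation metrics: character error rate, precision/recall/F1, k-fold
splits and the input-rate summary."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorCounts",
    "ConfusionTally",
    "character_error_rate",
    "precision_recall_f1",
    "kfold_split",
    "input_rate",
]


@dataclass
class ErrorCounts:
    substitutions: int
    deletions: int
    insertions: int
    reference_length: int

    @property
    def total(self) -> int:
        return self.substitutions + self.deletions + self.insertions


def character_error_rate(ref, hyp):
    """CER = (S + D + I) / len(ref) under a minimal edit alignment.

    ``ref`` and ``hyp`` are symbol sequences (strings or tuples).  Ties
    between minimal alignments are broken in the backtrace by preferring
    substitution, then deletion, then insertion; S + D + I is unique.
    """
    ref = list(ref)
    hyp = list(hyp)
    if not ref:
        raise ValueError("empty reference")
    n, m = len(ref), len(hyp)
    D = np.zeros((n + 1, m + 1), dtype=int)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = D[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1])
            D[i, j] = min(sub, D[i - 1, j] + 1, D[i, j - 1] + 1)
    s = d = ins = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (ref[i - 1] != hyp[j - 1]):
            s += ref[i - 1] != hyp[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            d += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    counts = ErrorCounts(s, d, ins, n)
    return counts.total / n, counts


@dataclass
class ConfusionTally:
    """Per-class true-positive / false-positive / false-negative counts."""

    tp: dict
    fp: dict
    fn: dict

    @classmethod
    def from_pairs(cls, y_true, y_pred, classes=None):
        classes = list(classes) if classes is not None else sorted(set(y_true) | set(y_pred))
        tp = {c: 0 for c in classes}
        fp = {c: 0 for c in classes}
        fn = {c: 0 for c in classes}
        for t, p in zip(y_true, y_pred, strict=True):
            if t == p:
                tp[t] += 1
            else:
                fn[t] += 1
                fp[p] += 1
        return cls(tp, fp, fn)


def precision_recall_f1(tally: ConfusionTally):
    """Per-class and macro-averaged precision, recall and F1.

    Classes with undefined precision (TP+FP=0) or recall (TP+FN=0) are
    excluded from the corresponding macro average.
    """
    per_class = {}
    precs, recs, f1s = [], [], []
    any_support = False
    for c in tally.tp:
        tp, fp, fn = tally.tp[c], tally.fp[c], tally.fn[c]
        any_support = any_support or (tp + fp + fn) > 0
        prec = tp / (tp + fp) if (tp + fp) > 0 else None
        rec = tp / (tp + fn) if (tp + fn) > 0 else None
        if prec is not None and rec is not None and (prec + rec) > 0:
            f1 = 2 * prec * rec / (prec + rec)
        elif prec is not None and rec is not None:
            f1 = 0.0
        else:
            f1 = None
        per_class[c] = {"precision": prec, "recall": rec, "f1": f1}
        if prec is not None:
            precs.append(prec)
        if rec is not None:
            recs.append(rec)
        if f1 is not None:
            f1s.append(f1)
    if not any_support:
        raise ValueError("all-zero tally")
    macro = {
        "precision": float(np.mean(precs)) if precs else float("nan"),
        "recall": float(np.mean(recs)) if recs else float("nan"),
        "f1": float(np.mean(f1s)) if f1s else float("nan"),
    }
    return per_class, macro


def kfold_split(items, k: int = 10, seed: int = 0, labels=None):
    """Partition ``items`` into k disjoint folds (sizes differ by <= 1),
    stratified by ``labels`` when given."""
    n = len(items)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    idx = np.arange(n)
    if labels is not None:
        labels = np.asarray(labels)
        order = []
        for c in sorted(set(labels.tolist()), key=str):
            members = idx[labels == c]
            rng.shuffle(members)
            order.extend(members.tolist())
        order = np.array(order)
    else:
        order = idx.copy()
        rng.shuffle(order)
    folds = [[] for _ in range(k)]
    for pos, i in enumerate(order):
        folds[pos % k].append(items[int(i)])
    return folds


def input_rate(transcriptions, durations_s) -> float:
    """Total characters per minute over a set of items."""
    durations_s = list(durations_s)
    if any(d <= 0 for d in durations_s):
        raise ValueError("durations must be positive")
    total_chars = sum(len(t) for t in transcriptions)
    total_min = sum(durations_s) / 60.0
    if total_min == 0:
        raise ValueError("zero total duration")
    return total_chars / total_min
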