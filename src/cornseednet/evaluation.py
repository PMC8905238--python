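"""Detection evaluation: confusion counting, precision/recall/F1, reports.

Per class, with n_TP correctly identified seeds, n_FP misidentified
detections and n_FN missed seeds:

    P  = 100 x n_TP / (n_TP + n_FP)
    R  = 100 x n_TP / (n_TP + n_FN)
    F1 = 2 P R / (P + R)

"Averaged" (macro) precision/recall/accuracy are unweighted means over the
two classes, and the reported F1 is the harmonic mean of the *macro*
precision and recall — not the mean of per-class F1 values; this is the
convention that reproduces published summary tables of this form.
Displayed values are rounded to 2 decimals, half away from zero.

Detections are matched to ground-truth seeds greedily by descending mask
Jaccard (accepting overlaps >= 0.5, one-to-one); a matched pair with equal
labels is a TP, with different labels an FP for the predicted class and an
FN for the true class, and unmatched detections / truth seeds are FP / FN.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

CLASSES = ("good", "bad")
JACCARD_THRESHOLD = 0.5


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (so 95.625 -> 95.63), as used in displays."""
    scale = 10 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * scale + 0.5) / scale)


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN counts."""

    classes: tuple = CLASSES
    tp: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)
    fn: dict = field(default_factory=dict)

    def __post_init__(self):
        for cls in self.classes:
            self.tp.setdefault(cls, 0)
            self.fp.setdefault(cls, 0)
            self.fn.setdefault(cls, 0)
        for d in (self.tp, self.fp, self.fn):
            if any(v < 0 for v in d.values()):
                raise ValueError("confusion counts must be >= 0")

    def add(self, other: "ConfusionCounts") -> "ConfusionCounts":
        out = ConfusionCounts(self.classes)
        for cls in self.classes:
            out.tp[cls] = self.tp[cls] + other.tp[cls]
            out.fp[cls] = self.fp[cls] + other.fp[cls]
            out.fn[cls] = self.fn[cls] + other.fn[cls]
        return out


def precision(counts: ConfusionCounts, cls: str):
    """100 x n_TP / (n_TP + n_FP); None (with a warning) if undefined."""
    tp, fp = counts.tp[cls], counts.fp[cls]
    if tp + fp == 0:
        warnings.warn(f"precision undefined for class {cls!r} (no detections)")
        return None
    return 100.0 * tp / (tp + fp)


def recall(counts: ConfusionCounts, cls: str):
    """100 x n_TP / (n_TP + n_FN); None (with a warning) if undefined."""
    tp, fn = counts.tp[cls], counts.fn[cls]
    if tp + fn == 0:
        warnings.warn(f"recall undefined for class {cls!r} (no truth seeds)")
        return None
    return 100.0 * tp / (tp + fn)


def f1(macro_p: float, macro_r: float) -> float:
    """Harmonic mean 2PR/(P+R) of macro precision and recall (percent in/out)."""
    if macro_p + macro_r == 0:
        return 0.0
    return 2.0 * macro_p * macro_r / (macro_p + macro_r)


def averaged_accuracy(correct: dict, totals: dict):
    """Per-class accuracies (100 x correct/total) and their unweighted mean."""
    per_class = {}
    for cls, total in totals.items():
        if total <= 0:
            raise ValueError(f"class {cls!r} has zero total")
        per_class[cls] = 100.0 * correct[cls] / total
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


def mask_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.count_nonzero(a & b)
    if inter == 0:
        return 0.0
    return inter / np.count_nonzero(a | b)


def _jaccard_matrix(instances, truth):
    jac = np.zeros((len(instances), len(truth.masks)))
    for i, inst in enumerate(instances):
        for j, tmask in enumerate(truth.masks):
            jac[i, j] = mask_jaccard(inst.mask, tmask)
    return jac


def match_detections(instances, predicted_labels, truth) -> ConfusionCounts:
    """Greedy one-to-one Jaccard matching of detections to truth seeds.

    Pairs are accepted in descending Jaccard order while >= 0.5 (ties broken
    by lowest detection then truth index, making the result invariant to
    instance ordering up to identical masks).
    """
    counts = ConfusionCounts()
    jac = _jaccard_matrix(instances, truth)
    pairs = [(jac[i, j], i, j) for i in range(jac.shape[0]) for j in range(jac.shape[1])
             if jac[i, j] >= JACCARD_THRESHOLD]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_i, used_j = set(), set()
    for _, i, j in pairs:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pred, true = predicted_labels[i], truth.labels[j]
        if pred == true:
            counts.tp[true] += 1
        else:
            counts.fp[pred] += 1
            counts.fn[true] += 1
    for i in range(len(instances)):
        if i not in used_i:
            counts.fp[predicted_labels[i]] += 1
    for j in range(len(truth.masks)):
        if j not in used_j:
            counts.fn[truth.labels[j]] += 1
    return counts


def match_detections_exhaustive(instances, predicted_labels, truth) -> ConfusionCounts:
    """Oracle matcher: enumerate all one-to-one assignments, maximise total
    accepted Jaccard.  Exponential; for small scenes / tests only."""
    jac = _jaccard_matrix(instances, truth)
    n_i, n_j = jac.shape
    best, best_score = [], -1.0
    smaller, larger = (range(n_i), range(n_j)) if n_i <= n_j else (range(n_j), range(n_i))
    for subset in itertools.permutations(larger, len(list(smaller))):
        pairs = []
        score = 0.0
        for a, b in zip(smaller, subset):
            i, j = (a, b) if n_i <= n_j else (b, a)
            if jac[i, j] >= JACCARD_THRESHOLD:
                pairs.append((i, j))
                score += jac[i, j]
        if score > best_score:
            best_score, best = score, pairs
    counts = ConfusionCounts()
    used_i = {i for i, _ in best}
    used_j = {j for _, j in best}
    for i, j in best:
        if predicted_labels[i] == truth.labels[j]:
            counts.tp[truth.labels[j]] += 1
        else:
            counts.fp[predicted_labels[i]] += 1
            counts.fn[truth.labels[j]] += 1
    for i in range(n_i):
        if i not in used_i:
            counts.fp[predicted_labels[i]] += 1
    for j in range(n_j):
        if j not in used_j:
            counts.fn[truth.labels[j]] += 1
    return counts


@dataclass
class EvaluationReport:
    """Per-class and macro precision/recall (percent), F1 of the macro values."""

    counts: ConfusionCounts
    per_class_precision: dict
    per_class_recall: dict
    macro_precision: float
    macro_recall: float
    f1: float

    def to_rows(self):
        """Rows mirroring the published comparison-table layout."""
        rows = []
        for cls in self.counts.classes:
            rows.append({
                "class": cls,
                "precision": round_display(self.per_class_precision[cls])
                if self.per_class_precision[cls] is not None else None,
                "recall": round_display(self.per_class_recall[cls])
                if self.per_class_recall[cls] is not None else None,
                "averaged_precision": round_display(self.macro_precision),
                "averaged_recall": round_display(self.macro_recall),
                "f1": round_display(self.f1),
            })
        return rows


def make_report(counts: ConfusionCounts) -> EvaluationReport:
    """Macro-average the per-class rates and compute F1 from the macro pair."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pcs = {cls: precision(counts, cls) for cls in counts.classes}
        rcs = {cls: recall(counts, cls) for cls in counts.classes}
    p_def = [v for v in pcs.values() if v is not None]
    r_def = [v for v in rcs.values() if v is not None]
    if len(p_def) < len(pcs) or len(r_def) < len(rcs):
        warnings.warn("some per-class rates are undefined and excluded from macro averaging")
    macro_p = float(np.mean(p_def)) if p_def else 0.0
    macro_r = float(np.mean(r_def)) if r_def else 0.0
    return EvaluationReport(
        counts=counts,
        per_class_precision=pcs,
        per_class_recall=rcs,
        macro_precision=macro_p,
        macro_recall=macro_r,
        f1=f1(macro_p, macro_r),
    )
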