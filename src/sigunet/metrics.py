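"""Protein-level evaluation indices.

Signal peptide is the positive class.  Besides the four usual confusion
counts, reports carry the transmembrane false-positive rate
``FPR_TM = FP_TM / N_TM`` — the fraction of transmembrane negatives that
are miscalled as signal peptides — because N-terminal transmembrane helices
are the classic confounder for signal-peptide predictors.

All degenerate denominators map to 0 so that reports are total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0
    FP_TM: int = 0
    N_TM: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN", "FP_TM", "N_TM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.FP_TM > self.FP or self.FP_TM > self.N_TM:
            raise ValueError("FP_TM cannot exceed FP or N_TM")


def mcc(c: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient; 0 when any denominator factor is 0."""
    denom = (
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if denom == 0:
        return 0.0
    return (c.TP * c.TN - c.FP * c.FN) / math.sqrt(denom)


def fpr_tm(c: ConfusionCounts) -> float:
    """False-positive rate restricted to transmembrane negatives."""
    if c.N_TM == 0:
        return 0.0
    return c.FP_TM / c.N_TM


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and F1 (harmonic mean), with 0 for empty denominators."""
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    f1 = 2 * c.TP / (2 * c.TP + c.FN + c.FP) if (2 * c.TP + c.FN + c.FP) else 0.0
    return precision, recall, f1


def f1_from_pr(precision: float, recall: float) -> float:
    """F1 directly from a precision/recall pair (harmonic mean)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate_counts(
    true_is_sp: Sequence[bool],
    true_is_tm: Sequence[bool],
    calls: Sequence[bool],
) -> ConfusionCounts:
    """Tally confusion counts over aligned truth/call sequences."""
    if not (len(true_is_sp) == len(true_is_tm) == len(calls)):
        raise ValueError("inputs must be aligned")
    c = ConfusionCounts()
    for sp, tm, call in zip(true_is_sp, true_is_tm, calls):
        if sp and call:
            c.TP += 1
        elif sp and not call:
            c.FN += 1
        elif not sp and call:
            c.FP += 1
        else:
            c.TN += 1
        if tm:
            c.N_TM += 1
            if call:
                c.FP_TM += 1
    return c


def evaluate(records, calls: Sequence[bool]) -> tuple[ConfusionCounts, dict]:
    """Evaluate sequence-level calls against records carrying truth flags.

    ``records`` need ``id``/``source_id``-free alignment: the i-th call is
    for the i-th record.  Records must expose ``is_sp``/``is_tm`` (as
    :class:`~sigunet.io.ProteinRecord` properties do) or
    ``true_is_sp``/``true_is_tm`` attributes.
    """
    if len(records) != len(calls):
        raise ValueError("records and calls must be aligned")
    sp, tm = [], []
    for r in records:
        s = getattr(r, "true_is_sp", None)
        if s is None:
            s = r.is_sp
        t = getattr(r, "true_is_tm", None)
        if t is None:
            t = r.is_tm
        if s is None or t is None:
            raise ValueError("record without labels cannot be evaluated")
        sp.append(bool(s))
        tm.append(bool(t))
    counts = evaluate_counts(sp, tm, list(calls))
    return counts, metric_report(counts)


def metric_report(c: ConfusionCounts) -> dict:
    """All indices in percent, as printed in benchmark tables."""
    precision, recall, f1 = precision_recall_f1(c)
    return {
        "MCC": 100.0 * mcc(c),
        "FPR_TM": 100.0 * fpr_tm(c),
        "Precision": 100.0 * precision,
        "Recall": 100.0 * recall,
        "F1": 100.0 * f1,
    }
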