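"""Confusion counts and the derived evaluation metrics.

The positive class is *alcoholic*.  Metrics with a zero denominator are
reported as ``None`` (undefined), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ConfusionCounts", "confusion_counts", "metrics"]

POSITIVE = "alcoholic"
NEGATIVE = "control"


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for t, p in zip(y_true, y_pred):
        for lab in (t, p):
            if lab not in (POSITIVE, NEGATIVE):
                raise ValueError(f"unknown label {lab!r}")
        if t == POSITIVE:
            counts["TP" if p == POSITIVE else "FN"] += 1
        else:
            counts["TN" if p == NEGATIVE else "FP"] += 1
    return ConfusionCounts(**counts)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(counts: ConfusionCounts) -> dict:
    """accuracy, sensitivity, specificity, ppv, npv from the counts."""
    c = counts
    return {
        "accuracy": _ratio(c.TP + c.TN, c.total),
        "sensitivity": _ratio(c.TP, c.TP + c.FN),
        "specificity": _ratio(c.TN, c.TN + c.FP),
        "ppv": _ratio(c.TP, c.TP + c.FP),
        "npv": _ratio(c.TN, c.TN + c.FN),
    }
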