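"""Confusion-count bookkeeping and the three evaluation statistics.

Ictal is the positive class throughout: sensitivity = TP/(TP+FN) is the
fraction of seizures caught, specificity = TN/(TN+FP) the fraction of
between-seizure windows correctly passed, accuracy the overall fraction
correct. All three are reported as percentages rounded half-to-even to
one decimal, the precision clinical seizure-detection results are
conventionally printed at.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ConfigError, UndefinedMetricError
from .svm import Decision

__all__ = [
    "ConfusionCounts",
    "accumulate",
    "sensitivity",
    "specificity",
    "accuracy",
    "metrics_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally with ictal (=1) as the positive class."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            TP=self.TP + other.TP,
            FP=self.FP + other.FP,
            TN=self.TN + other.TN,
            FN=self.FN + other.FN,
        )


def accumulate(
    decisions: Iterable[tuple[Decision | int, int | None]],
) -> ConfusionCounts:
    """Tally (decision, ground-truth label) pairs into confusion counts.

    Each item is ``(Decision or predicted 0/1 label, true 0/1 label)``.
    """
    tp = fp = tn = fn = 0
    for k, (pred, truth) in enumerate(decisions):
        if truth not in (0, 1):
            raise ConfigError(f"item {k}: ground-truth label missing or not 0/1: {truth!r}")
        label = pred.label if isinstance(pred, Decision) else int(pred)
        if label not in (0, 1):
            raise ConfigError(f"item {k}: predicted label must be 0/1, got {label!r}")
        if truth == 1:
            tp += label
            fn += 1 - label
        else:
            fp += label
            tn += 1 - label
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def _as_percentage(num: int, den: int, decimals: int | None) -> float:
    value = 100.0 * num / den
    if decimals is None:
        return value
    return float(np.round(value, decimals))  # round-half-to-even


def sensitivity(c: ConfusionCounts, decimals: int | None = 1) -> float:
    """TP/(TP+FN) as a percentage (ictal detection rate)."""
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive ground truth")
    return _as_percentage(c.TP, c.TP + c.FN, decimals)


def specificity(c: ConfusionCounts, decimals: int | None = 1) -> float:
    """TN/(TN+FP) as a percentage (interictal pass rate)."""
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative ground truth")
    return _as_percentage(c.TN, c.TN + c.FP, decimals)


def accuracy(c: ConfusionCounts, decimals: int | None = 1) -> float:
    """(TP+TN)/total as a percentage."""
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined: no decisions")
    return _as_percentage(c.TP + c.TN, c.total, decimals)


def metrics_report(c: ConfusionCounts) -> dict:
    """All three statistics plus the raw counts, JSON-serialisable."""
    return {
        "counts": {"TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN},
        "total": c.total,
        "sensitivity_pct": sensitivity(c),
        "specificity_pct": specificity(c),
        "accuracy_pct": accuracy(c),
    }


def format_confusion(c: ConfusionCounts) -> str:
    """Human-readable confusion matrix dump."""
    lines = [
        "                predicted",
        "                ictal  interictal",
        f"true ictal      {c.TP:6d} {c.FN:10d}",
        f"true interictal {c.FP:6d} {c.TN:10d}",
    ]
    return "\n".join(lines)


def save_metrics_json(c: ConfusionCounts, path) -> None:
    from pathlib import Path

    Path(path).write_text(json.dumps(metrics_report(c), indent=1))
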