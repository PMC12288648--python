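"""Accuracy and latency evaluation for phenotyping runs.

The pipeline's classifiers emit hard labels, not scores, so the ROC
curve of a binarized prediction has exactly three points — (0, 0),
(1 - specificity, sensitivity), (1, 1) — and its trapezoidal area is
(sensitivity + specificity) / 2, i.e. balanced accuracy. That is the
AUROC reported here, per class one-vs-rest, together with sensitivity,
specificity, the predicted-positive count, unweighted macro averages
over phenotype groups, and mean response latencies per prompt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .reference import NONE_LABEL, PHENOTYPES

__all__ = [
    "MACRO_GROUPS",
    "UndefinedMetricError",
    "ConfusionCounts",
    "ClassMetrics",
    "EvalReport",
    "binary_prediction_auroc",
    "confusion_counts",
    "one_vs_rest_metrics",
    "macro_average_auroc",
    "latency_summary",
    "evaluate_labels",
]

#: Phenotype groups for macro-averaged AUROC: encounters with no therapy
#: or a single therapy, versus multi-therapy (sequence) phenotypes.
MACRO_GROUPS: dict[str, tuple[str, ...]] = {
    "single_therapy_and_none": ("IMV Only", "NIPPV Only", "HFNI Only", NONE_LABEL),
    "multi_therapy": ("NIPPV Failure", "HFNI Failure", "IMV to NIPPV", "IMV to HFNI"),
}


class UndefinedMetricError(ValueError):
    """Truth contains a single class, so ROC-based metrics are undefined."""


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

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class ClassMetrics:
    n_true: int
    n_predicted: int
    auroc: float
    sensitivity: float
    specificity: float


def confusion_counts(pred: Sequence[bool], truth: Sequence[bool]) -> ConfusionCounts:
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise ValueError("pred and truth must have equal length")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def binary_prediction_auroc(pred: Sequence[bool], truth: Sequence[bool]) -> float:
    """AUROC of a hard binary predictor: (sensitivity + specificity) / 2.

    Requires both classes present in *truth*; a single-class truth makes
    the curve degenerate and raises :class:`UndefinedMetricError`.
    """
    c = confusion_counts(pred, truth)
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise UndefinedMetricError("truth must contain both classes")
    return (c.sensitivity + c.specificity) / 2


def one_vs_rest_metrics(
    pred_labels: Sequence[str], true_labels: Sequence[str], cls: str
) -> ClassMetrics:
    """Binarize both label vectors on membership in *cls* and evaluate."""
    if cls not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {cls!r}")
    pred = [p == cls for p in pred_labels]
    truth = [t == cls for t in true_labels]
    auroc = binary_prediction_auroc(pred, truth)
    c = confusion_counts(pred, truth)
    return ClassMetrics(
        n_true=sum(truth),
        n_predicted=sum(pred),
        auroc=auroc,
        sensitivity=c.sensitivity,
        specificity=c.specificity,
    )


def macro_average_auroc(per_class_aurocs: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-class AUROCs, to 3 decimals."""
    if len(per_class_aurocs) == 0:
        raise ValueError("cannot macro-average an empty list")
    return round(float(np.mean(per_class_aurocs)), 3)


def latency_summary(latencies_by_prompt: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Mean seconds per prompt plus the pooled overall mean.

    The overall mean pools every recorded call, so it equals the
    call-count-weighted mean of the per-prompt means.
    """
    out: dict[str, float] = {}
    pooled: list[float] = []
    for name, values in latencies_by_prompt.items():
        vals = list(values)
        if any(v < 0 for v in vals):
            raise ValueError("latencies must be non-negative")
        if vals:
            out[f"mean_{name}_seconds"] = float(np.mean(vals))
        pooled.extend(vals)
    out["mean_overall_seconds"] = float(np.mean(pooled)) if pooled else float("nan")
    out["n_calls"] = len(pooled)
    return out


@dataclass
class EvalReport:
    """Per-class table plus macro-group means and an optional latency block."""

    per_class: dict[str, ClassMetrics | None]
    macro_groups: dict[str, float | None]
    latency: dict[str, float] = field(default_factory=dict)
    n_encounters: int = 0

    def to_dict(self) -> dict:
        return {
            "n_encounters": self.n_encounters,
            "per_class": {
                cls: (None if m is None else vars(m)) for cls, m in self.per_class.items()
            },
            "macro_groups": self.macro_groups,
            "latency": self.latency,
        }

    def summary_lines(self) -> list[str]:
        lines = [f"encounters evaluated: {self.n_encounters}"]
        lines.append(f"{'phenotype':<16} {'n_true':>7} {'n_pred':>7} {'AUROC':>7} {'sens':>7} {'spec':>7}")
        for cls, m in self.per_class.items():
            if m is None:
                lines.append(f"{cls:<16} {'-':>7} {'-':>7} {'n/a':>7} {'n/a':>7} {'n/a':>7}")
            else:
                lines.append(
                    f"{cls:<16} {m.n_true:>7} {m.n_predicted:>7} "
                    f"{m.auroc:>7.3f} {m.sensitivity:>7.3f} {m.specificity:>7.3f}"
                )
        for group, mean in self.macro_groups.items():
            lines.append(f"macro AUROC [{group}]: {'n/a' if mean is None else f'{mean:.3f}'}")
        for key, val in self.latency.items():
            lines.append(f"{key}: {val}")
        return lines


def evaluate_labels(
    pred: Mapping[str, str],
    truth: Mapping[str, str],
    latencies_by_prompt: Mapping[str, Sequence[float]] | None = None,
) -> EvalReport:
    """Evaluate predicted vs. true phenotype labels per encounter.

    Only encounters present in *truth* are scored; classes with no true
    member (or absent from the truth entirely) report ``None`` metrics
    rather than a fabricated 0 or 1, and macro-group means average the
    member classes that are defined.
    """
    ids = sorted(truth)
    missing = [i for i in ids if i not in pred]
    if missing:
        raise ValueError(f"{len(missing)} encounter(s) missing predictions, e.g. {missing[:3]}")
    y_pred = [pred[i] for i in ids]
    y_true = [truth[i] for i in ids]
    per_class: dict[str, ClassMetrics | None] = {}
    for cls in PHENOTYPES:
        try:
            per_class[cls] = one_vs_rest_metrics(y_pred, y_true, cls)
        except UndefinedMetricError:
            per_class[cls] = None
    macro: dict[str, float | None] = {}
    for group, members in MACRO_GROUPS.items():
        vals = [per_class[c].auroc for c in members if per_class[c] is not None]
        macro[group] = macro_average_auroc(vals) if vals else None
    latency = latency_summary(latencies_by_prompt) if latencies_by_prompt else {}
    return EvalReport(per_class=per_class, macro_groups=macro, latency=latency, n_encounters=len(ids))
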