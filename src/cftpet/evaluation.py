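"""Confusion-matrix bookkeeping and diagnostic metrics.

Covers every metric the classifier reports: per-class sensitivity,
specificity, PPV, NPV (one-vs-rest collapse of the multiclass matrix),
overall accuracy, and rank-statistic ROC AUC.  Also provides the small
reconstruction utilities used to audit published tables for internal
consistency (accuracy from sensitivity/specificity and class sizes;
accuracy from error counts).

Convention: confusion-matrix rows are predicted classes, columns are true
classes, in the fixed order (PD, MSA, PSP).  Display rounding is one
decimal of percent, half-up.  Metrics with a zero denominator are
reported as ``None`` and flagged, never raised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import DIAGNOSES

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "metrics_from_matrix",
    "binary_accuracy_from_sens_spec",
    "accuracy_from_error_count",
    "auc_rank",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as diagnostic tables are printed."""
    scale = 10.0**decimals
    return float(np.floor(np.abs(x) * scale + 0.5) * np.sign(x) / scale)


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = predicted class, columns = true class."""

    counts: np.ndarray
    classes: tuple[str, ...] = DIAGNOSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_predictions(
        cls, y_true, y_pred, classes: tuple[str, ...] = DIAGNOSES
    ) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[idx[p], idx[t]] += 1
        return cls(counts, classes)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=[f"predicted_{c}" for c in self.classes],
            columns=[f"true_{c}" for c in self.classes],
        )
        df.to_csv(path)


@dataclass
class MetricsReport:
    """Per-class diagnostic metrics plus overall accuracy (fractions in [0,1])."""

    accuracy: float
    per_class: dict[str, dict[str, float | None]]
    undefined: list[str] = field(default_factory=list)
    auc: dict[str, float] | None = None

    def as_percent_table(self) -> pd.DataFrame:
        rows = []
        for cls, m in self.per_class.items():
            rows.append(
                {"class": cls}
                | {
                    k: (None if v is None else round_half_up(100 * v))
                    for k, v in m.items()
                }
            )
        return pd.DataFrame(rows)

    def save_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {
                "accuracy": self.accuracy,
                "per_class": self.per_class,
                "undefined": self.undefined,
                "auc": self.auc,
            },
            indent=2,
        ))


def _safe_div(num: float, den: float, flag: str, undefined: list[str]) -> float | None:
    if den == 0:
        undefined.append(flag)
        return None
    return num / den


def metrics_from_matrix(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest sensitivity/specificity/PPV/NPV per class + accuracy."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    per_class = {}
    c = cm.counts
    for i, cls in enumerate(cm.classes):
        tp = int(c[i, i])
        fp = int(c[i, :].sum() - tp)
        fn = int(c[:, i].sum() - tp)
        tn = int(cm.total - tp - fp - fn)
        per_class[cls] = {
            "sensitivity": _safe_div(tp, tp + fn, f"{cls}:sensitivity", undefined),
            "specificity": _safe_div(tn, tn + fp, f"{cls}:specificity", undefined),
            "ppv": _safe_div(tp, tp + fp, f"{cls}:ppv", undefined),
            "npv": _safe_div(tn, tn + fn, f"{cls}:npv", undefined),
        }
    accuracy = float(np.trace(c)) / cm.total
    return MetricsReport(accuracy=accuracy, per_class=per_class, undefined=undefined)


def binary_accuracy_from_sens_spec(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> float:
    """Reconstruct binary accuracy from printed sensitivity/specificity.

    TP and TN are recovered by rounding sens*n_pos and spec*n_neg to the
    nearest integer count, which must land in [0, n].
    """
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class sizes must be positive")
    tp = int(round(sens * n_pos))
    tn = int(round(spec * n_neg))
    if not (0 <= tp <= n_pos and 0 <= tn <= n_neg):
        raise ValueError("reconstructed counts fall outside [0, n]")
    return (tp + tn) / (n_pos + n_neg)


def accuracy_from_error_count(errors: int, total: int) -> float:
    """Accuracy (as a percent, one half-up decimal) from an error count."""
    if not 0 <= errors <= total:
        raise ValueError("need 0 <= errors <= total")
    return round_half_up(100.0 * (1.0 - errors / total))


def auc_rank(scores, labels) -> float:
    """ROC AUC by the Mann-Whitney rank statistic with midrank ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
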