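"""Confusion matrix and micro-averaged / per-type precision, recall, F-score.

The DDI task's standard metric pools true positives, false positives and
false negatives across the four positive classes only — the Negative class
(no interaction asserted) contributes to the pooled counts solely through its
confusions with positive classes:

    micro-P = TP̄ / (TP̄ + FP̄),  micro-R = TP̄ / (TP̄ + FN̄),
    micro-F = harmonic mean of micro-P and micro-R.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np

from .corpus import LABELS, LABEL_TO_ID, POSITIVE_LABELS

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "micro_prf",
           "error_breakdown", "as_percent"]


def as_percent(fraction: float, decimals: int = 2) -> float:
    """Format a fraction as a percentage, rounded half-up."""
    q = Decimal(10) ** -decimals
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """C×C counts; rows are true labels, columns predicted labels."""

    counts: np.ndarray
    labels: tuple[str, ...] = LABELS

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.labels)
        if self.counts.shape != (C, C):
            raise ValueError(f"expected a {C}x{C} matrix")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    def __getitem__(self, key: tuple[str, str]) -> int:
        g, p = key
        return int(self.counts[LABEL_TO_ID[g], LABEL_TO_ID[p]])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path: str | Path) -> None:
        rows = ["true\\pred\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.counts):
            rows.append(lab + "\t" + "\t".join(map(str, row)))
        Path(path).write_text("\n".join(rows) + "\n")


def _label_ids(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    return np.asarray([LABEL_TO_ID[l] for l in labels], dtype=np.int64)


def confusion(gold, pred) -> ConfusionMatrix:
    """Tally gold-vs-predicted labels (strings or integer ids)."""
    g, p = _label_ids(gold), _label_ids(pred)
    if len(g) != len(p):
        raise ValueError(f"length mismatch: {len(g)} gold vs {len(p)} predicted")
    C = len(LABELS)
    counts = np.zeros((C, C), dtype=np.int64)
    np.add.at(counts, (g, p), 1)
    return ConfusionMatrix(counts)


@dataclass
class MetricsReport:
    """Micro and per-type precision/recall/F over the positive classes."""

    micro_p: float
    micro_r: float
    micro_f: float
    per_type: dict[str, tuple[float, float, float]]
    tp: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "micro": {"precision": self.micro_p, "recall": self.micro_r,
                      "f_score": self.micro_f},
            "per_type": {lab: {"precision": p, "recall": r, "f_score": f}
                         for lab, (p, r, f) in self.per_type.items()},
            "counts": {"tp": self.tp, "fp": self.fp, "fn": self.fn},
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def format_table(self) -> str:
        """Human-readable table: per-type F columns then overall P/R/F (%)."""
        hdr = ("type      precision   recall   f-score")
        lines = [hdr, "-" * len(hdr)]
        for lab, (p, r, f) in self.per_type.items():
            lines.append(f"{lab:<10}{as_percent(p):>8.2f} {as_percent(r):>8.2f}"
                         f" {as_percent(f):>9.2f}")
        lines.append(f"{'micro':<10}{as_percent(self.micro_p):>8.2f}"
                     f" {as_percent(self.micro_r):>8.2f}"
                     f" {as_percent(self.micro_f):>9.2f}")
        return "\n".join(lines)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, metric defined as 0",
                      stacklevel=3)
        return 0.0
    return num / den


def micro_prf(cm: ConfusionMatrix) -> MetricsReport:
    """Micro and per-type P/R/F; the Negative class is excluded from pooling."""
    pos = [LABEL_TO_ID[l] for l in POSITIVE_LABELS]
    c = cm.counts
    tp = int(c[pos, pos].sum())
    fp = int(sum(c[:, j].sum() - c[j, j] for j in pos))
    fn = int(sum(c[i, :].sum() - c[i, i] for i in pos))
    p = _safe_div(tp, tp + fp, "micro precision")
    r = _safe_div(tp, tp + fn, "micro recall")
    f = _safe_div(2 * p * r, p + r, "micro f-score")
    per_type = {}
    for lab in POSITIVE_LABELS:
        i = LABEL_TO_ID[lab]
        pi = _safe_div(c[i, i], c[:, i].sum(), f"{lab} precision")
        ri = _safe_div(c[i, i], c[i, :].sum(), f"{lab} recall")
        fi = _safe_div(2 * pi * ri, pi + ri, f"{lab} f-score")
        per_type[lab] = (float(pi), float(ri), float(fi))
    return MetricsReport(micro_p=float(p), micro_r=float(r), micro_f=float(f),
                         per_type=per_type, tp=tp, fp=fp, fn=fn)


def error_breakdown(cm: ConfusionMatrix) -> dict[str, int]:
    """Summary of the misclassification structure.

    Returns counts of (a) positive instances predicted Negative, (b) Negative
    instances predicted positive, (c) positive instances predicted as a wrong
    positive class, and their total.
    """
    pos = [LABEL_TO_ID[l] for l in POSITIVE_LABELS]
    neg = LABEL_TO_ID["Negative"]
    c = cm.counts
    pos_as_neg = int(c[pos, neg].sum())
    neg_as_pos = int(c[neg, pos].sum())
    pos_confusions = int(sum(c[i, j] for i in pos for j in pos if i != j))
    return {
        "positives_as_negative": pos_as_neg,
        "negatives_as_positive": neg_as_pos,
        "positive_confusions": pos_confusions,
        "total_misclassified": pos_as_neg + neg_as_pos + pos_confusions,
    }
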