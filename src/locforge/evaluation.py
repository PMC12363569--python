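"""Multi-label evaluation: per-label MCC / F1 / AUPRC, threshold decisions
with a closest-to-threshold fallback, and location count-table metrics.

Every protein may carry several localization labels, so evaluation is
per-label binary: each label's confusion counts come from the decided
label sets, MCC and F1 are computed from those counts, and AUPRC
(average precision) is computed from the raw scores.  The decision rule
thresholds each label's score, but a protein whose scores all fall below
their thresholds is never left unlabelled — it receives the single label
whose score comes closest to (least below) its threshold.

The count-table metrics mirror how drug-target localization audits are
reported: per location, the number of true targets, predicted targets
and hits, with recall = hit/true and precision = hit/predicted in
percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "LocationCountRow",
    "EvalReport",
    "mcc",
    "f1_score",
    "auprc",
    "decide_labels",
    "calibrate_thresholds",
    "confusion_from_decisions",
    "location_count_metrics",
    "evaluate_multilabel",
    "location_rows_from_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def f1_score(counts: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 when TP = 0."""
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 0.0
    return 2 * tp / denom


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision: mean precision at each positive's rank.

    Instances are ranked by descending score; tied scores are processed
    as a single block, with the block-end precision credited to each
    positive inside the block (deterministic across sort implementations).
    Undefined without at least one positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be aligned 1D sequences")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPRC is undefined without positive instances")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    total = 0.0
    tp = 0
    seen = 0
    i = 0
    n = len(s)
    while i < n:
        j = i
        block_pos = 0
        while j < n and s[j] == s[i]:
            block_pos += int(y[j])
            j += 1
        tp += block_pos
        seen = j
        total += block_pos * (tp / seen)
        i = j
    return total / n_pos


def decide_labels(
    scores: Sequence[float], thresholds: Sequence[float] | float = 0.5
) -> list[int]:
    """Indices of decided labels: thresholded, with a nonempty fallback.

    All labels whose score meets its threshold are returned; if none
    does, the single label maximizing ``score - threshold`` is returned
    (ties to the lowest label index), so every instance gets >= 1 label.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    thr = np.broadcast_to(np.asarray(thresholds, dtype=float), scores.shape)
    chosen = np.nonzero(scores >= thr)[0]
    if chosen.size:
        return [int(i) for i in chosen]
    return [int(np.argmax(scores - thr))]


def confusion_from_decisions(
    decided: np.ndarray, truth: np.ndarray
) -> list[ConfusionCounts]:
    """Per-label confusion counts from binary decision/truth matrices."""
    decided = np.asarray(decided, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if decided.shape != truth.shape:
        raise ValueError("decision and truth matrices must be aligned")
    out = []
    for j in range(decided.shape[1]):
        d, t = decided[:, j], truth[:, j]
        out.append(
            ConfusionCounts(
                TP=int((d & t).sum()),
                TN=int((~d & ~t).sum()),
                FP=int((d & ~t).sum()),
                FN=int((~d & t).sum()),
            )
        )
    return out


@dataclass(frozen=True)
class LocationCountRow:
    location: str
    true_count: int
    predicted_count: int
    hit_count: int

    def __post_init__(self) -> None:
        if self.hit_count > min(self.true_count, self.predicted_count):
            raise ValueError(
                f"{self.location}: hits exceed true or predicted count"
            )
        if min(self.true_count, self.predicted_count, self.hit_count) < 0:
            raise ValueError("counts must be nonnegative")


def location_count_metrics(rows: Sequence[LocationCountRow]) -> dict[str, dict]:
    """Recall and precision (percent, 2 decimals) per location plus totals.

    Recall = 100 * hit / true; precision = 100 * hit / predicted.  A zero
    denominator yields ``None`` for that metric.  The totals row sums the
    three counts over all locations and recomputes both metrics from the
    summed counts.
    """
    if not rows:
        raise ValueError("no count rows supplied")
    out: dict[str, dict] = {}

    def metrics(true: int, pred: int, hit: int) -> dict:
        return {
            "true_count": true,
            "predicted_count": pred,
            "hit_count": hit,
            "recall": round(100.0 * hit / true, 2) if true else None,
            "precision": round(100.0 * hit / pred, 2) if pred else None,
        }

    for row in rows:
        out[row.location] = metrics(row.true_count, row.predicted_count, row.hit_count)
    out["Total"] = metrics(
        sum(r.true_count for r in rows),
        sum(r.predicted_count for r in rows),
        sum(r.hit_count for r in rows),
    )
    return out


def location_rows_from_predictions(
    decided: np.ndarray, truth: np.ndarray, labels: Sequence[str]
) -> list[LocationCountRow]:
    """Build count-table rows from per-protein decision and truth matrices."""
    decided = np.asarray(decided, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    return [
        LocationCountRow(
            location=lab,
            true_count=int(truth[:, j].sum()),
            predicted_count=int(decided[:, j].sum()),
            hit_count=int((decided[:, j] & truth[:, j]).sum()),
        )
        for j, lab in enumerate(labels)
    ]


@dataclass
class EvalReport:
    """Per-label and aggregate multi-label metrics."""

    labels: list[str]
    per_label_mcc: dict[str, float]
    per_label_f1: dict[str, float]
    per_label_auprc: dict[str, float | None]
    macro_mcc: float
    macro_f1: float
    macro_auprc: float
    micro_f1: float
    micro_mcc: float
    location_table: dict[str, dict] = field(default_factory=dict)
    fold_summary: dict[str, dict] | None = None

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "per_label_mcc": self.per_label_mcc,
            "per_label_f1": self.per_label_f1,
            "per_label_auprc": self.per_label_auprc,
            "macro_mcc": self.macro_mcc,
            "macro_f1": self.macro_f1,
            "macro_auprc": self.macro_auprc,
            "micro_f1": self.micro_f1,
            "micro_mcc": self.micro_mcc,
            "location_table": self.location_table,
            "fold_summary": self.fold_summary,
        }


def calibrate_thresholds(
    score_matrix: np.ndarray,
    label_matrix: np.ndarray,
    candidates: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-label decision thresholds maximizing MCC on validation data.

    Scans a candidate grid (default 0.05..0.95 in steps of 0.05) per
    label and keeps the lowest threshold attaining the best MCC of the
    simple thresholded decision (the nonempty-fallback rule is applied
    only at prediction time).
    """
    scores = np.asarray(score_matrix, dtype=float)
    truth = np.asarray(label_matrix, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("score and label matrices must be aligned")
    grid = np.asarray(candidates if candidates is not None else np.arange(0.05, 0.96, 0.05))
    thresholds = np.empty(scores.shape[1])
    for j in range(scores.shape[1]):
        best_t, best_m = grid[0], -np.inf
        for t in grid:
            d, y = scores[:, j] >= t, truth[:, j]
            m = mcc(
                ConfusionCounts(
                    TP=int((d & y).sum()),
                    TN=int((~d & ~y).sum()),
                    FP=int((d & ~y).sum()),
                    FN=int((~d & y).sum()),
                )
            )
            if m > best_m:
                best_t, best_m = t, m
        thresholds[j] = best_t
    return thresholds


def decide_matrix(score_matrix: np.ndarray, thresholds) -> np.ndarray:
    """Apply :func:`decide_labels` to every row of a score matrix."""
    scores = np.asarray(score_matrix, dtype=float)
    decided = np.zeros(scores.shape, dtype=bool)
    for i in range(scores.shape[0]):
        decided[i, decide_labels(scores[i], thresholds)] = True
    return decided


def evaluate_multilabel(
    score_matrix: np.ndarray,
    label_matrix: np.ndarray,
    thresholds: Sequence[float] | float = 0.5,
    labels: Sequence[str] | None = None,
    folds: Sequence[Sequence[int]] | None = None,
) -> EvalReport:
    """Full multi-label evaluation of a proteins x labels score matrix.

    Decisions come from the thresholded-with-fallback rule; MCC and F1
    are computed per label from the decided confusion counts, AUPRC from
    raw scores (``None`` and excluded from the macro mean for labels
    with no positive instance).  Micro aggregates pool the confusion
    counts over labels.  When ``folds`` (disjoint row-index groups) are
    given, per-fold macro metrics are summarized as mean +/- standard
    error.
    """
    scores = np.asarray(score_matrix, dtype=float)
    truth = np.asarray(label_matrix, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("score and label matrices must be aligned")
    n_labels = scores.shape[1]
    names = list(labels) if labels is not None else [f"label_{j}" for j in range(n_labels)]
    if len(names) != n_labels:
        raise ValueError("label names misaligned with matrix")

    decided = decide_matrix(scores, thresholds)
    counts = confusion_from_decisions(decided, truth)
    per_mcc = {n: mcc(c) for n, c in zip(names, counts)}
    per_f1 = {n: f1_score(c) for n, c in zip(names, counts)}
    per_ap: dict[str, float | None] = {}
    for j, n in enumerate(names):
        per_ap[n] = auprc(scores[:, j], truth[:, j].astype(int)) if truth[:, j].any() else None

    pooled = ConfusionCounts(
        TP=sum(c.TP for c in counts),
        TN=sum(c.TN for c in counts),
        FP=sum(c.FP for c in counts),
        FN=sum(c.FN for c in counts),
    )
    ap_values = [v for v in per_ap.values() if v is not None]

    fold_summary = None
    if folds is not None:
        per_fold_f1, per_fold_mcc = [], []
        for rows in folds:
            rows = list(rows)
            sub = evaluate_multilabel(scores[rows], truth[rows], thresholds, names)
            per_fold_f1.append(sub.macro_f1)
            per_fold_mcc.append(sub.macro_mcc)

        def mean_se(vals: list[float]) -> dict:
            arr = np.asarray(vals)
            se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
            return {"mean": float(arr.mean()), "se": se, "n_folds": len(arr)}

        fold_summary = {"macro_f1": mean_se(per_fold_f1), "macro_mcc": mean_se(per_fold_mcc)}

    return EvalReport(
        labels=names,
        per_label_mcc=per_mcc,
        per_label_f1=per_f1,
        per_label_auprc=per_ap,
        macro_mcc=float(np.mean(list(per_mcc.values()))),
        macro_f1=float(np.mean(list(per_f1.values()))),
        macro_auprc=float(np.mean(ap_values)) if ap_values else 0.0,
        micro_f1=f1_score(pooled),
        micro_mcc=mcc(pooled),
        location_table=location_count_metrics(
            location_rows_from_predictions(decided, truth, names)
        ),
        fold_summary=fold_summary,
    )
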