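"""Confusion-matrix metrics, ROC/AUC, macro averages and dataset summaries."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binomtest, rankdata


@dataclass(frozen=True)
class MetricsBundle:
    """Binary-classification counts and derived fractions.

    Ratios with a zero denominator are reported as 0 and flagged in
    ``undefined`` (e.g. ``{"precision"}`` when no positive predictions
    exist).
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f_measure: float
    fnr: float
    fpr: float
    auc: float | None = None
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = sorted(self.undefined)
        return d


def _safe_ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def confusion_metrics(
    predictions: np.ndarray, labels: np.ndarray, scores: np.ndarray | None = None
) -> MetricsBundle:
    """Standard binary metrics from hard predictions (1 = positive).

    Optionally attaches AUC when continuous ``scores`` are supplied and
    both classes are present.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if predictions.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    undefined: set[str] = set()
    precision = _safe_ratio(tp, tp + fp, "precision", undefined)
    recall = _safe_ratio(tp, tp + fn, "recall", undefined)
    specificity = _safe_ratio(tn, tn + fp, "specificity", undefined)
    f_measure = f_measure_from_pr(precision, recall, undefined)
    auc = None
    if scores is not None and len(set(labels.tolist())) == 2:
        auc, _ = roc_auc(scores, labels)
    return MetricsBundle(
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / predictions.size,
        precision=precision,
        recall=recall,
        specificity=specificity,
        f_measure=f_measure,
        fnr=1.0 - recall,
        fpr=1.0 - specificity,
        auc=auc,
        undefined=frozenset(undefined),
    )


def f_measure_from_pr(
    precision: float, recall: float, undefined: set[str] | None = None
) -> float:
    """Harmonic mean of precision and recall (same scale as its inputs)."""
    if precision + recall == 0:
        if undefined is not None:
            undefined.add("f_measure")
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Rank-based (Mann-Whitney) AUC with ties counted one half.

    AUC is the probability that a random positive outscores a random
    negative.  Also returns the ROC curve as an ``(k, 2)`` array of
    (FPR, TPR) points at every distinct score threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks -> half credit for ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (
        n_pos * n_neg
    )

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels == 1)
    fps = np.cumsum(sorted_labels == 0)
    # threshold boundaries: last index of each distinct score
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    curve = np.column_stack([fpr, tpr])
    return float(auc), curve


def macro_average(values) -> float:
    """Unweighted mean across channels, rounded to 2 decimals for reporting."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    return float(round(values.mean(), 2))


def dataset_summary(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-channel dataset statistics from a patch manifest.

    ``manifest`` needs columns channel, split, label.  Returns one row per
    channel with per-split class counts, totals, benign/malignant
    percentages (1 decimal) and a two-sided exact binomial test of the
    50/50 balance null.
    """
    required = {"channel", "split", "label"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    rows = []
    for channel, grp in manifest.groupby("channel", sort=True):
        counts = {}
        for split in ("train", "test", "val"):
            sub = grp[grp["split"] == split]
            counts[f"{split}_benign"] = int((sub["label"] == 0).sum())
            counts[f"{split}_malignant"] = int((sub["label"] == 1).sum())
        n_benign = int((grp["label"] == 0).sum())
        n_malignant = int((grp["label"] == 1).sum())
        total = n_benign + n_malignant
        benign_pct = round(100.0 * n_benign / total, 1)
        p = binomtest(n_benign, total, 0.5, alternative="two-sided").pvalue
        rows.append(
            {
                "channel": channel,
                **counts,
                "n_benign": n_benign,
                "n_malignant": n_malignant,
                "total": total,
                "benign_pct": benign_pct,
                "malignant_pct": round(100.0 - benign_pct, 1),
                "balance_p_value": float(p),
            }
        )
    return pd.DataFrame(rows)


def write_metrics_report(
    per_channel: dict[str, MetricsBundle], path: str | Path
) -> None:
    """JSON report: per-channel bundles plus macro averages."""
    payload = {
        "channels": {k: v.as_dict() for k, v in per_channel.items()},
    }
    aucs = [v.auc for v in per_channel.values() if v.auc is not None]
    macro = {
        "accuracy": macro_average(
            [100 * v.accuracy for v in per_channel.values()]
        ),
        "f_measure": macro_average(
            [100 * v.f_measure for v in per_channel.values()]
        ),
    }
    if aucs:
        macro["auc"] = macro_average([100 * a for a in aucs])
    payload["macro"] = macro
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
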