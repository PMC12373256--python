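"""Evaluation metrics from one-vs-rest confusion counts.

Accuracy, precision, recall, Dice and Jaccard are computed per class from
TP/FP/TN/FN and macro-averaged; a class whose denominator is zero (e.g. a
class absent from both prediction and ground truth for precision/recall) is
reported as undefined (NaN), excluded from the macro mean and logged.
Results are reported in percent, matching the convention of the
segmentation literature this package follows.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["confusion_counts", "metrics_from_counts", "evaluate_masks",
           "METRIC_NAMES", "format_metrics_table"]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "dice", "jaccard")
CLASS_NAMES = ("background", "ZP", "TE", "ICM", "blastocoele")


def confusion_counts(pred: np.ndarray, true: np.ndarray, num_classes: int = 5) -> dict:
    """One-vs-rest TP/FP/TN/FN per class, summed over all supplied pixels."""
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError("prediction and ground truth differ in size")
    n = pred.size
    joint = np.bincount(true * num_classes + pred, minlength=num_classes ** 2)
    joint = joint.reshape(num_classes, num_classes)  # rows: true, cols: pred
    tp = np.diag(joint).astype(float)
    fp = joint.sum(axis=0) - tp
    fn = joint.sum(axis=1) - tp
    tn = n - tp - fp - fn
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


def _safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    out = np.full_like(num, np.nan, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        bad = [CLASS_NAMES[i] if i < len(CLASS_NAMES) else str(i)
               for i in np.nonzero(~ok)[0]]
        logger.info("%s undefined for class(es) %s; excluded from macro mean",
                    name, ", ".join(bad))
    return out


def metrics_from_counts(counts: dict, reduction: str = "macro",
                        percent: bool = True) -> dict:
    """Accuracy/precision/recall/Dice/Jaccard from confusion counts.

    ``reduction``: ``macro`` (mean over all classes), ``per_class``
    (vectors), or ``foreground`` (mean over the 4 non-background classes).
    """
    tp, fp, tn, fn = (np.asarray(counts[k], dtype=float) for k in ("TP", "FP", "TN", "FN"))
    per = {
        "accuracy": _safe_ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        "precision": _safe_ratio(tp, tp + fp, "precision"),
        "recall": _safe_ratio(tp, tp + fn, "recall"),
        "dice": _safe_ratio(2 * tp, 2 * tp + fp + fn, "dice"),
        "jaccard": _safe_ratio(tp, tp + fp + fn, "jaccard"),
    }
    scale = 100.0 if percent else 1.0
    if reduction == "per_class":
        return {k: v * scale for k, v in per.items()}
    if reduction == "macro":
        sel = slice(None)
    elif reduction == "foreground":
        sel = slice(1, None)
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    return {k: float(np.nanmean(v[sel])) * scale for k, v in per.items()}


def evaluate_masks(preds, trues, num_classes: int = 5, reduction: str = "macro",
                   percent: bool = True) -> dict:
    """Pool confusion counts over a list of (pred, true) mask pairs and reduce."""
    total = {k: np.zeros(num_classes) for k in ("TP", "FP", "TN", "FN")}
    for p, t in zip(preds, trues):
        c = confusion_counts(p, t, num_classes)
        for k in total:
            total[k] += c[k]
    return metrics_from_counts(total, reduction=reduction, percent=percent)


def format_metrics_table(rows: list[dict], label_key: str = "method",
                         metrics=("dice", "jaccard"), sd_key_suffix: str = "_sd") -> str:
    """TSV table in the Dice/Jaccard reporting style (percent, 2 decimals,
    mean±sd when a standard deviation is present)."""
    header = [label_key.capitalize()] + [f"{m.capitalize()} (%)" for m in metrics]
    lines = ["\t".join(header)]
    for row in rows:
        cells = [str(row[label_key])]
        for m in metrics:
            val = row[m]
            sd = row.get(m + sd_key_suffix)
            cells.append(f"{val:.2f}" + (f"±{sd:.2f}" if sd is not None else ""))
        lines.append("\t".join(cells))
    return "\n".join(lines)
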