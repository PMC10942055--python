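"""Per-class diagnostic metrics from confusion-matrix counts, plus ROC / PR.

From a multiclass confusion matrix (rows = actual, columns = predicted) each
class gets one-vs-rest counts TP/FP/TN/FN, from which

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (TN + FP)

are computed.  A metric whose denominator is zero is reported as undefined
(None), never as 0.  ROC and precision-recall curves use one-vs-rest class
scores with the standard threshold sweep (trapezoidal ROC area, step-wise PR
area).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "ConfusionCounts",
    "confusion_matrix",
    "per_class_metrics",
    "roc_pr_curves",
    "round_half_up",
    "format_metrics",
    "write_report",
]


@dataclass
class ConfusionCounts:
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    n_classes: int
    total: int

    def __post_init__(self):
        for arr in (self.tp, self.fp, self.tn, self.fn):
            if (np.asarray(arr) < 0).any():
                raise ValueError("counts must be non-negative")

    @classmethod
    def single(cls, tp, fp, tn, fn):
        """One-vs-rest counts for a single class."""
        return cls(tp=np.array([tp]), fp=np.array([fp]), tn=np.array([tn]),
                   fn=np.array([fn]), n_classes=1, total=tp + fp + tn + fn)


def confusion_matrix(y_true, y_pred, n_classes):
    """Multiclass confusion matrix and the derived one-vs-rest counts."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = _skm.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    total = int(cm.sum())
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp   # predicted k but actually other
    fn = cm.sum(axis=1) - tp   # actually k but predicted other
    tn = total - tp - fp - fn
    return cm, ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn,
                               n_classes=n_classes, total=total)


def _ratio(num, den):
    return float(num) / float(den) if den > 0 else None


def per_class_metrics(counts: ConfusionCounts):
    """Accuracy / precision / sensitivity / specificity per class.

    Returns a list of dicts, one per class; undefined ratios are None.
    Accuracy is returned as a fraction (multiply by 100 for the percentage).
    """
    out = []
    for k in range(counts.n_classes):
        tp, fp = int(counts.tp[k]), int(counts.fp[k])
        tn, fn = int(counts.tn[k]), int(counts.fn[k])
        out.append({
            "accuracy": _ratio(tp + tn, tp + fp + tn + fn),
            "precision": _ratio(tp, tp + fp),
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
        })
    return out


def round_half_up(x, ndigits):
    """Decimal half-up rounding (the convention of printed metric tables)."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_metrics(metrics):
    """Render metric dicts the way diagnostic tables print them:
    ratios at 4 decimals, accuracy as a percentage at 2 decimals."""
    rows = []
    for m in metrics:
        rows.append({
            "accuracy_pct": round_half_up(m["accuracy"] * 100, 2)
            if m["accuracy"] is not None else None,
            "precision": round_half_up(m["precision"], 4),
            "sensitivity": round_half_up(m["sensitivity"], 4),
            "specificity": round_half_up(m["specificity"], 4),
        })
    return rows


def roc_pr_curves(scores, y_true):
    """One-vs-rest ROC and precision-recall curves per class.

    scores: (n, K) class scores; y_true: (n,) integer labels.  A class absent
    from y_true gets None.  Areas: trapezoidal for ROC, step interpolation
    (average precision) for PR.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    y_true = np.asarray(y_true, dtype=int)
    n_classes = scores.shape[1]
    results = []
    for k in range(n_classes):
        pos = (y_true == k).astype(int)
        if pos.sum() == 0 or pos.sum() == len(pos):
            results.append(None)
            continue
        fpr, tpr, _ = _skm.roc_curve(pos, scores[:, k])
        prec, rec, _ = _skm.precision_recall_curve(pos, scores[:, k])
        results.append({
            "roc": (fpr, tpr),
            "pr": (rec, prec),
            "auroc": float(_skm.auc(fpr, tpr)),
            "auprc": float(_skm.average_precision_score(pos, scores[:, k])),
        })
    defined = [r["auroc"] for r in results if r]
    macro = {
        "macro_auroc": float(np.mean(defined)) if defined else None,
        "macro_auprc": float(np.mean([r["auprc"] for r in results if r]))
        if defined else None,
    }
    return results, macro


def write_report(out_dir, cm, metrics, curves=None, class_names=None,
                 make_plots=True):
    """CSV of per-class metrics plus (optionally) ROC/PR and heatmap PNGs."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    n = len(metrics)
    names = class_names or [str(i) for i in range(n)]
    rows = format_metrics(metrics)
    csv_path = os.path.join(out_dir, "per_class_metrics.csv")
    with open(csv_path, "w", newline="") as f:
        writer = csv.writer(f)
        header = ["class", "accuracy_pct", "precision", "sensitivity", "specificity"]
        if curves:
            header += ["auroc", "auprc"]
        writer.writerow(header)
        for k, row in enumerate(rows):
            line = [names[k], row["accuracy_pct"], row["precision"],
                    row["sensitivity"], row["specificity"]]
            if curves:
                c = curves[0][k]
                line += [round_half_up(c["auroc"], 4) if c else None,
                         round_half_up(c["auprc"], 4) if c else None]
            writer.writerow(line)
    np.savetxt(os.path.join(out_dir, "confusion_matrix.csv"), cm,
               fmt="%d", delimiter=",")
    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(cm, cmap="Blues")
        for (i, j), v in np.ndenumerate(cm):
            ax.text(j, i, str(v), ha="center", va="center")
        ax.set_xlabel("predicted")
        ax.set_ylabel("actual")
        ax.set_xticks(range(n), names)
        ax.set_yticks(range(n), names)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "confusion_matrix.png"), dpi=100)
        plt.close(fig)
        if curves:
            per_class, _ = curves
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
            for k, c in enumerate(per_class):
                if not c:
                    continue
                ax1.plot(*c["roc"], label=f"{names[k]} (AUC={c['auroc']:.3f})")
                ax2.plot(*c["pr"], label=f"{names[k]} (AP={c['auprc']:.3f})")
            ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
            ax1.set_xlabel("false positive rate")
            ax1.set_ylabel("true positive rate")
            ax1.set_title("ROC")
            ax1.legend(fontsize=7)
            ax2.set_xlabel("recall")
            ax2.set_ylabel("precision")
            ax2.set_title("precision-recall")
            ax2.legend(fontsize=7)
            fig.tight_layout()
            fig.savefig(os.path.join(out_dir, "roc_pr.png"), dpi=100)
            plt.close(fig)
    return csv_path
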