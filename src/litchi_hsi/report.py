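"""Confusion-matrix reporting shared by the spectral and image classifiers.

Rows of the confusion matrix index the true class, columns the predicted
class.  Per-class recall (= per-class accuracy on the truth axis) is the
diagonal over the row sum; precision is the diagonal over the column sum
(0 when the column is empty).  Summary means are unweighted over the four
quality classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLASS_CODES = (0, 1, 2, 3)
CLASS_NAMES = ("fresh", "newly damaged", "2 h after damage", "4 h after damage")


@dataclass
class ClassReport:
    confusion: np.ndarray          # 4x4 counts, rows = truth, cols = predicted
    recall: np.ndarray             # per class, percent
    precision: np.ndarray          # per class, percent
    accuracy: np.ndarray           # per class (diag / row support), percent
    mean_recall: float
    mean_precision: float
    mean_accuracy: float           # unweighted mean of per-class accuracies
    overall_accuracy: float        # total correct / total, percent

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.confusion, index=CLASS_NAMES, columns=CLASS_NAMES)
        df["recall_%"] = np.round(self.recall, 2)
        df["precision_%"] = np.round(self.precision, 2)
        return df

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df = self.to_frame()
        with open(path, "w") as fh:
            df.to_csv(fh, index_label="truth \\ predicted")
            fh.write(f"mean_recall_%,{self.mean_recall:.2f}\n")
            fh.write(f"mean_precision_%,{self.mean_precision:.2f}\n")
            fh.write(f"average_accuracy_%,{self.mean_accuracy:.2f}\n")
            fh.write(f"overall_accuracy_%,{self.overall_accuracy:.2f}\n")
        return path


def classification_report(preds, truth) -> ClassReport:
    """Build a :class:`ClassReport` from predicted and true quality codes."""
    preds = np.asarray(preds, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if preds.shape != truth.shape or preds.ndim != 1:
        raise ValueError("preds and truth must be 1-D vectors of equal length")
    if preds.size == 0:
        raise ValueError("empty prediction vector")
    codes = np.array(CLASS_CODES)
    if not (np.isin(preds, codes).all() and np.isin(truth, codes).all()):
        raise ValueError("labels must lie in {0, 1, 2, 3}")

    n = len(codes)
    confusion = np.zeros((n, n), dtype=int)
    np.add.at(confusion, (truth, preds), 1)
    return report_from_confusion(confusion)


def report_from_confusion(confusion: np.ndarray) -> ClassReport:
    """Metrics from a rows-are-truth confusion matrix of counts."""
    confusion = np.asarray(confusion)
    if confusion.shape != (4, 4) or np.any(confusion < 0):
        raise ValueError("confusion matrix must be 4x4 with non-negative counts")
    diag = np.diag(confusion).astype(float)
    row = confusion.sum(axis=1).astype(float)
    col = confusion.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row > 0, 100.0 * diag / row, 0.0)
        precision = np.where(col > 0, 100.0 * diag / col, 0.0)
    total = confusion.sum()
    overall = 100.0 * diag.sum() / total if total else 0.0
    return ClassReport(
        confusion=confusion.astype(int),
        recall=recall,
        precision=precision,
        accuracy=recall.copy(),
        mean_recall=float(recall.mean()),
        mean_precision=float(precision.mean()),
        mean_accuracy=float(recall.mean()),
        overall_accuracy=float(overall),
    )


def mean_per_type(values) -> float:
    """Unweighted mean of per-class percentages, as printed in summary rows."""
    return float(np.mean(np.asarray(values, dtype=float)))
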