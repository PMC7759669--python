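"""Accuracy, confusion matrices and per-subject reports.

The headline metric for the four-class task is fraction-correct times 100.
For completeness, per-class one-vs-rest TP/TN/FP/FN counts are available
(``one_vs_rest_counts``), under which binary accuracy (TP+TN)/(TP+TN+FP+FN)
can be formed per class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = [
    "ConfusionMatrix",
    "accuracy",
    "confusion",
    "one_vs_rest_counts",
    "subject_report",
]


@dataclass
class ConfusionMatrix:
    """Counts with rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or np.any(c < 0):
            raise ValueError("counts must be a square nonnegative matrix")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return 100.0 * np.trace(self.counts) / self.total


def _check_labels(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    return y_true, y_pred


def accuracy(y_true, y_pred) -> float:
    """Percent of correctly classified trials: 100 * n_correct / n."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return 100.0 * float(_skm.accuracy_score(y_true, y_pred))


def confusion(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Confusion counts; ``counts[i, j]`` = trials of true class i predicted j."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    for v in (y_true, y_pred):
        if v.min() < 0 or v.max() >= n_classes:
            raise ValueError("labels must lie in [0, n_classes)")
    c = _skm.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    return ConfusionMatrix(c)


def one_vs_rest_counts(y_true, y_pred, n_classes: int) -> pd.DataFrame:
    """Per-class TP/TN/FP/FN under the one-vs-rest reading."""
    cm = confusion(y_true, y_pred, n_classes).counts
    total = cm.sum()
    rows = []
    for k in range(n_classes):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        rows.append({"class": k, "TP": tp, "TN": tn, "FP": fp, "FN": fn})
    return pd.DataFrame(rows).set_index("class")


def subject_report(runs: dict[str, float]) -> pd.DataFrame:
    """Per-subject accuracy table with an AVG row (arithmetic mean)."""
    if not runs:
        raise ValueError("need at least one subject run")
    df = pd.DataFrame(
        {"accuracy": [float(v) for v in runs.values()]},
        index=list(runs.keys()),
    )
    df.loc["AVG"] = df["accuracy"].mean()
    df.index.name = "subject"
    return df


def render_confusion(cm: ConfusionMatrix, path, class_names=None) -> None:
    """Optionally render a confusion matrix to an image file (needs matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = cm.counts.shape[0]
    names = class_names or [str(i) for i in range(n)]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(cm.counts, cmap="Blues")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(cm.counts[i, j]), ha="center", va="center")
    ax.set_xticks(range(n), names)
    ax.set_yticks(range(n), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
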