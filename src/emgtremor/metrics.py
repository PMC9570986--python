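"""Confusion-matrix evaluation: accuracy, per-class precision and recall.

Convention: rows of the confusion matrix are true classes, columns are
predicted classes.  Per class, TP is the diagonal entry, FN the rest of
its row, FP the rest of its column and TN everything else; accuracy is
the diagonal total over the grand total, precision TP/(TP+FP), recall
TP/(TP+FN).  Ratios with a zero denominator are reported as absent
(``None``), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix", "ClassMetrics", "confusion_matrix", "metrics",
    "chance_level", "compare_initializations", "load_confusion_csv",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts matrix with rows = true class, columns = predicted class."""

    classes: Tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be ({k}, {k}), got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def support(self) -> Dict[str, int]:
        return {c: int(s) for c, s in zip(self.classes, self.counts.sum(axis=1))}

    def render(self) -> str:
        """Plain-text rendering, true classes down the rows."""
        df = pd.DataFrame(self.counts, index=self.classes, columns=self.classes)
        df.index.name = "true\\pred"
        return df.to_string()

    def to_csv(self, path: Path) -> None:
        df = pd.DataFrame(self.counts, index=self.classes, columns=self.classes)
        df.index.name = "class"
        df.to_csv(path)


@dataclass(frozen=True)
class ClassMetrics:
    """Overall accuracy plus per-class precision/recall and TP/FP/TN/FN."""

    accuracy: float
    precision: Dict[str, Optional[float]]
    recall: Dict[str, Optional[float]]
    tp: Dict[str, int]
    fp: Dict[str, int]
    tn: Dict[str, int]
    fn: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.tp:
            rows.append(
                {
                    "class": c,
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "tp": self.tp[c],
                    "fp": self.fp[c],
                    "tn": self.tn[c],
                    "fn": self.fn[c],
                }
            )
        return pd.DataFrame(rows)


def confusion_matrix(
    true_labels: Sequence,
    predicted_labels: Sequence,
    classes: Sequence[str],
) -> ConfusionMatrix:
    """Tally a confusion matrix over an explicit ordered class list."""
    true_labels = [str(l) for l in true_labels]
    predicted_labels = [str(l) for l in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"label vectors differ in length: {len(true_labels)} vs "
            f"{len(predicted_labels)}"
        )
    index = {c: i for i, c in enumerate(classes)}
    unknown = sorted(set(true_labels + predicted_labels) - set(index))
    if unknown:
        raise ValueError(f"labels {unknown} not in class list {list(classes)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Accuracy and per-class precision/recall from a confusion matrix."""
    total = cm.total
    if total == 0:
        raise ValueError("confusion matrix is empty")
    counts = cm.counts
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    tp = diag
    fn = row - diag
    fp = col - diag
    tn = total - tp - fn - fp
    precision = {
        c: (float(tp[i] / (tp[i] + fp[i])) if tp[i] + fp[i] > 0 else None)
        for i, c in enumerate(cm.classes)
    }
    recall = {
        c: (float(tp[i] / (tp[i] + fn[i])) if tp[i] + fn[i] > 0 else None)
        for i, c in enumerate(cm.classes)
    }
    wrap = lambda arr: {c: int(arr[i]) for i, c in enumerate(cm.classes)}
    return ClassMetrics(
        accuracy=float(diag.sum() / total),
        precision=precision,
        recall=recall,
        tp=wrap(tp),
        fp=wrap(fp),
        tn=wrap(tn),
        fn=wrap(fn),
    )


def chance_level(n_classes: int) -> float:
    """Expected accuracy of uniform random guessing: 1 / n_classes."""
    if n_classes < 1:
        raise ValueError("n_classes must be at least 1")
    return 1.0 / n_classes


def load_confusion_csv(path: Path) -> ConfusionMatrix:
    """Load a confusion matrix from CSV (class names in the first column)."""
    df = pd.read_csv(path, index_col=0)
    classes = tuple(str(c) for c in df.index)
    if tuple(str(c) for c in df.columns) != classes:
        raise ValueError("row and column class orders differ in the CSV")
    return ConfusionMatrix(classes=classes, counts=df.to_numpy())


def compare_initializations(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    source_model,
    hyper: Dict[str, object],
    seeds: Sequence[int],
    cell_mode: str = "standard",
    source_subject: Optional[str] = None,
    target_subject: Optional[str] = None,
) -> pd.DataFrame:
    """Train warm- and cold-started models under identical seeds and compare.

    The warm model is initialized from ``source_model`` (a model trained on
    a different subject); the cold model from fresh random weights.  For
    every seed, both are trained with the same hyperparameters and the
    per-class precision/recall and overall accuracy on the test windows
    are reported side by side with their deltas (warm minus cold).
    """
    import warnings

    from emgtremor.bilstm import BiLSTMClassifier

    if source_subject is not None and source_subject == target_subject:
        warnings.warn(
            "warm-start source and target subjects are identical; "
            "the comparison is degenerate",
            UserWarning,
        )
    classes = sorted({str(l) for l in y_train} | {str(l) for l in y_test})
    rows = []
    for seed in seeds:
        results = {}
        for kind, init in (("cold", None), ("warm", source_model)):
            clf = BiLSTMClassifier(cell_mode=cell_mode, random_state=int(seed), **hyper)
            clf.fit(X_train, y_train, init=init)
            cm = confusion_matrix(y_test, clf.predict(X_test), classes)
            results[kind] = metrics(cm)
        cold, warm = results["cold"], results["warm"]
        rows.append(
            {
                "seed": seed, "class": "__overall__", "metric": "accuracy",
                "cold": cold.accuracy, "warm": warm.accuracy,
                "delta": warm.accuracy - cold.accuracy,
            }
        )
        for metric_name in ("precision", "recall"):
            for c in classes:
                cv = getattr(cold, metric_name)[c]
                wv = getattr(warm, metric_name)[c]
                rows.append(
                    {
                        "seed": seed, "class": c, "metric": metric_name,
                        "cold": cv, "warm": wv,
                        "delta": (wv - cv) if cv is not None and wv is not None else None,
                    }
                )
    return pd.DataFrame(rows)
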