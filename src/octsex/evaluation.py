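"""Evaluation surface: 3-class confusion matrix, metrics, curves, size sweep.

The evaluation vocabulary has three outcomes — female, male and
not_detect — even though the classifier itself is binary: frames whose
anatomy was occluded carry not_detect as their *true* class, and the
confidence rule can produce not_detect as a *predicted* class.

Macro averages are taken over classes with nonzero support only (an empty
class says nothing about the classifier); weighted averages weight by
support, which makes weighted recall algebraically equal to overall
accuracy whenever every evaluated sample's true class participates.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cnn import CNNClassifier
from .preprocess import resize

__all__ = [
    "CLASSES",
    "ConfusionMatrix3",
    "MetricsReport",
    "confusion_matrix",
    "metrics",
    "evaluate_predictions",
    "size_ablation",
    "learning_curves",
    "plot_learning_curves",
    "TABLE_SIZES",
]

CLASSES = ("female", "male", "not_detect")

#: (width, height) sizes of the published image-size sweep
TABLE_SIZES = ((1000, 600), (224, 224), (128, 128), (128, 64), (64, 64), (75, 64))


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3×3 count matrix; rows = true class, columns = predicted class."""

    counts: tuple[tuple[int, ...], ...]
    classes: tuple[str, ...] = CLASSES

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.array.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.array, index=list(self.classes), columns=list(self.classes))


@dataclass(frozen=True)
class MetricsReport:
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    accuracy: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        rows = {c: [self.precision[c], self.recall[c], self.f1[c], self.support[c]] for c in self.precision}
        df = pd.DataFrame(rows, index=["precision", "recall", "f1", "support"]).T
        df.loc["macro"] = [self.macro_precision, self.macro_recall, self.macro_f1, sum(self.support.values())]
        df.loc["weighted"] = [self.weighted_precision, self.weighted_recall, self.weighted_f1, sum(self.support.values())]
        return df


def confusion_matrix(y_true, y_pred, classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix3:
    """Tally (true, predicted) label pairs into a count matrix."""
    y_true = [str(v) for v in y_true]
    y_pred = [str(v) for v in y_pred]
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            bad = t if t not in index else p
            raise ValueError(f"unknown label {bad!r}; expected one of {classes}")
        cm[index[t], index[p]] += 1
    return ConfusionMatrix3(counts=tuple(tuple(int(v) for v in row) for row in cm), classes=classes)


def metrics(cm: ConfusionMatrix3) -> MetricsReport:
    """Per-class, macro and support-weighted precision/recall/F1 plus accuracy.

    Undefined ratios (empty row or column) are reported as 0; classes with
    zero support are excluded from the macro mean and carry zero weight in
    the weighted mean.
    """
    a = cm.array
    total = a.sum()
    if total == 0:
        raise ValueError("cannot compute metrics of an empty confusion matrix")
    tp = np.diag(a).astype(float)
    col = a.sum(axis=0).astype(float)
    row = a.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        rec = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.where(denom > 0, denom, 1), 0.0)

    present = row > 0
    weights = row / total
    macro = lambda v: float(v[present].mean()) if present.any() else 0.0
    weighted = lambda v: float((v * weights).sum())

    names = cm.classes
    return MetricsReport(
        precision={c: float(p) for c, p in zip(names, prec)},
        recall={c: float(r) for c, r in zip(names, rec)},
        f1={c: float(v) for c, v in zip(names, f1)},
        support={c: int(s) for c, s in zip(names, row)},
        macro_precision=macro(prec),
        macro_recall=macro(rec),
        macro_f1=macro(f1),
        weighted_precision=weighted(prec),
        weighted_recall=weighted(rec),
        weighted_f1=weighted(f1),
        accuracy=float(np.trace(a) / total),
    )


def evaluate_predictions(y_true, y_pred) -> tuple[ConfusionMatrix3, MetricsReport]:
    cm = confusion_matrix(y_true, y_pred)
    return cm, metrics(cm)


def size_ablation(
    train_images: list[np.ndarray],
    train_labels,
    test_images: list[np.ndarray],
    test_true_labels,
    sizes=TABLE_SIZES,
    clf_params: dict | None = None,
    seeds=(0,),
    tau: float | None = None,
) -> pd.DataFrame:
    """Train and evaluate the classifier at each (width, height) size.

    For every size, images are resized, a fresh seed-controlled model is
    trained per seed, evaluated on the test set with the τ rejection rule,
    and the metric reports averaged over seeds.  Sizes too small for the
    three pooling stages produce an error row; the sweep continues.
    Returns one row per size with macro/weighted precision, recall, F1 and
    accuracy, mirroring the published sweep layout.
    """
    clf_params = dict(clf_params or {})
    rows = []
    for width, height in sizes:
        row: dict = {"width": width, "height": height, "size": f"{width} x {height}"}
        t0 = time.perf_counter()
        try:
            if height // 8 < 1 or width // 8 < 1:
                raise ValueError(f"size {width}×{height} too small for three pooling stages")
            Xtr = np.stack([resize(im, width, height) for im in train_images])
            Xte = np.stack([resize(im, width, height) for im in test_images])
            reports = []
            for seed in seeds:
                clf = CNNClassifier(
                    input_height=height, input_width=width, random_state=int(seed), **clf_params
                )
                clf.fit(Xtr, train_labels)
                y_pred = clf.predict_with_reject(Xte, tau=tau)
                reports.append(metrics(confusion_matrix(test_true_labels, y_pred)))
            for key in (
                "macro_precision", "weighted_precision", "macro_recall", "weighted_recall",
                "macro_f1", "weighted_f1", "accuracy",
            ):
                row[key] = float(np.mean([getattr(r, key) for r in reports]))
            row["error"] = ""
        except ValueError as e:
            row["error"] = str(e)
        row["seconds"] = time.perf_counter() - t0
        rows.append(row)
    return pd.DataFrame(rows)


def learning_curves(history: dict[str, list[float]]) -> pd.DataFrame:
    """Per-epoch training/validation loss and accuracy as a tidy table."""
    if not history or not len(next(iter(history.values()))):
        raise ValueError("empty training history")
    df = pd.DataFrame(history)
    df.insert(0, "epoch", np.arange(1, len(df) + 1))
    return df


def plot_learning_curves(history: dict[str, list[float]], path) -> None:
    """Two panels — accuracy and loss vs epoch — written to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = learning_curves(history)
    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 4))
    ax_acc.plot(df["epoch"], df["train_acc"], label="train")
    ax_acc.plot(df["epoch"], df["val_acc"], label="validation")
    ax_acc.set(xlabel="epoch", ylabel="accuracy", title="Model accuracy")
    ax_acc.legend()
    ax_loss.plot(df["epoch"], df["train_loss"], label="train")
    ax_loss.plot(df["epoch"], df["val_loss"], label="validation")
    ax_loss.set(xlabel="epoch", ylabel="loss", title="Model loss")
    ax_loss.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
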