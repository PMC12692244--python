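"""Confusion-count metrics and sliced evaluation reports.

Metrics follow the one-vs-rest convention for multi-class data: per class c,
TP = correctly assigned to c, FP = wrongly assigned to c, FN = members of c
assigned elsewhere, TN = the rest.  Precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 their harmonic mean; classes with a zero denominator score 0
and are flagged.  Overall accuracy is the fraction of correctly classified
samples (trace of the confusion matrix over N).  Single summary values use
the unweighted (macro) mean over classes; per-class values are always kept.

Two slicings mirror the study design: variety-task metrics per storage day
(does variety recognition survive storage-induced drift?) and storage-period
metrics per variety.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import TASK_PERIOD, TASK_VARIETY, Network
from .synthspec import SpectraTable
from .train import task_targets

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion",
    "metrics",
    "evaluate_sliced",
    "evaluate_pooled",
    "compare",
]


@dataclass
class ConfusionCounts:
    """K x K confusion matrix plus one-vs-rest counts per class."""

    classes: list
    matrix: np.ndarray  # rows = true class, columns = predicted class

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        if m.shape != (len(self.classes), len(self.classes)):
            raise ValueError("matrix shape must be K x K")
        self.matrix = m

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def fp(self) -> np.ndarray:
        return self.matrix.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.matrix.sum(axis=1) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.n - self.tp - self.fp - self.fn


def confusion(y_true, y_pred, classes) -> ConfusionCounts:
    """Exact integer confusion counts."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted label sequences differ in length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    unknown = sorted({l for l in y_true + y_pred if l not in index}, key=str)
    if unknown:
        raise ValueError(f"labels outside class set: {unknown}")
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    return ConfusionCounts(classes=classes, matrix=m)


@dataclass
class EvalReport:
    """Accuracy plus per-class and macro precision/recall/F1 for one slice."""

    accuracy: float
    precision: dict
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int
    zero_division_classes: list = field(default_factory=list)
    slice_key: object = None
    task: str | None = None
    variant: str | None = None
    seed: int | None = None

    def to_row(self) -> dict:
        return {
            "variant": self.variant, "seed": self.seed, "task": self.task,
            "slice": self.slice_key, "n": self.n, "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall, "macro_f1": self.macro_f1,
        }


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Accuracy, precision, recall and F1 from confusion counts."""
    if counts.n == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    flagged = []
    prec = np.zeros(len(counts.classes))
    rec = np.zeros(len(counts.classes))
    f1 = np.zeros(len(counts.classes))
    for i, c in enumerate(counts.classes):
        pd_ = tp[i] + fp[i]
        rd_ = tp[i] + fn[i]
        prec[i] = tp[i] / pd_ if pd_ > 0 else 0.0
        rec[i] = tp[i] / rd_ if rd_ > 0 else 0.0
        if pd_ == 0 or rd_ == 0:
            flagged.append(c)
        s = prec[i] + rec[i]
        f1[i] = 2.0 * prec[i] * rec[i] / s if s > 0 else 0.0
    return EvalReport(
        accuracy=float(counts.tp.sum() / counts.n),
        precision={c: float(prec[i]) for i, c in enumerate(counts.classes)},
        recall={c: float(rec[i]) for i, c in enumerate(counts.classes)},
        f1={c: float(f1[i]) for i, c in enumerate(counts.classes)},
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        n=counts.n,
        zero_division_classes=flagged,
    )


# ---------------------------------------------------------------------------
# Sliced evaluation
# ---------------------------------------------------------------------------

_SLICINGS = {
    "by_day": (TASK_VARIETY, "day"),
    "by_variety": (TASK_PERIOD, "variety"),
}


def _predict_task(network: Network, table: SpectraTable, band_indices,
                  task: str) -> tuple[np.ndarray, np.ndarray, list]:
    X = table.X[:, np.asarray(band_indices, dtype=int)]
    preds = network.predict(X)
    if task not in preds:
        raise ValueError(f"network variant {network.variant.value} has no {task} head")
    y_idx, classes = task_targets(table)[task]
    return y_idx, preds[task], classes


def evaluate_sliced(network: Network, test_table: SpectraTable, slicing: str,
                    band_indices) -> list[EvalReport]:
    """Per-slice reports: variety task by storage day, or period task by variety."""
    if slicing not in _SLICINGS:
        raise ValueError(f"slicing must be one of {sorted(_SLICINGS)}")
    task, slice_col = _SLICINGS[slicing]
    y_idx, p_idx, classes = _predict_task(network, test_table, band_indices, task)
    reports = []
    for key in sorted(test_table.labels[slice_col].unique()):
        mask = (test_table.labels[slice_col] == key).to_numpy()
        if not mask.any():
            raise ValueError(f"empty slice {slice_col}={key}")
        counts = confusion(y_idx[mask], p_idx[mask], range(len(classes)))
        counts.classes = classes
        rep = metrics(counts)
        rep.slice_key = key
        rep.task = task
        rep.variant = network.variant.value
        reports.append(rep)
    return reports


def evaluate_pooled(network: Network, test_table: SpectraTable, task: str,
                    band_indices) -> EvalReport:
    """Whole-test-set report for one task."""
    y_idx, p_idx, classes = _predict_task(network, test_table, band_indices, task)
    counts = confusion(y_idx, p_idx, range(len(classes)))
    counts.classes = classes
    rep = metrics(counts)
    rep.slice_key = "pooled"
    rep.task = task
    rep.variant = network.variant.value
    return rep


def compare(run_dirs) -> pd.DataFrame:
    """Side-by-side mean +/- sd metrics across runs sharing one test set.

    Each run directory must hold a ``reports.csv`` (one row per variant x
    seed x task x slice, as written by the pipeline).  Rows are aggregated
    over seeds per (variant, task, slice).
    """
    frames = []
    test_hashes = set()
    for d in run_dirs:
        d = Path(d)
        frames.append(pd.read_csv(d / "reports.csv"))
        h = d / "test_eggs.txt"
        if h.exists():
            test_hashes.add(h.read_text())
    if len(frames) < 1:
        raise ValueError("need at least one run directory")
    if len(test_hashes) > 1:
        raise ValueError("runs were evaluated on different test sets")
    allr = pd.concat(frames, ignore_index=True)
    num_cols = ["accuracy", "macro_precision", "macro_recall", "macro_f1"]
    out = (allr.groupby(["variant", "task", "slice"], sort=True)[num_cols]
               .agg(["mean", "std"]))  # std is the sample (ddof=1) sd
    out.columns = [f"{m}_{'sd' if a == 'std' else a}" for m, a in out.columns]
    sd_cols = [c for c in out.columns if c.endswith("_sd")]
    out[sd_cols] = out[sd_cols].fillna(0.0)
    return out.reset_index()
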