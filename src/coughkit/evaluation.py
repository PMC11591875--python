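"""Classification metrics, ROC/AUC, the majority-class reference accuracy,
and the cross-environment generalization matrix.

On heavily imbalanced segment sets, raw accuracy is dominated by the
majority (non-cough) class: a constant all-negative predictor already scores
1 − positive_fraction.  Sensitivity (recall on coughs) is therefore reported
alongside accuracy and specificity, and the combined "mixed" score
accuracy + sensitivity is used for checkpoint selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Confusion counts with derived rates.

    Ratios with a zero denominator are reported as ``None`` (absent), never
    silently coerced to 0 or 1.
    """

    counts: ConfusionCounts
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    auc: float | None = None

    @property
    def mixed(self) -> float | None:
        if self.accuracy is None or self.sensitivity is None:
            return None
        return self.accuracy + self.sensitivity

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mixed": self.mixed,
            "auc": self.auc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }


def _safe_ratio(num: int, den: int, name: str) -> float | None:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as absent",
                      RuntimeWarning, stacklevel=3)
        return None
    return num / den


def compute_metrics(labels, predictions) -> MetricsReport:
    """Accuracy, sensitivity and specificity from binary labels/predictions."""
    y = np.asarray(labels, dtype=bool)
    yhat = np.asarray(predictions, dtype=bool)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs "
                         f"{yhat.shape} predictions")
    tp = int(np.sum(y & yhat))
    tn = int(np.sum(~y & ~yhat))
    fp = int(np.sum(~y & yhat))
    fn = int(np.sum(y & ~yhat))
    counts = ConfusionCounts(tp, tn, fp, fn)
    return MetricsReport(
        counts=counts,
        accuracy=_safe_ratio(tp + tn, counts.total, "accuracy"),
        sensitivity=_safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=_safe_ratio(tn, tn + fp, "specificity"),
    )


def baseline_accuracy(positive_fraction: float) -> float:
    """Accuracy of the constant all-negative predictor: 1 − positive fraction."""
    if not (0.0 <= positive_fraction <= 1.0):
        raise ValueError("positive_fraction must be in [0, 1]")
    return 1.0 - positive_fraction


def roc_curve(labels, scores) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve over all distinct score thresholds, plus trapezoid AUC.

    Returns (fpr, tpr, thresholds, auc).  Thresholds are the distinct scores
    in decreasing order preceded by +inf, so the curve runs exactly from
    (0, 0) to (1, 1).  Requires both classes present.
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], s_sorted.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def roc_to_csv(labels, scores, path) -> float:
    """Export ROC points to CSV; returns the AUC."""
    fpr, tpr, thr, auc = roc_curve(labels, scores)
    pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr}).to_csv(
        path, index=False)
    return auc


@dataclass
class CrossValMatrix:
    """Metrics for every (training source, test subset) combination."""

    entries: dict[tuple[str, str], MetricsReport | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (train, test), report in sorted(self.entries.items()):
            row = {"train": train, "test": test}
            row.update(report.as_dict() if report is not None else
                       {"accuracy": None, "sensitivity": None,
                        "specificity": None})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _stratified_split(y: np.ndarray, test_fraction: float,
                      rng: np.random.Generator,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of a stratified train/test split (at least 1 test per class)."""
    test_idx = []
    for cls in (False, True):
        idx = np.nonzero(y == cls)[0]
        if idx.size == 0:
            continue
        n_test = max(int(round(test_fraction * idx.size)), 1)
        test_idx.append(rng.permutation(idx)[:n_test])
    test = np.concatenate(test_idx) if test_idx else np.array([], dtype=int)
    mask = np.ones(y.size, dtype=bool)
    mask[test] = False
    return np.nonzero(mask)[0], np.sort(test)


def cross_validate(subsets: dict[str, tuple[np.ndarray, np.ndarray]],
                   model_factory: Callable[[], object],
                   test_fraction: float = 0.10, seed: int = 0,
                   all_label: str = "all") -> CrossValMatrix:
    """Train on each environment (and on all pooled) and test on every one.

    ``subsets`` maps subset name → (X, y).  Each subset is first split into
    train/test parts (stratified, shared seed); every training source uses
    only train parts and every evaluation uses only test parts, so the
    diagonal is held out too and the pooled row leaks nothing.  Subsets whose
    training part contains a single class are skipped with a warning and
    recorded as absent.  Result: a (len(subsets)+1) × len(subsets) matrix.
    """
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets for cross-validation")
    rng = np.random.default_rng(seed)
    parts = {}
    for name, (X, y) in subsets.items():
        y = np.asarray(y, dtype=bool)
        tr, te = _stratified_split(y, test_fraction, rng)
        parts[name] = (np.asarray(X)[tr], y[tr], np.asarray(X)[te], y[te])

    names = list(subsets)
    sources: dict[str, tuple[np.ndarray, np.ndarray]] = {
        name: (parts[name][0], parts[name][1]) for name in names
    }
    sources[all_label] = (
        np.concatenate([parts[n][0] for n in names]),
        np.concatenate([parts[n][1] for n in names]),
    )

    entries: dict[tuple[str, str], MetricsReport | None] = {}
    for src, (Xtr, ytr) in sources.items():
        if ytr.all() or not ytr.any():
            warnings.warn(f"training source {src!r} has a single class; skipped",
                          RuntimeWarning, stacklevel=2)
            for name in names:
                entries[(src, name)] = None
            continue
        model = model_factory()
        model.fit(Xtr, ytr)
        for name in names:
            Xte, yte = parts[name][2], parts[name][3]
            entries[(src, name)] = compute_metrics(yte, model.predict(Xte))
    return CrossValMatrix(entries)


def table_report(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """Model-by-metric summary table (accuracy / sensitivity / specificity)."""
    rows = []
    for name, rep in reports.items():
        d = rep.as_dict()
        rows.append({"model": name, "accuracy": d["accuracy"],
                     "sensitivity": d["sensitivity"],
                     "specificity": d["specificity"], "auc": d["auc"]})
    return pd.DataFrame(rows)
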