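"""Metrics and the split-wise comparison protocol.

Classifiers are scored per train/test split with accuracy, support-weighted
F1 and the Brier score S = <(p_i - y_i)^2>; per classifier configuration the
mean and standard error over splits are reported, and per classifier family
the configuration with the maximal mean is retained. Families are compared
with a one-sided paired t-test over common splits. Splits where a classifier
collapses to a single predicted class are flagged, since that pathology
inflates accuracy on unbalanced data while carrying no information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, f1_score


@dataclass(frozen=True)
class MetricRecord:
    classifier: str
    split: int
    accuracy: float
    weighted_f1: float
    brier: float
    single_class: bool = False

    def __post_init__(self) -> None:
        for v in (self.accuracy, self.weighted_f1, self.brier):
            if not 0.0 <= v <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")


def brier_score(p: np.ndarray, y: np.ndarray) -> float:
    """Mean squared difference between class-1 probability and label."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have the same length")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def weighted_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Support-weighted mean of per-class F1 (undefined classes score 0)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


def detect_single_class(y_pred: np.ndarray) -> bool:
    """True iff every prediction in the split shares one label."""
    y_pred = np.asarray(y_pred)
    return bool(y_pred.size > 0 and np.unique(y_pred).size == 1)


def score_split(classifier: str, split: int, y_true: np.ndarray,
                p: np.ndarray) -> MetricRecord:
    """All split metrics from the class-1 probabilities (threshold 0.5,
    ties to class 1)."""
    y_pred = (np.asarray(p) >= 0.5).astype(int)
    return MetricRecord(
        classifier=classifier,
        split=split,
        accuracy=float(accuracy_score(y_true, y_pred)),
        weighted_f1=weighted_f1(y_true, y_pred),
        brier=brier_score(p, y_true),
        single_class=detect_single_class(y_pred),
    )


def records_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def aggregate_splits(records: list[MetricRecord]) -> pd.DataFrame:
    """Mean and standard error of each metric over splits, per classifier.

    SE = sample SD / sqrt(n); a single record yields SE 0.
    """
    if not records:
        raise ValueError("no records to aggregate")
    df = records_frame(records)
    rows = []
    for clf, grp in df.groupby("classifier"):
        row: dict = {"classifier": clf, "n_splits": len(grp)}
        for metric in ("accuracy", "weighted_f1", "brier"):
            vals = grp[metric].to_numpy()
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            )
        row["single_class_splits"] = int(grp["single_class"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def max_mean_report(records: list[MetricRecord], metric: str = "weighted_f1",
                    family_of=lambda name: name.split(":")[0]) -> pd.DataFrame:
    """Per classifier family, the configuration maximizing the mean metric.

    Higher is better for accuracy/F1; for the Brier score the minimizing
    configuration is reported instead.
    """
    summary = aggregate_splits(records)
    summary["family"] = summary["classifier"].map(family_of)
    col = f"{metric}_mean"
    pick = summary.groupby("family")[col].idxmin() if metric == "brier" else (
        summary.groupby("family")[col].idxmax()
    )
    return summary.loc[pick].reset_index(drop=True)


def compare_classifiers(records_a: list[MetricRecord],
                        records_b: list[MetricRecord],
                        metric: str = "weighted_f1") -> float:
    """One-sided paired t-test p-value that A's mean metric exceeds B's.

    Records are paired by split id; unmatched splits are an error. A
    zero-variance difference degenerates to p = 0 (A uniformly better),
    1 (worse), or 0.5 (identical).
    """
    a = {r.split: getattr(r, metric) for r in records_a}
    b = {r.split: getattr(r, metric) for r in records_b}
    if set(a) != set(b):
        raise ValueError("records are not paired by split id")
    splits = sorted(a)
    if len(splits) < 2:
        raise ValueError("need at least two common splits")
    va = np.array([a[s] for s in splits])
    vb = np.array([b[s] for s in splits])
    diff = va - vb
    if np.allclose(diff.std(ddof=1), 0.0):
        mean = diff.mean()
        return 0.5 if np.isclose(mean, 0.0) else (0.0 if mean > 0 else 1.0)
    return float(stats.ttest_rel(va, vb, alternative="greater").pvalue)
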