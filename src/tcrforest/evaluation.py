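"""Benchmark metrics: confusion counts, ROC/AUC, and stratified reports.

The four benchmark metrics are AUC, accuracy, sensitivity and specificity
at a stated probability threshold. AUC is the area under the ROC curve,
equal to the Mann–Whitney probability that a random binding pair outranks
a random non-binding pair (ties counted half). Stratified reports split
an evaluated set by any record-level key (pathogen source, cancer type,
dominant vs other peptides); a stratum with a single truth class reports
the threshold metrics and marks AUC unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .classifier import classify
from .core_io import PairRecord


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class EvalReport:
    auc: float | None
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    threshold: float
    n_pos: int
    n_neg: int
    stratum: str | None = None

    def as_dict(self) -> dict:
        return {"stratum": self.stratum, "auc": self.auc, "accuracy": self.accuracy,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "threshold": self.threshold, "n_pos": self.n_pos, "n_neg": self.n_neg}


def _check_inputs(probabilities, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=np.float64)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    if not set(np.unique(t).tolist()) <= {0, 1}:
        raise ValueError("truth must be binary 0/1")
    return p, t.astype(int)


def confusion_at_threshold(probabilities, truth,
                           threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts under the ≥-threshold binding call."""
    p, t = _check_inputs(probabilities, truth)
    calls = classify(p, threshold)
    return ConfusionCounts(
        tp=int(((calls == 1) & (t == 1)).sum()),
        fp=int(((calls == 1) & (t == 0)).sum()),
        tn=int(((calls == 0) & (t == 0)).sum()),
        fn=int(((calls == 0) & (t == 1)).sum()),
    )


def roc_auc(probabilities, truth) -> tuple[float, pd.DataFrame]:
    """AUC plus the ROC curve points (fpr, tpr, threshold).

    The trapezoidal area over the ROC curve equals the tie-aware
    Mann–Whitney statistic.
    """
    p, t = _check_inputs(probabilities, truth)
    if len(set(t.tolist())) < 2:
        raise ValueError("both classes must be present for ROC")
    fpr, tpr, thresholds = roc_curve(t, p)
    value = float(_trapezoid_auc(fpr, tpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return value, curve


def metrics_report(probabilities, truth, threshold: float = 0.5,
                   stratum: str | None = None) -> EvalReport:
    """The four-metric report at one operating point.

    sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
    accuracy = (tp+tn)/total; AUC is None when only one class is present
    (unavailable, not zero).
    """
    p, t = _check_inputs(probabilities, truth)
    c = confusion_at_threshold(p, t, threshold)
    n_pos, n_neg = c.tp + c.fn, c.tn + c.fp
    auc_val = roc_auc(p, t)[0] if n_pos and n_neg else None
    return EvalReport(
        auc=auc_val,
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=c.tp / n_pos if n_pos else None,
        specificity=c.tn / n_neg if n_neg else None,
        threshold=threshold, n_pos=n_pos, n_neg=n_neg, stratum=stratum,
    )


def stratified_report(records: Sequence[PairRecord], probabilities, truth,
                      stratum_key: Callable[[PairRecord], str],
                      threshold: float = 0.5) -> list[EvalReport]:
    """One EvalReport per stratum; per-stratum counts partition the pooled set."""
    p, t = _check_inputs(probabilities, truth)
    if len(records) != p.size:
        raise ValueError("records and probabilities differ in length")
    strata: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault(stratum_key(rec), []).append(i)
    reports = []
    for name in sorted(strata):
        idx = np.array(strata[name])
        reports.append(metrics_report(p[idx], t[idx], threshold, stratum=name))
    return reports


def reports_to_frame(reports: Sequence[EvalReport]) -> pd.DataFrame:
    """Flatten reports into the one-row-per-stratum CSV layout."""
    return pd.DataFrame([r.as_dict() for r in reports])
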