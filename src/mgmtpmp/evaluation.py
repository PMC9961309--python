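"""Confusion counts and the eight binary-classification performance measures.

The positive class is MGMT+ (label 1).  Measures: accuracy A, sensitivity
S_n (recall / TPR), specificity S_p (TNR), precision P_r (PPV), NPV,
F1-score, Matthews correlation coefficient and FPR, plus the trapezoidal
ROC AUC.  A, S_n, S_p, P_r, NPV and FPR are reported on the percent scale,
rounded half-up to 2 decimals; F1, MCC and AUC stay on the unit scale.
Zero denominators yield a defined 0 with the affected measure flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt

import numpy as np

from .rejection import round_half_up

PERCENT_METRICS = ("accuracy", "sensitivity", "specificity", "precision",
                   "npv", "fpr")
UNIT_METRICS = ("f1", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Exact TP/FN/TN/FP with class 1 positive."""
    t = np.asarray(y_true, dtype=np.int64)
    p = np.asarray(y_pred, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        bad = set(np.unique(arr)) - {0, 1}
        if bad:
            raise ValueError(f"{name} contains labels outside {{0, 1}}: {sorted(bad)}")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
    )


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    f1: float
    mcc: float
    fpr: float
    auc: float | None = None
    undefined: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in PERCENT_METRICS + UNIT_METRICS}
        d["undefined"] = list(self.undefined)
        return d


def _ratio(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts, *, auc: float | None = None) -> MetricsReport:
    """All eight formulas applied exactly, percent measures rounded to 2 dp.

    A  = (TP+TN)/(TP+FP+FN+TN) * 100          S_n = TP/(TP+FN)
    S_p = TN/(TN+FP)                          P_r = TP/(TP+FP)
    NPV = TN/(TN+FN)                          FPR = FP/(TN+FP)
    F1  = 2*P_r*R_c/(P_r+R_c)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FN)(TN+FN)(TP+FP)(TN+FP))
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics of all-zero counts")
    und: list = []
    tp, fn, tn, fp = (float(c.tp), float(c.fn), float(c.tn), float(c.fp))
    a = (tp + tn) / c.total
    sn = _ratio(tp, tp + fn, "sensitivity", und)
    sp = _ratio(tn, tn + fp, "specificity", und)
    pr = _ratio(tp, tp + fp, "precision", und)
    npv = _ratio(tn, tn + fn, "npv", und)
    fpr = _ratio(fp, tn + fp, "fpr", und)
    f1 = _ratio(2 * pr * sn, pr + sn, "f1", und)
    mcc_den = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    mcc = _ratio(tp * tn - fp * fn, sqrt(mcc_den) if mcc_den else 0.0, "mcc", und)
    return MetricsReport(
        accuracy=round_half_up(100 * a),
        sensitivity=round_half_up(100 * sn),
        specificity=round_half_up(100 * sp),
        precision=round_half_up(100 * pr),
        npv=round_half_up(100 * npv),
        f1=f1,
        mcc=mcc,
        fpr=round_half_up(100 * fpr),
        auc=auc,
        undefined=und,
    )


def roc_auc(y_true, scores) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the rank statistic: the probability that a uniformly drawn
    positive outscores a uniformly drawn negative, ties counting 1/2.
    """
    t = np.asarray(y_true, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes present in y_true")
    ranks = _midranks(s)
    r_pos = ranks[t == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _midranks(s: np.ndarray) -> np.ndarray:
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=np.float64)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def aggregate_fold_metrics(reports: list[MetricsReport]) -> dict:
    """Fold-wise mean +- sample standard deviation (K-1 denominator)."""
    out = {}
    for key in PERCENT_METRICS + UNIT_METRICS:
        vals = [getattr(r, key) for r in reports]
        if any(v is None for v in vals):
            continue
        arr = np.asarray(vals, dtype=np.float64)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out[key] = {"mean": float(arr.mean()), "sd": sd}
    return out
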