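"""Performance statistics over populations of single-case runs.

Confusion counts, sensitivity/specificity/precision/recall/F1/accuracy,
ROC curves with trapezoidal AUROC (equivalently the midrank
Mann-Whitney statistic), and the pooled-variance t-test used to compare
accuracy sets across classification questions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class EvaluationSummary:
    """Confusion counts and derived statistics for one run population.

    Ratios with a zero denominator are NaN ("not applicable"), never 0.
    Recall equals sensitivity by construction.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    accuracy: float
    f1: float
    auroc: float
    n_runs: int
    loop: str

    def as_dict(self) -> dict:
        return {
            "loop": self.loop, "n_runs": self.n_runs,
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "sensitivity": _none_if_nan(self.sensitivity),
            "specificity": _none_if_nan(self.specificity),
            "precision": _none_if_nan(self.precision),
            "recall": _none_if_nan(self.recall),
            "accuracy": _none_if_nan(self.accuracy),
            "f1": _none_if_nan(self.f1),
            "auroc": _none_if_nan(self.auroc),
        }


@dataclass(frozen=True)
class RocCurve:
    """ROC from a score sweep: one threshold per distinct score value."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float


@dataclass(frozen=True)
class AccuracyComparison:
    """Two-sample pooled-variance t comparison of two accuracy sets.

    Both degree-of-freedom conventions are reported: the conventional
    pooled ``df = n_a + n_b - 2`` and ``df_min = min(n) - 1``; ``p``
    uses the pooled df, ``p_min`` the alternative.
    """

    t: float
    df: int
    p: float
    df_min: int
    p_min: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float

    def __iter__(self):  # (t, df, p) unpacking
        return iter((self.t, self.df, self.p))


def _none_if_nan(x: float):
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else x


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def summarize(records: Sequence) -> EvaluationSummary:
    """Confusion counts and all derived statistics for one loop population."""
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty run population")
    loops = {r.loop for r in records}
    if len(loops) > 1:
        raise ValueError(f"mixed loop types in one population: {sorted(loops)}")
    truth = np.array([r.truth for r in records])
    pred = np.array([r.prediction for r in records])
    TP = int(((truth == 1) & (pred == 1)).sum())
    FN = int(((truth == 1) & (pred == -1)).sum())
    TN = int(((truth == -1) & (pred == -1)).sum())
    FP = int(((truth == -1) & (pred == 1)).sum())
    sens = _ratio(TP, TP + FN)
    spec = _ratio(TN, TN + FP)
    prec = _ratio(TP, TP + FP)
    if math.isnan(prec) or math.isnan(sens) or (prec + sens) == 0:
        f1 = float("nan")
    else:
        f1 = 2 * prec * sens / (prec + sens)
    try:
        auroc = roc(records).auroc
    except ValueError:
        auroc = float("nan")
    return EvaluationSummary(
        TP=TP, FP=FP, TN=TN, FN=FN,
        sensitivity=sens, specificity=spec, precision=prec, recall=sens,
        accuracy=(TP + TN) / len(records), f1=f1, auroc=auroc,
        n_runs=len(records), loop=loops.pop(),
    )


def roc(records: Sequence) -> RocCurve:
    """Threshold sweep over every distinct score (positive iff score >= t).

    Anchored at (0,0) and (1,1); equal scores collapse to one threshold;
    the area is the trapezoidal integral, which equals the midrank
    Mann-Whitney statistic U / (n+ * n-).
    """
    truth = np.array([r.truth for r in records])
    scores = np.array([r.score for r in records], dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ROC requires finite scores")
    n_pos = int((truth == 1).sum())
    n_neg = int((truth == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both truth classes in the population")
    thresholds = np.unique(scores)[::-1]  # descending: strictest first
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        called_pos = scores >= t
        tpr.append(((truth == 1) & called_pos).sum() / n_pos)
        fpr.append(((truth == -1) & called_pos).sum() / n_neg)
    tpr.append(1.0)
    fpr.append(1.0)
    tpr_a, fpr_a = np.array(tpr), np.array(fpr)
    return RocCurve(
        thresholds=thresholds, fpr=fpr_a, tpr=tpr_a,
        auroc=float(np.trapezoid(tpr_a, fpr_a)),
    )


def compare_accuracy_sets(
    acc_a: Iterable[float], acc_b: Iterable[float]
) -> AccuracyComparison:
    """Pooled-variance two-sample t-test between two accuracy sets.

    ``t = (m_a - m_b) / sqrt(s_p^2 (1/n_a + 1/n_b))``; two-tailed p.
    Scale-invariant (percent and fraction units give the same t) and
    antisymmetric in its arguments.
    """
    a = np.asarray(list(acc_a), dtype=float)
    b = np.asarray(list(acc_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each accuracy set needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    df_min = min(len(a), len(b)) - 1
    return AccuracyComparison(
        t=float(t),
        df=df,
        p=float(2 * stats.t.sf(abs(t), df)),
        df_min=df_min,
        p_min=float(2 * stats.t.sf(abs(t), df_min)),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
    )
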