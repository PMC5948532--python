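"""Synthetic-test performance measures and latent-factor regressions.

Per-gesture precision, recall and F-measure summarize hard-label
classification of the basic gestures; the mean squared output error
E_MS covers the compound gestures where hard labels are ill-defined.
Because E_MS is strongly right-skewed across subjects, the per-subject
performance index

    Re_i = ln( E_MS,i / median_j E_MS,j )

is used for parametric statistics; by construction the cohort median of
Re is 0 and Re is invariant to any common rescaling of the errors.
Ordinary least squares relates Re (or the game score) to latent
factors such as the synergist–antagonist coefficient or body-fat index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class GestureCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class ConfusionCounts:
    """Per-gesture true-positive / false-positive / false-negative counts."""

    per_gesture: dict[str, GestureCounts]

    @classmethod
    def from_labels(cls, true_labels, pred_labels) -> "ConfusionCounts":
        true_labels = np.asarray(true_labels)
        pred_labels = np.asarray(pred_labels)
        if true_labels.shape != pred_labels.shape:
            raise ValueError("label arrays must have equal length")
        counts = {}
        for g in np.unique(np.concatenate([true_labels, pred_labels])):
            tp = int(((true_labels == g) & (pred_labels == g)).sum())
            fp = int(((true_labels != g) & (pred_labels == g)).sum())
            fn = int(((true_labels == g) & (pred_labels != g)).sum())
            counts[g] = GestureCounts(tp=tp, fp=fp, fn=fn)
        return cls(per_gesture=counts)


@dataclass
class FMeasureResult:
    """Per-gesture (precision, recall, F); None where undefined."""

    per_gesture: dict[str, tuple]
    pooled_f: float | None


def f_measure(counts: ConfusionCounts) -> FMeasureResult:
    """Precision P = TP/(TP+FP), recall R = TP/(TP+FN), F = 2PR/(P+R).

    A gesture with TP+FP = 0 or TP+FN = 0 has an undefined measure and
    is reported as None (flagged missing, never coerced to 0).  With
    FN = 0 and TP > 0 the recall is 1 by definition.  The pooled value
    is the macro average of the defined per-gesture F values.
    """
    per = {}
    fs = []
    for g, c in counts.per_gesture.items():
        if c.tp + c.fp == 0 or c.tp + c.fn == 0:
            per[g] = (None, None, None)
            continue
        p = c.tp / (c.tp + c.fp)
        r = c.tp / (c.tp + c.fn)
        f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        per[g] = (p, r, f)
        fs.append(f)
    pooled = float(np.mean(fs)) if fs else None
    return FMeasureResult(per_gesture=per, pooled_f=pooled)


def performance_index(ems_values) -> np.ndarray:
    """Log-normalized per-subject error: Re_i = ln(E_MS,i / median)."""
    e = np.asarray(ems_values, dtype=float)
    if e.size < 2:
        raise ValueError("the performance index needs at least 2 subjects")
    if (e <= 0).any():
        raise ValueError("all E_MS values must be positive")
    return np.log(e / np.median(e))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "p_value": self.p_value,
            "n": self.n,
        }


def factor_regression(x, y) -> RegressionResult:
    """OLS line y = slope·x + intercept with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 subjects")
    if np.ptp(x) == 0:
        raise ValueError("factor values are constant; slope undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        p_value=float(fit.pvalues[1]),
        n=int(x.size),
    )


def normality_diagnostic(values) -> tuple[float, float]:
    """Optional Lilliefors-type normality check (statistic, p-value)."""
    from statsmodels.stats.diagnostic import lilliefors

    stat, p = lilliefors(np.asarray(values, dtype=float))
    return float(stat), float(p)


def group_ttest(a, b) -> tuple[float, float]:
    """Convenience two-sample t-test (statistic, p-value)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(t), float(p)
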