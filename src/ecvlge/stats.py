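"""Diagnostic and agreement statistics for threshold-method evaluation.

ROC cutoff derivation (Youden J), 2x2 diagnostic statistics, 2x2
reconstruction from printed cohort summaries, Lin's concordance
correlation coefficient, and Bland-Altman 95% limits of agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "ConfusionTable", "ROCCurve", "DiagStats", "AgreementResult",
    "roc_curve", "diag_stats", "table_from_summary", "table_from_rates",
    "lin_ccc", "bland_altman", "agreement", "CCC_BANDS",
]

#: Interpretation bands for Lin's CCC: below 0.40 poor, 0.40-0.75 fair
#: to good, above 0.75 excellent.
CCC_BANDS = ((0.40, "poor"), (0.75, "fair to good"), (float("inf"), "excellent"))


def ccc_band(ccc: float) -> str:
    """Qualitative band of a CCC value."""
    if ccc < 0.40:
        return "poor"
    if ccc <= 0.75:
        return "fair to good"
    return "excellent"


@dataclass(frozen=True)
class ConfusionTable:
    """Diagnostic 2x2 counts (reference positive rows, test positive cols)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        cells = (self.tp, self.fp, self.fn, self.tn)
        if any(c < 0 for c in cells):
            raise ValueError("confusion-table cells must be non-negative")
        if sum(cells) == 0:
            raise ValueError("confusion table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def misclassified(self) -> int:
        return self.fp + self.fn


@dataclass
class ROCCurve:
    """ROC points (decreasing thresholds), AUC and the Youden-optimal cutoff."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    optimal_cutoff: float
    optimal_rule: str = ">="


@dataclass
class DiagStats:
    """Sensitivity/specificity/PPV/NPV in percent (NaN where undefined)."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined: tuple = ()

    def rounded(self, ndigits: int = 1) -> dict:
        return {k: (round(v, ndigits) if math.isfinite(v) else None)
                for k, v in (("sensitivity", self.sensitivity),
                             ("specificity", self.specificity),
                             ("ppv", self.ppv), ("npv", self.npv))}


@dataclass
class AgreementResult:
    """Lin's CCC plus Bland-Altman bias and 95% limits of agreement."""

    ccc: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def roc_curve(scores, labels) -> ROCCurve:
    """ROC analysis with a Youden-J optimal cutoff.

    AUC is the trapezoidal area over the empirical ROC points, which
    equals the Mann-Whitney concordant-pair statistic with half credit
    for ties. The optimal cutoff maximizes J = sensitivity +
    specificity - 1; ties prefer higher sensitivity, then the lower
    threshold; the decision rule is ``score >= cutoff`` positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC analysis")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    j = tpr - fpr
    best = 0
    for i in range(1, len(thr)):
        if (j[i], tpr[i], -thr[i]) > (j[best], tpr[best], -thr[best]):
            best = i
    cutoff = float(thr[best])
    if not np.isfinite(cutoff):  # the "predict nothing positive" endpoint
        cutoff = float(scores.max()) + 1.0
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc,
                    optimal_cutoff=cutoff)


def diag_stats(t: ConfusionTable) -> DiagStats:
    """Sensitivity, specificity, PPV, NPV in percent.

    A zero denominator yields NaN and the statistic's name in
    ``undefined`` rather than a silent 0.
    """
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    out = DiagStats(
        sensitivity=ratio(t.tp, t.tp + t.fn, "sensitivity"),
        specificity=ratio(t.tn, t.tn + t.fp, "specificity"),
        ppv=ratio(t.tp, t.tp + t.fp, "ppv"),
        npv=ratio(t.tn, t.tn + t.fn, "npv"),
    )
    out.undefined = tuple(undefined)
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def table_from_summary(n_total: int, n_positive: int, n_test_positive: int,
                       sensitivity: float) -> ConfusionTable:
    """Reconstruct the 2x2 table implied by printed cohort summaries.

    Given the cohort size, the number of reference-positive cases, the
    number of test-positive cases and the printed sensitivity:
    tp = round(sens * n_positive), fn = n_positive - tp,
    fp = n_test_positive - tp, tn = n_total - n_positive - fp.
    Inconsistent summaries (any negative cell) raise ``ValueError``
    naming the offending cell.
    """
    if not (0.0 <= sensitivity <= 1.0):
        raise ValueError("sensitivity must be a fraction in [0, 1]")
    tp = _round_half_up(sensitivity * n_positive)
    fn = n_positive - tp
    fp = n_test_positive - tp
    tn = n_total - n_positive - fp
    for name, v in (("tp", tp), ("fn", fn), ("fp", fp), ("tn", tn)):
        if v < 0:
            raise ValueError(f"inconsistent summary: cell {name} = {v} < 0")
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def table_from_rates(n_positive: int, n_negative: int,
                     sensitivity: float, specificity: float) -> ConfusionTable:
    """2x2 table implied by printed sensitivity/specificity on known counts."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a fraction in [0, 1]")
    tp = _round_half_up(sensitivity * n_positive)
    tn = _round_half_up(specificity * n_negative)
    return ConfusionTable(tp=tp, fn=n_positive - tp,
                          tn=tn, fp=n_negative - tn)


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population moments.

    CCC = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2), all moments
    with the 1/n convention. Returns NaN when both variances are zero
    and the means agree (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be paired 1-D arrays of length >= 2")
    mx, my = x.mean(), y.mean()
    sx2 = np.mean((x - mx) ** 2)
    sy2 = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        return float("nan")
    return float(2.0 * sxy / denom)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement of d = x - y.

    LoA = bias +/- 1.96 * SD(d), sample SD (n-1 denominator).
    Returns ``(bias, loa_low, loa_high)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 paired values")
    d = x - y
    bias = float(d.mean())
    half = 1.96 * float(d.std(ddof=1))
    return bias, bias - half, bias + half


def agreement(x, y) -> AgreementResult:
    """Combined agreement summary: Lin's CCC plus Bland-Altman LoA."""
    bias, lo, hi = bland_altman(x, y)
    return AgreementResult(ccc=lin_ccc(x, y), bias=bias, loa_low=lo,
                           loa_high=hi, n=len(np.asarray(x)))
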