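"""Performance metrics: confusion counts, sensitivity/specificity/accuracy
with exact Clopper-Pearson 95% confidence intervals, Matthews correlation
coefficient, and ROC/AUC, plus helpers to reconstruct integer confusion
matrices from printed summary statistics.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import beta as _beta
from sklearn.metrics import roc_curve as _sk_roc_curve


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention used for printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    """2x2 tally of patch-level decisions against histology truth."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def n_positive(self) -> int:
        return self.TP + self.FN

    @property
    def n_negative(self) -> int:
        return self.TN + self.FP


@dataclass
class MetricsReport:
    """One row of the three-strategy comparison table.

    Fractions carry (lower, upper) exact binomial 95% CIs; single-class
    inputs leave the undefined entries as NaN.
    """

    strategy: str
    confusion: ConfusionCounts
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    mcc: float
    auc: float


def confusion(predicted, truth) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from two equal-length binary vectors."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape or pred.ndim != 1:
        raise ValueError("predicted and truth must be equal-length 1-D vectors")
    for v in (pred, true):
        if not set(np.unique(v)) <= {0, 1}:
            raise ValueError("entries must be binary 0/1")
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (true == 1))),
        FP=int(np.sum((pred == 1) & (true == 0))),
        TN=int(np.sum((pred == 0) & (true == 0))),
        FN=int(np.sum((pred == 0) & (true == 1))),
    )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    marginal makes the denominator vanish, in which case 0 is returned by
    convention (no correlation information).
    """
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via beta-distribution quantiles.

    Lower bound is 0 when successes = 0 and upper bound is 1 when
    successes = trials.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    lo = 0.0 if successes == 0 else float(
        _beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    hi = 1.0 if successes == trials else float(
        _beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lo, hi


def roc_auc(scores, truth) -> tuple[np.ndarray, float, float]:
    """ROC curve by threshold sweep, trapezoidal AUC, and Youden cutoff.

    Returns ``(points, auc, optimal_cutoff)`` where ``points`` is an
    (n, 2) array of (FPR, TPR) pairs and ``optimal_cutoff`` maximizes
    Youden's J = TPR - FPR. A case is called positive when its score is
    >= the cutoff.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=int)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-D vectors")
    if len(np.unique(t)) < 2:
        raise ValueError("ROC requires both classes in the truth vector")
    fpr, tpr, thresholds = _sk_roc_curve(t, s)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    cutoff = float(thresholds[int(np.argmax(j))])
    return np.column_stack([fpr, tpr]), auc, cutoff


def _rate_with_ci(successes: int, trials: int) -> tuple[float, tuple[float, float]]:
    if trials == 0:
        return float("nan"), (float("nan"), float("nan"))
    return successes / trials, clopper_pearson(successes, trials)


def report_from_counts(
    c: ConfusionCounts, strategy: str = "", auc: float = float("nan")
) -> MetricsReport:
    """Assemble a metrics report from a confusion matrix (AUC optional)."""
    sens, sens_ci = _rate_with_ci(c.TP, c.n_positive)
    spec, spec_ci = _rate_with_ci(c.TN, c.n_negative)
    acc, acc_ci = _rate_with_ci(c.TP + c.TN, c.total)
    return MetricsReport(
        strategy=strategy,
        confusion=c,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
        accuracy=acc,
        accuracy_ci=acc_ci,
        mcc=mcc(c),
        auc=auc,
    )


def metrics_report(predictions, truth, scores=None, strategy: str = "") -> MetricsReport:
    """Full report for one labeling strategy.

    ``scores`` (e.g. tumor-pixel fractions) are only needed for the AUC;
    without them, or with single-class truth, AUC is NaN.
    """
    c = confusion(predictions, truth)
    auc = float("nan")
    if scores is not None:
        t = np.asarray(truth)
        if len(np.unique(t)) == 2:
            _, auc, _ = roc_auc(scores, truth)
    return report_from_counts(c, strategy=strategy, auc=auc)


def recover_confusion(
    n_positive: int,
    n_negative: int,
    sensitivity: float,
    specificity: float,
    decimals: int = 2,
) -> ConfusionCounts:
    """Invert printed sensitivity/specificity back to integer counts.

    Finds the unique TP with round(TP/n_positive) = sensitivity and the
    unique TN with round(TN/n_negative) = specificity at the printed
    precision (half-up rounding). Raises if no integer solution exists or
    if the solution is ambiguous.
    """

    def _unique_count(target: float, trials: int, name: str) -> int:
        hits = [
            k for k in range(trials + 1)
            if round_half_up(k / trials, decimals) == round_half_up(target, decimals)
        ]
        if not hits:
            raise ValueError(f"no integer {name} count matches {target} over {trials}")
        if len(hits) > 1:
            raise ValueError(f"{name} count ambiguous at {decimals} decimals: {hits}")
        return hits[0]

    tp = _unique_count(sensitivity, n_positive, "TP")
    tn = _unique_count(specificity, n_negative, "TN")
    return ConfusionCounts(TP=tp, FP=n_negative - tn, TN=tn, FN=n_positive - tp)
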