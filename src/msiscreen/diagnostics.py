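"""Exact-binomial diagnostic accuracy, ROC/AUC, and study-design power.

Accuracy estimates (sensitivity, specificity, PPV, NPV) come with exact
Clopper-Pearson confidence intervals, obtained from the beta-quantile
closed form

    lower = Beta^{-1}(alpha/2; x, n - x + 1)      (0 when x = 0)
    upper = Beta^{-1}(1 - alpha/2; x + 1, n - x)  (1 when x = n),

which inverts the binomial tail probabilities exactly and is therefore
conservative (coverage >= nominal for every n, p).

Study-design helpers give the exact upper-tail binomial probability that a
cohort of size n contains at least k affected subjects, with the per-subject
probability either supplied directly (disease prevalence) or compounded
from an annual incidence over a screening lead time,
``p_eff = 1 - (1 - incidence)^lead_years``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

DEFAULT_CONFIDENCE = 0.95


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 screening outcome counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ContingencyTable":
        """Table with the positive/negative class labels exchanged."""
        return ContingencyTable(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class CIResult:
    estimate: float
    lower: float
    upper: float
    confidence: float
    x: int
    n: int


def clopper_pearson(
    x: int, n: int, confidence: float = DEFAULT_CONFIDENCE
) -> CIResult:
    """Exact binomial confidence interval for x successes in n trials."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("require 0 <= x <= n")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    alpha = 1.0 - confidence
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return CIResult(
        estimate=x / n, lower=lower, upper=upper, confidence=confidence, x=x, n=n
    )


def format_percent(fraction: float, decimals: int = 1) -> float:
    """Display rounding in percent, one decimal by default.

    An interior value never rounds to the degenerate endpoints: a bound
    that is close to but not exactly 0 or 1 displays as 0.1 / 99.9 rather
    than 0.0 / 100.0 (e.g. an exact upper bound of 99.97% is reported as
    99.9%), matching clinical reporting practice.
    """
    pct = round(fraction * 100.0, decimals)
    step = 10.0**-decimals
    if fraction < 1.0 and pct >= 100.0:
        pct = 100.0 - step
    if fraction > 0.0 and pct <= 0.0:
        pct = step
    return pct


@dataclass(frozen=True)
class DiagnosticStats:
    """Accuracy estimates with exact CIs; None where undefined (0 denom)."""

    table: ContingencyTable
    sensitivity: Optional[CIResult]
    specificity: Optional[CIResult]
    ppv: Optional[CIResult]
    npv: Optional[CIResult]
    confidence: float

    def as_rows(self) -> list[dict]:
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            ci: Optional[CIResult] = getattr(self, name)
            if ci is None:
                rows.append({"statistic": name, "defined": False})
            else:
                rows.append(
                    {
                        "statistic": name,
                        "defined": True,
                        "estimate_pct": format_percent(ci.estimate),
                        "lower_pct": format_percent(ci.lower),
                        "upper_pct": format_percent(ci.upper),
                        "x": ci.x,
                        "n": ci.n,
                    }
                )
        return rows


def diagnostic_accuracy(
    table: ContingencyTable, confidence: float = DEFAULT_CONFIDENCE
) -> DiagnosticStats:
    """Sensitivity, specificity, PPV, NPV with Clopper-Pearson CIs."""
    if table.total == 0:
        raise ValueError("all-zero contingency table")

    def _stat(x: int, n: int) -> Optional[CIResult]:
        return None if n == 0 else clopper_pearson(x, n, confidence)

    return DiagnosticStats(
        table=table,
        sensitivity=_stat(table.tp, table.tp + table.fn),
        specificity=_stat(table.tn, table.tn + table.fp),
        ppv=_stat(table.tp, table.tp + table.fp),
        npv=_stat(table.tn, table.tn + table.fn),
        confidence=confidence,
    )


@dataclass(frozen=True)
class ROCResult:
    points: list[tuple[float, float]]  # (FPR, TPR), threshold-swept
    auc: float


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney formulation: concordant pair fraction, ties half."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rank_sum_pos = float(ranks[labels].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC over unique score thresholds with trapezoidal AUC.

    The trapezoidal area is cross-checked internally against the
    rank-statistic (Mann-Whitney) formulation with ties counted half; the
    two agree to numerical precision for a threshold sweep over all unique
    scores.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y.astype(int), s)
    auc_trap = float(np.trapezoid(tpr, fpr))
    auc_rank = _auc_rank(s, y)
    if abs(auc_trap - auc_rank) > 1e-9:
        raise AssertionError(
            f"trapezoidal AUC {auc_trap} disagrees with rank AUC {auc_rank}"
        )
    return ROCResult(points=list(zip(fpr.tolist(), tpr.tolist())), auc=auc_trap)


def binomial_design_at_least(n: int, p: float, k: int) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def screening_yield_probability(
    n: int, annual_incidence: float, lead_years: float, k: int
) -> float:
    """P(>= k screen-detectable cancers in a cohort of n).

    The per-subject probability compounds the annual incidence over the
    screening lead time: ``p_eff = 1 - (1 - incidence)^lead``.
    """
    if n <= 0 or lead_years <= 0:
        raise ValueError("n and lead_years must be positive")
    if not 0.0 <= annual_incidence <= 1.0:
        raise ValueError("annual_incidence must lie in [0, 1]")
    p_eff = 1.0 - (1.0 - annual_incidence) ** lead_years
    return binomial_design_at_least(n, p_eff, k)
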