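"""Diagnostic 2×2 performance: sensitivity, specificity, PPV, NPV, accuracy.

Point estimates are the usual count ratios; binomial confidence
intervals use the Wilson score interval by default (Clopper–Pearson
exact available).  Predictive values can also be computed from
(sensitivity, specificity, prevalence) via Bayes' theorem, which agrees
exactly with the count ratios at the cohort's own prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from statsmodels.stats.proportion import proportion_confint

from .io_tables import Group

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "DiagnosticPerformance",
    "confusion",
    "performance",
    "predictive_values_at_prevalence",
    "proportion_ci",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return self.n_diseased / self.total


def confusion(
    calls: Sequence[bool],
    truth: Sequence[Group | str],
) -> tuple[ConfusionMatrix, list[int]]:
    """Tally test calls against the malignant/benign truth labels.

    Patients with ``unknown`` truth are excluded; their indices are
    returned alongside the matrix so exclusions are never silent.
    """
    if len(calls) != len(truth):
        raise ValueError("calls and truth must align")
    tp = fp = tn = fn = 0
    excluded: list[int] = []
    for i, (call, t) in enumerate(zip(calls, truth)):
        g = Group(t)
        if g == Group.UNKNOWN:
            excluded.append(i)
            continue
        diseased = g == Group.MALIGNANT
        if call and diseased:
            tp += 1
        elif call and not diseased:
            fp += 1
        elif not call and diseased:
            fn += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise ValueError("no patients with known truth label")
    return ConfusionMatrix(tp, fp, tn, fn), excluded


def proportion_ci(k: int, n: int, method: str = "wilson") -> tuple[float, float]:
    """95% binomial CI for k successes out of n: Wilson score or exact."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    if method == "wilson":
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    elif method == "exact":
        lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its defining counts and 95% CI; NaN if undefined."""

    value: float
    k: int
    n: int
    ci95: tuple[float, float]

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def _estimate(k: int, n: int, ci_method: str) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(math.nan, 0, 0, (math.nan, math.nan))
    return MetricEstimate(k / n, k, n, proportion_ci(k, n, ci_method))


@dataclass(frozen=True)
class DiagnosticPerformance:
    cm: ConfusionMatrix
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate
    prevalence: float
    ci_method: str = "wilson"


def performance(cm: ConfusionMatrix, ci_method: str = "wilson") -> DiagnosticPerformance:
    """All 2×2 operating characteristics with CIs from one confusion matrix.

    A predictive value with a zero denominator (no positive or no
    negative calls) is reported as undefined (NaN), never as 0.
    """
    if cm.n_diseased == 0 or cm.n_healthy == 0:
        raise ValueError("both diseased and healthy rows must be non-empty")
    return DiagnosticPerformance(
        cm=cm,
        sensitivity=_estimate(cm.tp, cm.n_diseased, ci_method),
        specificity=_estimate(cm.tn, cm.n_healthy, ci_method),
        ppv=_estimate(cm.tp, cm.tp + cm.fp, ci_method),
        npv=_estimate(cm.tn, cm.tn + cm.fn, ci_method),
        accuracy=_estimate(cm.tp + cm.tn, cm.total, ci_method),
        prevalence=cm.prevalence,
        ci_method=ci_method,
    )


def predictive_values_at_prevalence(
    sens: float, spec: float, prevalence: float
) -> tuple[float, float]:
    """PPV and NPV at a stated prevalence via Bayes' theorem.

    PPV = sens·p / (sens·p + (1−spec)(1−p));
    NPV = spec(1−p) / (spec(1−p) + (1−sens)p).
    At prevalence 0 the PPV is undefined (NaN); at prevalence 1 the NPV.
    """
    for name, x in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0 <= x <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {x}")
    p = prevalence
    pos_mass = sens * p + (1 - spec) * (1 - p)
    neg_mass = spec * (1 - p) + (1 - sens) * p
    # boundary prevalences: there is no diseased (or no healthy) stratum,
    # so the corresponding predictive value is undefined, not 0
    ppv = sens * p / pos_mass if p > 0 and pos_mass > 0 else math.nan
    npv = spec * (1 - p) / neg_mass if p < 1 and neg_mass > 0 else math.nan
    return ppv, npv
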