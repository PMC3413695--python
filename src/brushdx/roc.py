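"""ROC analysis for continuous diagnostic markers on the ΔCt scale.

Markers over-expressed in malignancy have *lower* ΔCt in diseased
patients, so the default test-positivity convention is value ≤ cutoff
(``lower_is_positive``), with the cutoff inclusive.  Candidate cutoffs
are the observed marker values themselves, which is what lets derived
cutoffs land on observed-value precision.

AUC is the Mann–Whitney concordance probability (ties weighted ½),
computed from mid-ranks; it coincides exactly with trapezoidal
integration of the empirical ROC curve.  Its standard error uses the
Hanley–McNeil formula and the 95% CI the normal approximation clipped
to [0, 1].  The optimal cutoff maximizes the Youden index
J = sensitivity + specificity − 1, ties broken toward higher
sensitivity (rule-out priority in a screening context; configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Orientation",
    "RocPoint",
    "RocResult",
    "roc_curve",
    "auc",
    "trapezoid_auc",
    "hanley_mcneil_se",
    "optimal_cutoff",
    "binormal_auc",
    "analyze_marker",
]

Orientation = Literal["lower_is_positive", "higher_is_positive"]


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class RocResult:
    """Full single-marker ROC analysis."""

    marker: str
    orientation: Orientation
    points: list[RocPoint]
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    youden: float
    useless_marker: bool


def _validate(values: Sequence[float], labels: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if v.shape != y.shape or v.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    if np.isnan(v).any():
        raise ValueError("missing marker values must be filtered before ROC analysis")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return v, y


def roc_curve(
    values: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "lower_is_positive",
) -> list[RocPoint]:
    """Empirical ROC points, one per observed candidate cutoff plus endpoints.

    Under ``lower_is_positive`` a patient tests positive when
    value ≤ cutoff (inclusive); under ``higher_is_positive`` when
    value ≥ cutoff.  Endpoints (sens 0, spec 1) and (sens 1, spec 0)
    carry ∓inf cutoffs.
    """
    v, y = _validate(values, labels)
    if orientation == "higher_is_positive":
        flipped = roc_curve(-v, y, "lower_is_positive")
        return [
            RocPoint(-p.cutoff, p.sensitivity, p.specificity) for p in flipped
        ]
    if orientation != "lower_is_positive":
        raise ValueError(f"unknown orientation {orientation!r}")

    pos, neg = v[y], v[~y]
    n_pos, n_neg = pos.size, neg.size
    cutoffs = np.unique(v)
    points = [RocPoint(-math.inf, 0.0, 1.0)]
    for c in cutoffs:
        sens = float(np.count_nonzero(pos <= c)) / n_pos
        spec = float(np.count_nonzero(neg > c)) / n_neg
        points.append(RocPoint(float(c), sens, spec))
    points.append(RocPoint(math.inf, 1.0, 0.0))
    return points


def trapezoid_auc(points: Sequence[RocPoint]) -> float:
    """Area under the empirical ROC polygon (trapezoidal rule)."""
    pts = sorted(points, key=lambda p: (1 - p.specificity, p.sensitivity))
    fpr = np.array([1 - p.specificity for p in pts])
    tpr = np.array([p.sensitivity for p in pts])
    return float(np.trapezoid(tpr, fpr))


def _mann_whitney_auc(v: np.ndarray, y: np.ndarray) -> float:
    # concordance P(score_pos > score_neg) + 0.5 P(tie) via mid-ranks,
    # on a "higher score = more diseased" scale
    ranks = stats.rankdata(v)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u) / (n_pos * n_neg)


def hanley_mcneil_se(auc_value: float, n_pos: int, n_neg: int) -> float:
    """Hanley–McNeil standard error of the empirical AUC."""
    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc(
    values: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "lower_is_positive",
) -> tuple[float, float, tuple[float, float]]:
    """Empirical AUC with Hanley–McNeil SE and clipped 95% normal CI.

    AUC equals the probability that a random diseased patient looks more
    positive than a random non-diseased one, ties counting ½; computed
    from mid-ranks (identical to trapezoidal integration of the curve).
    """
    v, y = _validate(values, labels)
    score = -v if orientation == "lower_is_positive" else v
    a = _mann_whitney_auc(score, y)
    se = hanley_mcneil_se(a, int(y.sum()), int((~y).sum()))
    lo = max(0.0, a - 1.96 * se)
    hi = min(1.0, a + 1.96 * se)
    return a, se, (lo, hi)


def optimal_cutoff(points: Sequence[RocPoint]) -> tuple[float, float, float, bool]:
    """Cutoff maximizing the Youden index over candidate cutoffs.

    Degenerate endpoint cutoffs (±inf) are not candidates.  Ties are
    broken toward higher sensitivity.  If no cutoff achieves J > 0 the
    marker is useless at every threshold: the lowest candidate is
    returned with the warning flag set.

    Returns ``(cutoff, sensitivity, specificity, useless_flag)``.
    """
    candidates = [p for p in points if math.isfinite(p.cutoff)]
    if not candidates:
        raise ValueError("no finite candidate cutoffs")
    best = max(candidates, key=lambda p: (p.youden, p.sensitivity))
    if best.youden <= 0:
        lowest = min(candidates, key=lambda p: p.cutoff)
        return lowest.cutoff, lowest.sensitivity, lowest.specificity, True
    return best.cutoff, best.sensitivity, best.specificity, False


def binormal_auc(
    mean_pos: float,
    sd_pos: float,
    mean_neg: float,
    sd_neg: float,
    orientation: Orientation = "lower_is_positive",
) -> float:
    """Closed-form AUC for normal marker distributions in each class.

    Under ``lower_is_positive`` this is Φ((μ_neg − μ_pos)/√(σ_pos² + σ_neg²));
    the opposite sign under ``higher_is_positive``.  Serves as the exact
    reference value for simulation-based checks.
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    gap = mean_neg - mean_pos
    if orientation == "higher_is_positive":
        gap = -gap
    elif orientation != "lower_is_positive":
        raise ValueError(f"unknown orientation {orientation!r}")
    return float(stats.norm.cdf(gap / math.hypot(sd_pos, sd_neg)))


def analyze_marker(
    marker: str,
    values: Sequence[float],
    labels: Sequence[bool],
    orientation: Orientation = "lower_is_positive",
) -> RocResult:
    """Run the full single-marker ROC analysis: curve, AUC ± SE/CI, cutoff."""
    points = roc_curve(values, labels, orientation)
    a, se, ci = auc(values, labels, orientation)
    cut, sens, spec, useless = optimal_cutoff(points)
    return RocResult(
        marker=marker,
        orientation=orientation,
        points=points,
        auc=a,
        auc_se=se,
        auc_ci95=ci,
        optimal_cutoff=cut,
        sens_at_cutoff=sens,
        spec_at_cutoff=spec,
        youden=sens + spec - 1.0,
        useless_marker=useless,
    )
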