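"""Empirical ROC analysis and trough-threshold derivation.

Builds stepwise empirical ROC curves, computes the trapezoidal area (equal
to the tie-adjusted Mann-Whitney concordance), attaches the Hanley-McNeil
standard error and confidence interval, compares paired predictors with the
DeLong construction, and derives the Youden-optimal cutoff with its
sensitivity, specificity and predictive values.

Orientation is explicit. The positive class is the clinical flare
(treatment failure). For exposure metrics low values predict a flare, so
``direction="lower_is_positive"`` and a case is test-positive when its
score is *below* the cutoff; for the MPAG/MPA ratio high values predict a
flare (``higher_is_positive``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DomainError

LOWER = "lower_is_positive"
HIGHER = "higher_is_positive"


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos = labels.astype(bool)
    if pos.all() or (~pos).all():
        raise DomainError("need at least one positive and one negative label")
    return pos, ~pos


def _oriented(scores: np.ndarray, direction: str) -> np.ndarray:
    """Map scores so that larger oriented score = more positive-looking."""
    if direction == LOWER:
        return -scores
    if direction == HIGHER:
        return scores.copy()
    raise DomainError(f"unknown direction {direction!r}")


@dataclass
class RocCurve:
    predictor: str
    direction: str
    points: np.ndarray  # (k, 2) array of (fpr, tpr), from (0,0) to (1,1)
    n_pos: int
    n_neg: int
    #: distinct observed cutoffs aligned with points[1:], in original units
    cutoffs: np.ndarray


@dataclass
class RocResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float


@dataclass
class ThresholdMetrics:
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: Optional[float]
    npv: Optional[float]
    youden_j: float
    tp: int
    fp: int
    tn: int
    fn: int


def empirical_roc(scores: Sequence[float], labels: Sequence[int],
                  direction: str = LOWER, predictor: str = "") -> RocCurve:
    """Stepwise empirical ROC over all distinct score cutoffs.

    Under ``lower_is_positive`` a case is called test-positive when its
    score is strictly below the cutoff; under ``higher_is_positive`` when
    it is strictly above.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos, neg = _check_labels(lab)
    z = _oriented(s, direction)
    order = np.argsort(-z, kind="stable")  # descending oriented score
    zs = z[order]
    ps = pos[order]
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    tps = np.cumsum(ps)
    fps = np.cumsum(~ps)
    # keep only the last index of each tied block of oriented scores
    distinct = np.r_[np.flatnonzero(np.diff(zs)), zs.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    cut_oriented = zs[distinct]
    cutoffs = -cut_oriented if direction == LOWER else cut_oriented
    return RocCurve(predictor, direction,
                    np.column_stack([fpr, tpr]), n_pos, n_neg, cutoffs)


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the curve (ties counted half)."""
    fpr, tpr = roc.points[:, 0], roc.points[:, 1]
    return float(np.trapezoid(tpr, fpr))


def auc_from_scores(scores: Sequence[float], labels: Sequence[int],
                    direction: str = LOWER) -> float:
    return auc(empirical_roc(scores, labels, direction))


def hanley_mcneil(auc_value: float, n_pos: int, n_neg: int,
                  alpha: float = 0.05) -> RocResult:
    """Hanley-McNeil standard error and normal CI for an empirical AUC.

    Uses the Q1/Q2 approximations Q1 = A/(2-A), Q2 = 2A^2/(1+A); the CI is
    A +/- z_{1-alpha/2} SE, truncated to [0, 1].
    """
    if not (0.0 <= auc_value <= 1.0):
        raise DomainError("AUC must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise DomainError("need at least one case per class")
    a = auc_value
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(sps.norm.ppf(1.0 - alpha / 2.0))
    return RocResult(a, se, max(0.0, a - z * se), min(1.0, a + z * se))


def roc_with_ci(scores, labels, direction=LOWER, predictor="",
                alpha=0.05) -> tuple[RocCurve, RocResult]:
    curve = empirical_roc(scores, labels, direction, predictor)
    return curve, hanley_mcneil(auc(curve), curve.n_pos, curve.n_neg, alpha)


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_placements(z: np.ndarray, pos: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values for one oriented predictor."""
    zp, zn = z[pos], z[~pos]
    m, n = zp.size, zn.size
    all_r = _midrank(np.concatenate([zp, zn]))
    rp, rn = _midrank(zp), _midrank(zn)
    a = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - rp) / n          # per-positive placements
    v01 = 1.0 - (all_r[m:] - rn) / m    # per-negative placements
    return float(a), v10, v01


def compare_paired_auc(scores_1: Sequence[float], scores_2: Sequence[float],
                       labels: Sequence[int],
                       direction_1: str = LOWER, direction_2: str = LOWER,
                       ) -> tuple[float, float, float]:
    """DeLong paired test for the difference of two correlated AUCs.

    Both predictors are scored on the same subjects. Returns
    (delta_auc = auc1 - auc2, z, two-sided p). Identical or rank-equivalent
    predictors give delta 0 and p = 1.
    """
    lab = np.asarray(labels)
    pos, _ = _check_labels(lab)
    z1 = _oriented(np.asarray(scores_1, dtype=float), direction_1)
    z2 = _oriented(np.asarray(scores_2, dtype=float), direction_2)
    if z1.size != z2.size or z1.size != lab.size:
        raise DomainError("both score vectors must align with the labels")
    a1, v10_1, v01_1 = _delong_placements(z1, pos)
    a2, v10_2, v01_2 = _delong_placements(z2, pos)
    m, n = int(pos.sum()), int((~pos).sum())
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_delta = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = a1 - a2
    if var_delta <= 1e-16:
        # degenerate covariance: identical (up to rank) predictors
        zstat = 0.0 if abs(delta) < 1e-12 else np.inf * np.sign(delta)
    else:
        zstat = delta / float(np.sqrt(var_delta))
    p = float(2.0 * sps.norm.sf(abs(zstat))) if np.isfinite(zstat) else 0.0
    return float(delta), float(zstat), p


def metrics_at(scores: Sequence[float], labels: Sequence[int], cutoff: float,
               direction: str = LOWER) -> ThresholdMetrics:
    """Confusion-matrix metrics at a given cutoff.

    lower_is_positive: test-positive iff score < cutoff;
    higher_is_positive: test-positive iff score > cutoff.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    pos, neg = _check_labels(lab)
    called = s < cutoff if direction == LOWER else s > cutoff
    if direction not in (LOWER, HIGHER):
        raise DomainError(f"unknown direction {direction!r}")
    tp = int((called & pos).sum())
    fp = int((called & neg).sum())
    fn = int((~called & pos).sum())
    tn = int((~called & neg).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if (tp + fp) else None
    npv = tn / (tn + fn) if (tn + fn) else None
    return ThresholdMetrics(float(cutoff), sens, spec, ppv, npv,
                            sens + spec - 1.0, tp, fp, tn, fn)


def optimal_threshold(scores: Sequence[float], labels: Sequence[int],
                      direction: str = LOWER) -> ThresholdMetrics:
    """Cutoff maximising the Youden index over all observed cutpoints.

    Candidate cutoffs are every distinct observed score (plus one sentinel
    beyond the extreme so the all-positive call is reachable). Ties in J
    break toward higher NPV, then higher specificity.
    """
    s = np.asarray(scores, dtype=float)
    distinct = np.unique(s)
    if direction == LOWER:
        candidates = np.r_[distinct, distinct[-1] + 1.0]
    else:
        candidates = np.r_[distinct[0] - 1.0, distinct]
    best: Optional[ThresholdMetrics] = None
    for c in candidates:
        m = metrics_at(s, labels, float(c), direction)
        if best is None or _better(m, best):
            best = m
    assert best is not None
    return best


def _better(m: ThresholdMetrics, best: ThresholdMetrics) -> bool:
    eps = 1e-12
    if m.youden_j > best.youden_j + eps:
        return True
    if m.youden_j < best.youden_j - eps:
        return False
    m_npv = -1.0 if m.npv is None else m.npv
    b_npv = -1.0 if best.npv is None else best.npv
    if m_npv > b_npv + eps:
        return True
    if m_npv < b_npv - eps:
        return False
    return m.specificity > best.specificity + eps
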