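"""Descriptive summaries and univariate success-vs-failure comparisons.

Continuous characteristics are summarised as median (Q1-Q3) and compared
with the two-sided Mann-Whitney U test; the sex distribution is compared
with Fisher's exact test. Correlations use Spearman's rank coefficient.
No multiplicity adjustment is applied — the comparison table is a
univariate screen, and reports should footnote that.

Conventions (recorded in run metadata): quantiles by linear interpolation
between order statistics; Mann-Whitney exact by enumeration for pooled
n <= 20 without ties, otherwise the normal approximation with tie and
continuity corrections; Fisher two-sided by the point-probability rule
(summing tables no more probable than the observed one), with the
doubled-one-sided rule available as an option; Spearman p by exact
permutation for n <= 9, else the t approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError
from .model import Cohort

__all__ = [
    "median_iqr", "cv_percent", "cv_percent_of", "mann_whitney",
    "fisher_exact", "spearman", "compare_groups", "correlations",
    "GroupComparison", "CorrelationResult",
]


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with quartiles by linear interpolation."""
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)],
                     dtype=float)
    if arr.size == 0:
        raise DomainError("median_iqr needs at least one finite value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, percent: 100 * sd / mean."""
    if mean == 0:
        raise DomainError("CV undefined for zero mean")
    if sd < 0:
        raise DomainError("standard deviation must be non-negative")
    return 100.0 * sd / mean

def cv_percent_of(values: Sequence[float]) -> float:
    """CV of a sample, using the n-1 standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DomainError("sample CV needs at least two values")
    return cv_percent(float(arr.mean()), float(arr.std(ddof=1)))


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float],
                 ) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p).

    Exact enumeration when the pooled sample has <= 20 observations and no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DomainError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table: Sequence[Sequence[int]],
                 rule: str = "point_probability") -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    ``point_probability`` (default) sums the hypergeometric probabilities of
    every table with fixed margins whose point probability does not exceed
    the observed one. ``double_one_sided`` doubles the smaller one-sided
    tail, capped at 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise DomainError("need a 2x2 table of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DomainError("every row and column margin must be positive")
    if rule == "point_probability":
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    if rule == "double_one_sided":
        p_less = sps.fisher_exact(t, alternative="less")[1]
        p_greater = sps.fisher_exact(t, alternative="greater")[1]
        return float(min(1.0, 2.0 * min(p_less, p_greater)))
    raise DomainError(f"unknown two-sided rule {rule!r}")


@dataclass
class CorrelationResult:
    pair: str
    rho: Optional[float]
    p_value: Optional[float]
    n: int
    note: str = ""


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for |rho| >= |rho_obs| (tiny n only)."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman(x: Sequence[float], y: Sequence[float], pair: str = "",
             ) -> CorrelationResult:
    """Spearman rank correlation with two-sided p.

    Exact permutation p for n <= 9; t approximation otherwise. A constant
    vector leaves rho undefined (flagged, not raised).
    """
    xs, ys = [], []
    for xi, yi in zip(x, y):
        if xi is not None and yi is not None and np.isfinite(xi) and np.isfinite(yi):
            xs.append(float(xi))
            ys.append(float(yi))
    xa, ya = np.asarray(xs), np.asarray(ys)
    n = xa.size
    if n < 3:
        raise DomainError("Spearman correlation needs at least 3 pairs")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        return CorrelationResult(pair, None, None, n, note="constant input, rho undefined")
    rho = float(sps.spearmanr(xa, ya).statistic)
    if n <= 9:
        p = _spearman_exact_p(xa, ya, rho)
    else:
        p = float(sps.spearmanr(xa, ya).pvalue)
    return CorrelationResult(pair, rho, p, n)


@dataclass
class GroupComparison:
    """One comparison-table row: total / successes / failures and a p value."""

    characteristic: str
    test: str  # mann_whitney | fisher_exact
    total_median: Optional[float] = None
    total_q1: Optional[float] = None
    total_q3: Optional[float] = None
    success_median: Optional[float] = None
    success_q1: Optional[float] = None
    success_q3: Optional[float] = None
    failure_median: Optional[float] = None
    failure_q1: Optional[float] = None
    failure_q3: Optional[float] = None
    p_value: Optional[float] = None
    # for the sex row: "F/M" count strings instead of medians
    total_counts: Optional[str] = None
    success_counts: Optional[str] = None
    failure_counts: Optional[str] = None


#: comparison-table rows in canonical order: (characteristic, source, field)
#: source is one of patient | pk
_TABLE_ROWS: list[tuple[str, str, str]] = [
    ("females_males", "patient", "sex"),
    ("age_years", "patient", "age"),
    ("body_weight_kg", "patient", "weight"),
    ("sledai_score", "patient", "sledai_entry"),
    ("c3_g_l", "patient", "c3"),
    ("c4_g_l", "patient", "c4"),
    ("anti_dsdna_iu_ml", "patient", "anti_dsdna"),
    ("gfr_ml_min", "patient", "gfr"),
    ("albumin_g_l", "patient", "albumin"),
    ("mmf_g_day", "patient", "mmf_dose"),
    ("corticosteroids_mg_day", "patient", "prednisone_dose"),
    ("months_of_mmf", "patient", "months_on_mmf"),
    ("months_of_corticosteroids", "patient", "months_on_steroids"),
    ("mpa_auc_0_12", "pk", "mpa_auc_0_12"),
    ("mpa_cmax", "pk", "mpa_cmax"),
    ("mpa_tmax", "pk", "mpa_tmax"),
    ("mpa_c12h", "pk", "mpa_c12h"),
    ("mpag_auc_0_12", "pk", "mpag_auc_0_12"),
    ("mpag_tmax", "pk", "mpag_tmax"),
    ("mpag_c12h", "pk", "mpag_c12h"),
    ("ratio_auc", "pk", "ratio_auc"),
    ("ratio_c12h", "pk", "ratio_c12h"),
]


def _values(source: str, field_name: str, cohort: Cohort,
            pk: pd.DataFrame, ids: list[str]) -> list[float]:
    if source == "patient":
        by_id = {p.patient_id: getattr(p, field_name) for p in cohort.patients}
        vals = [by_id.get(i) for i in ids]
    else:
        sub = pk.set_index("patient_id")[field_name]
        vals = [sub.get(i) for i in ids]
    return [v for v in vals if v is not None and np.isfinite(v)]


def compare_groups(cohort: Cohort, pk_params: pd.DataFrame,
                   outcomes) -> list[GroupComparison]:
    """Success-vs-failure univariate comparison over every table row.

    ``outcomes`` is a list of OutcomeLabel; excluded patients are dropped
    from both groups. If exclusions empty a group the medians/p for that
    row are reported absent (None), never fabricated.
    """
    succ_ids = [o.patient_id for o in outcomes if o.label == "success"]
    fail_ids = [o.patient_id for o in outcomes if o.label == "failure"]
    all_ids = succ_ids + fail_ids
    out: list[GroupComparison] = []
    sex_by_id = {p.patient_id: p.sex for p in cohort.patients}
    for name, source, field_name in _TABLE_ROWS:
        if field_name == "sex":
            def fm(ids):
                f = sum(1 for i in ids if sex_by_id[i] == "female")
                return f, len(ids) - f
            tf, tm = fm(all_ids)
            sf, sm = fm(succ_ids)
            ff, fmale = fm(fail_ids)
            p = None
            try:
                p = fisher_exact([[sf, sm], [ff, fmale]])
            except DomainError:
                p = None
            out.append(GroupComparison(
                name, "fisher_exact", p_value=p,
                total_counts=f"{tf}/{tm}", success_counts=f"{sf}/{sm}",
                failure_counts=f"{ff}/{fmale}"))
            continue
        total = _values(source, field_name, cohort, pk_params, all_ids)
        succ = _values(source, field_name, cohort, pk_params, succ_ids)
        fail = _values(source, field_name, cohort, pk_params, fail_ids)
        g = GroupComparison(name, "mann_whitney")
        if total:
            g.total_median, g.total_q1, g.total_q3 = median_iqr(total)
        if succ:
            g.success_median, g.success_q1, g.success_q3 = median_iqr(succ)
        if fail:
            g.failure_median, g.failure_q1, g.failure_q3 = median_iqr(fail)
        if succ and fail:
            _, g.p_value = mann_whitney(succ, fail)
        out.append(g)
    return out


#: correlation pairs examined alongside the comparison table
_CORRELATION_PAIRS: list[tuple[str, tuple[str, str], tuple[str, str]]] = [
    ("mpa_auc_vs_albumin", ("pk", "mpa_auc_0_12"), ("patient", "albumin")),
    ("mpa_auc_vs_weight", ("pk", "mpa_auc_0_12"), ("patient", "weight")),
    ("ratio_auc_vs_ratio_c12h", ("pk", "ratio_auc"), ("pk", "ratio_c12h")),
    ("dose_vs_mpa_auc", ("patient", "mmf_dose"), ("pk", "mpa_auc_0_12")),
    ("dose_vs_mpa_c12h", ("patient", "mmf_dose"), ("pk", "mpa_c12h")),
    ("ratio_c12h_vs_albumin", ("pk", "ratio_c12h"), ("patient", "albumin")),
    ("ratio_c12h_vs_gfr", ("pk", "ratio_c12h"), ("patient", "gfr")),
    ("ratio_c12h_vs_prednisone", ("pk", "ratio_c12h"), ("patient", "prednisone_dose")),
    ("c4_vs_mpa_c12h", ("patient", "c4"), ("pk", "mpa_c12h")),
    ("mpa_auc_vs_mpa_c12h", ("pk", "mpa_auc_0_12"), ("pk", "mpa_c12h")),
]


def correlations(cohort: Cohort, pk_params: pd.DataFrame,
                 outcomes=None) -> list[CorrelationResult]:
    """Spearman correlations for the standard exposure/covariate pairs."""
    if outcomes is not None:
        ids = [o.patient_id for o in outcomes if o.label in ("success", "failure")]
    else:
        ids = cohort.patient_ids()

    def pull(spec_pair):
        source, field_name = spec_pair
        if source == "patient":
            by_id = {p.patient_id: getattr(p, field_name) for p in cohort.patients}
            return [by_id.get(i) for i in ids]
        sub = pk_params.set_index("patient_id")[field_name]
        return [sub.get(i) for i in ids]

    results = []
    for pair_name, left, right in _CORRELATION_PAIRS:
        try:
            results.append(spearman(pull(left), pull(right), pair=pair_name))
        except DomainError as exc:
            results.append(CorrelationResult(pair_name, None, None, 0, note=str(exc)))
    return results


def comparison_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(g) for g in comparisons])


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
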