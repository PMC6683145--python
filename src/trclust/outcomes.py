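"""Conventional response markers and cluster-validation statistics.

Markers: weeks to discharge; response (>= 50% relative raw-score decrease at
the last observed visit); remission (raw score < 10 at the last observed
visit); the individual OLS slope of ln-transformed scores on week; and the
episode-mean raw score.  Group statistics: one-way ANOVA with Cohen's f
(thresholds 0.10 / 0.25 / 0.40 for small / medium / large) and a Gaussian
generalized-linear-model likelihood-ratio test of item ~ class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .prep import Cohort, RatingSeries, REMISSION_THRESHOLD


@dataclass
class ResponseMarkers:
    patient_id: str
    weeks_to_discharge: int
    response: bool
    remission: bool
    individual_slope: Optional[float]
    baseline_raw: float
    episode_mean_raw: float


@dataclass
class GroupComparison:
    f_stat: float
    p_value: float
    cohens_f: float
    effect_label: str
    degenerate: bool = False  # SS_within == 0


def individual_slope(series: RatingSeries) -> float:
    """OLS slope of ln-values on week index; requires >= 2 timepoints."""
    if series.lnvals is None:
        raise ValueError("series must be regularized")
    if len(series.weeks) < 2:
        raise ValueError("individual slope needs at least 2 timepoints")
    t = series.weeks.astype(float)
    y = series.lnvals
    tc = t - t.mean()
    return float((tc @ (y - y.mean())) / (tc @ tc))


def response_markers(series: RatingSeries) -> ResponseMarkers:
    """Markers evaluated at the last observed week (discharge or design end)."""
    if series.lnvals is None:
        raise ValueError("series must be regularized")
    baseline = float(series.raw[0])
    final = float(series.raw[-1])
    slope = individual_slope(series) if len(series.weeks) >= 2 else None
    return ResponseMarkers(
        patient_id=series.patient_id,
        weeks_to_discharge=series.last_week,
        response=(baseline - final) / baseline >= 0.5,
        remission=final < REMISSION_THRESHOLD,
        individual_slope=slope,
        baseline_raw=baseline,
        episode_mean_raw=float(np.mean(series.raw)),
    )


def markers_table(cohort: Cohort):
    """DataFrame of response markers keyed by patient_id."""
    import pandas as pd

    rows = [response_markers(s) for s in cohort.series]
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "weeks_to_discharge": [r.weeks_to_discharge for r in rows],
            "response": [r.response for r in rows],
            "remission": [r.remission for r in rows],
            "individual_slope": [r.individual_slope for r in rows],
            "baseline_raw": [r.baseline_raw for r in rows],
            "episode_mean_raw": [r.episode_mean_raw for r in rows],
        }
    ).set_index("patient_id")


def slope_correlates(cohort: Cohort, assignments):
    """Pearson correlations of cluster-derived slopes with severity summaries.

    Returns a dict with entries ``baseline`` and ``episode_mean``, each a
    (r, p) pair; entries are (nan, nan) when either variable is constant.
    """
    slopes = np.asarray(assignments.cluster_slopes, dtype=float)
    if len(slopes) != len(cohort):
        raise ValueError("assignments and cohort sizes differ")
    if len(slopes) < 3:
        raise ValueError("need at least 3 patients")
    baseline = np.array([s.raw[0] for s in cohort.series], dtype=float)
    episode = np.array([np.mean(s.raw) for s in cohort.series], dtype=float)
    out = {}
    for key, other in (("baseline", baseline), ("episode_mean", episode)):
        if np.std(slopes) == 0 or np.std(other) == 0:
            out[key] = (float("nan"), float("nan"))
        else:
            res = stats.pearsonr(slopes, other)
            out[key] = (float(res.statistic), float(res.pvalue))
    return out


def effect_label(f: float) -> str:
    """Cohen's f category: < 0.10 negligible, then small/medium/large."""
    if f < 0.10:
        return "negligible"
    if f < 0.25:
        return "small"
    if f < 0.40:
        return "medium"
    return "large"


def anova_f(values, labels) -> GroupComparison:
    """One-way ANOVA F, p, and Cohen's f = sqrt(eta2 / (1 - eta2)).

    Classes with zero members are dropped; zero within-group variation with
    distinct means yields an infinite effect size, reported as large with the
    ``degenerate`` flag set.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 occupied classes")
    if n - k < 1 or n < 3:
        raise ValueError("ANOVA needs at least 2 residual degrees of freedom")
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(((values - grand) ** 2).sum())
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        if ss_between == 0:
            return GroupComparison(0.0, 1.0, 0.0, "negligible")
        return GroupComparison(float("inf"), 0.0, float("inf"), "large", degenerate=True)
    f_stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f_stat, k - 1, n - k))
    eta2 = ss_between / ss_total
    cf = float(np.sqrt(eta2 / (1.0 - eta2)))
    return GroupComparison(float(f_stat), p, cf, effect_label(cf))


def univariate_lrt(item, labels) -> float:
    """Likelihood-ratio p-value of a Gaussian linear model item ~ class.

    Compares group-means against intercept-only with maximum-likelihood
    variance estimates; the statistic n*ln(SS0/SS1) is referred to a
    chi-square with K-1 degrees of freedom.
    """
    values = np.asarray(item, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    n = len(values)
    if k < 2:
        raise ValueError("likelihood-ratio test needs at least 2 occupied classes")
    if n - k < 1:
        raise ValueError("insufficient residual degrees of freedom")
    ss0 = float(((values - values.mean()) ** 2).sum())
    ss1 = 0.0
    for g in uniq:
        v = values[labels == g]
        ss1 += float(((v - v.mean()) ** 2).sum())
    if ss1 <= 0 or ss0 <= 0:
        return 0.0 if ss0 > ss1 else 1.0
    stat = n * np.log(ss0 / ss1)
    return float(stats.chi2.sf(stat, k - 1))
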