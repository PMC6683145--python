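"""Fixed-model classification of new cohorts.

A fitted mixture is projected onto a validation cohort without refitting:
posterior responsibilities come from an E-step under frozen parameters, and
cohort-level fit is summarized by the observed-data log-likelihood, the
classification (hard-assignment) log-likelihood, posterior entropy, and ICL.
Class proportions between two samples are compared with a Pearson chi-square
homogeneity test, and classification stability under shortened observation
windows is quantified by correlating cluster-derived slopes from truncated
versus full-window assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .mixture import (
    Assignments,
    MixtureModel,
    _e_step_arrays,
    cohort_suffstats,
    n_free_params,
    posterior_entropy,
)
from .prep import Cohort, DESIGN_WEEKS


@dataclass
class ProjectionResult:
    assignments: Assignments
    loglik: float
    class_loglik: float
    entropy: float
    icl: float
    n_patients: int


@dataclass
class TruncationResult:
    window_weeks: int           # number of leading weekly observations used
    pearson_r: float            # NaN when degenerate
    n_effective: int


def _assign(model: MixtureModel, cohort: Cohort, m: Optional[int] = None):
    ss = cohort_suffstats(cohort, m=m)
    z, loglik, ll = _e_step_arrays(ss, model.intercepts, model.slopes,
                                   model.residual_sds, model.weights)
    labels = np.argmax(z, axis=1)
    assignments = Assignments(ss.patient_ids, z, labels, model.slopes[labels])
    logw = np.log(model.weights)
    class_ll = float((ll[np.arange(len(labels)), labels] + logw[labels]).sum())
    return assignments, loglik, class_ll


def assign_fixed(model: MixtureModel, cohort: Cohort) -> ProjectionResult:
    """Classify a cohort under frozen mixture parameters (no refit)."""
    model.validate()
    assignments, loglik, class_ll = _assign(model, cohort)
    n = len(cohort)
    ent = posterior_entropy(assignments.posteriors)
    icl = -2.0 * loglik + n_free_params(model.k) * np.log(n) + 2.0 * ent
    return ProjectionResult(assignments, loglik, class_ll, ent, icl, n)


def truncate_and_assign(model: MixtureModel, cohort: Cohort, m: int) -> Assignments:
    """Classify using only each patient's first min(m, available) weekly values."""
    if m < 1:
        raise ValueError("m must be >= 1")
    model.validate()
    assignments, _, _ = _assign(model, cohort, m=m)
    return assignments


def truncation_curve(model: MixtureModel, cohort: Cohort) -> list:
    """Pearson r of cluster-derived slopes, truncated vs. full assignment.

    Evaluated for every window length m from 1 to the design's maximum
    (17 weekly values for the MARS grid, 13 for GENDEP).  Windows where
    either assignment leaves all patients in a single class have undefined
    correlation and are reported as NaN with a warning.
    """
    full = assign_fixed(model, cohort).assignments
    m_max = max(DESIGN_WEEKS[cohort.design]) + 1
    out = []
    for m in range(1, m_max + 1):
        trunc = truncate_and_assign(model, cohort, m)
        a, b = trunc.cluster_slopes, full.cluster_slopes
        if np.std(a) == 0 or np.std(b) == 0:
            if np.array_equal(trunc.labels, full.labels):
                r = 1.0
            else:
                warnings.warn(f"degenerate class variance at window m={m}; "
                              "correlation undefined", RuntimeWarning)
                r = float("nan")
        else:
            r = float(stats.pearsonr(a, b).statistic)
        out.append(TruncationResult(m, r, len(a)))
    return out


def proportion_test(counts_a, counts_b):
    """Pearson chi-square homogeneity test on a K x 2 contingency table.

    Classes empty in both samples are dropped with a warning.  Returns
    (chi2, df, p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must be 1-D with equal class counts")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("each sample must contain at least one patient")
    keep = (a + b) > 0
    if not np.all(keep):
        warnings.warn("dropping classes empty in both samples", RuntimeWarning)
        a, b = a[keep], b[keep]
    table = np.column_stack([a, b])
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
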