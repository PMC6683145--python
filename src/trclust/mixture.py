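"""Finite mixture of linear regressions for grouped trajectories.

Each latent class k is a line on the ln(HAM-D + 0.5) scale with independent
Gaussian residuals: y_it ~ N(I_k + S_k * t, sigma_k^2).  Patients (not
observations) are the exchangeable units: one posterior responsibility z_ik
per patient, computed from the product of that patient's point densities.
Fitting alternates an E-step (log-space responsibilities) and an M-step
(responsibility-weighted least squares per class) from a seeded random hard
partition; the class count is selected by the integrated completed
likelihood, ICL = BIC + 2 * posterior entropy, minimized over k.

Internally the likelihood and M-step are evaluated from per-patient
sufficient statistics (n_i, sum t, sum t^2, sum y, sum ty, sum y^2), which is
algebraically identical to the row-level computation but independent of
series length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .prep import Cohort, RatingSeries

LOG_2PI = float(np.log(2.0 * np.pi))
SIGMA_FLOOR = 1e-4        # residual-SD floor guarding against degenerate fits
WEIGHT_FLOOR = 1.0        # minimum effective patient mass per component


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class MixtureComponent:
    intercept: float
    slope: float
    residual_sd: float
    weight: float


@dataclass
class MixtureModel:
    components: list

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def intercepts(self) -> np.ndarray:
        return np.array([c.intercept for c in self.components])

    @property
    def slopes(self) -> np.ndarray:
        return np.array([c.slope for c in self.components])

    @property
    def residual_sds(self) -> np.ndarray:
        return np.array([c.residual_sd for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("model must have at least one component")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("mixing weights must sum to 1")
        if np.any(self.residual_sds <= 0):
            raise ValueError("residual_sd must be positive")


@dataclass
class FitDiagnostics:
    loglik: float
    n_params: int
    bic: float
    entropy: float
    icl: float
    n_iter: int
    converged: bool
    n_restarts_failed: int = 0


@dataclass
class Assignments:
    """Per-patient posterior responsibilities and derived hard labels."""

    patient_ids: list
    posteriors: np.ndarray  # (n, k)
    labels: np.ndarray      # argmax posterior, ties -> lowest index
    cluster_slopes: np.ndarray

    def __len__(self) -> int:
        return len(self.patient_ids)


def n_free_params(k: int) -> int:
    """3 parameters per component plus k-1 free mixing weights."""
    return 3 * k + (k - 1)


def posterior_entropy(posteriors: np.ndarray) -> float:
    """ENT = -sum_i sum_k z_ik ln z_ik (0 ln 0 := 0)."""
    z = np.asarray(posteriors, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(z > 0, z * np.log(z), 0.0)
    return float(-term.sum())


# --------------------------------------------------------------------------
# Sufficient statistics
# --------------------------------------------------------------------------

@dataclass
class SuffStats:
    """Per-patient sufficient statistics of a linear-Gaussian trajectory."""

    patient_ids: list
    n: np.ndarray
    st: np.ndarray
    stt: np.ndarray
    sy: np.ndarray
    sty: np.ndarray
    syy: np.ndarray

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def matrix(self) -> np.ndarray:
        """(n, 6) stacked stats [n, st, stt, sy, sty, syy]; cached."""
        m = getattr(self, "_matrix", None)
        if m is None:
            m = np.column_stack([self.n, self.st, self.stt, self.sy, self.sty, self.syy])
            self._matrix = m
        return m


def cohort_suffstats(cohort: Cohort, m: Optional[int] = None) -> SuffStats:
    """Sufficient statistics per patient over their regularized weekly grid.

    ``m`` limits each patient to their first min(m, available) weekly values
    (truncated-window classification).
    """
    ids, n, st, stt, sy, sty, syy = [], [], [], [], [], [], []
    for s in cohort.series:
        if s.lnvals is None:
            raise ValueError(f"patient {s.patient_id}: series not regularized")
        t = s.weeks.astype(float)
        y = s.lnvals
        if m is not None:
            if m < 1:
                raise ValueError("m must be >= 1")
            t, y = t[:m], y[:m]
        if len(y) == 0:
            raise ValueError(f"patient {s.patient_id}: no usable visits")
        ids.append(s.patient_id)
        n.append(len(y))
        st.append(t.sum())
        stt.append((t * t).sum())
        sy.append(y.sum())
        sty.append((t * y).sum())
        syy.append((y * y).sum())
    return SuffStats(ids, np.array(n, float), np.array(st), np.array(stt),
                     np.array(sy), np.array(sty), np.array(syy))


def _loglik_matrix(ss: SuffStats, intercepts, slopes, sds) -> np.ndarray:
    """(n_patients, k) matrix of per-patient component log-densities.

    The per-patient residual sum of squares under component (a, b) expands as
    a linear combination of the sufficient statistics, so the whole matrix is
    one matrix product: coef columns pair with [n, st, stt, sy, sty, syy].
    """
    a = np.atleast_1d(np.asarray(intercepts, float))
    b = np.atleast_1d(np.asarray(slopes, float))
    var = np.atleast_1d(np.asarray(sds, float)) ** 2
    inv2v = 1.0 / (2.0 * var)
    const = -0.5 * (LOG_2PI + np.log(var))
    coef = np.stack([
        const - a**2 * inv2v,        # * n
        -2.0 * a * b * inv2v,        # * st
        -(b**2) * inv2v,             # * stt
        2.0 * a * inv2v,             # * sy
        2.0 * b * inv2v,             # * sty
        -inv2v,                      # * syy
    ])
    return ss.matrix @ coef


def component_loglik(series: RatingSeries, comp: MixtureComponent) -> float:
    """Gaussian log-density of one patient's trajectory under one component."""
    if series.lnvals is None or len(series.lnvals) == 0:
        raise ValueError("series must be regularized and non-empty")
    ss = cohort_suffstats(Cohort([series]))
    return float(_loglik_matrix(ss, [comp.intercept], [comp.slope], [comp.residual_sd])[0, 0])


# --------------------------------------------------------------------------
# EM steps
# --------------------------------------------------------------------------

def _e_step_arrays(ss: SuffStats, intercepts, slopes, sds, weights):
    """Responsibilities, total log-likelihood, and the loglik matrix."""
    ll = _loglik_matrix(ss, intercepts, slopes, sds)
    logw = np.log(np.asarray(weights, float))[None, :]
    joint = ll + logw
    mx = joint.max(axis=1)
    shifted = np.exp(joint - mx[:, None])
    norm = mx + np.log(shifted.sum(axis=1))
    bad = ~np.isfinite(norm)
    z = np.exp(joint - norm[:, None])
    if np.any(bad):
        warnings.warn("all component densities underflowed for some patients; "
                      "assigning uniform posteriors", RuntimeWarning)
        z[bad] = 1.0 / joint.shape[1]
        norm = np.where(bad, -np.inf, norm)
        total = float(norm[~bad].sum())
    else:
        total = float(norm.sum())
    return z, total, ll


def e_step(model: MixtureModel, cohort: Cohort) -> Assignments:
    """Posterior responsibilities under a fixed model (log-space, stable)."""
    model.validate()
    ss = cohort_suffstats(cohort)
    z, _, _ = _e_step_arrays(ss, model.intercepts, model.slopes,
                             model.residual_sds, model.weights)
    labels = np.argmax(z, axis=1)
    return Assignments(ss.patient_ids, z, labels, model.slopes[labels])


def _m_step_arrays(ss: SuffStats, z: np.ndarray):
    """Responsibility-weighted least squares per component.

    Each patient's rows enter with that patient's z_ik; sigma_k^2 is the
    weighted mean squared residual and pi_k the mean responsibility.
    Returns (intercepts, slopes, sds, weights, degenerate_flag).
    """
    eff = z.sum(axis=0)                     # effective patients per component
    swn, swt, swtt, swy, swty, swyy = (z.T @ ss.matrix).T
    det = swn * swtt - swt**2
    degenerate = bool(np.any(eff < WEIGHT_FLOOR) or np.any(np.abs(det) < 1e-12))
    if degenerate:
        return None, None, None, None, True
    a = (swtt * swy - swt * swty) / det
    b = (swn * swty - swt * swy) / det
    rss = swyy - 2 * a * swy - 2 * b * swty + a**2 * swn + 2 * a * b * swt + b**2 * swtt
    var = np.maximum(rss, 0.0) / swn
    sds = np.maximum(np.sqrt(var), SIGMA_FLOOR)
    weights = z.mean(axis=0)
    return a, b, sds, weights, False


def m_step(cohort: Cohort, posteriors: np.ndarray) -> MixtureModel:
    """Weighted least-squares update; raises on degenerate responsibilities."""
    ss = cohort_suffstats(cohort)
    a, b, sds, w, degen = _m_step_arrays(ss, np.asarray(posteriors, float))
    if degen:
        raise RuntimeError("degenerate M-step: component effective weight below floor")
    return MixtureModel([MixtureComponent(a[j], b[j], sds[j], w[j]) for j in range(len(a))])


# --------------------------------------------------------------------------
# Fitting
# --------------------------------------------------------------------------

@dataclass
class EMFit:
    model: MixtureModel
    diagnostics: FitDiagnostics
    assignments: Assignments
    loglik_history: list = field(default_factory=list)


def _random_hard_partition(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random patient partition with every component non-empty."""
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    rng.shuffle(labels)
    return labels


def fit_em(cohort_or_ss, k: int, seed: int = 0, tol: float = 1e-8,
           max_iter: int = 500, init_labels: Optional[np.ndarray] = None) -> EMFit:
    """One EM run from a seeded random hard partition.

    Degenerate runs (a component losing essentially all patient mass) are
    returned with ``converged=False`` and the last valid parameters.
    """
    ss = cohort_or_ss if isinstance(cohort_or_ss, SuffStats) else cohort_suffstats(cohort_or_ss)
    n = ss.n_patients
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of patients ({n})")
    rng = np.random.default_rng(seed)
    if init_labels is None:
        init_labels = _random_hard_partition(n, k, rng)
    z = np.zeros((n, k))
    z[np.arange(n), np.asarray(init_labels, int)] = 1.0

    a = b = sds = w = None
    history = []
    converged = False
    degenerate = False
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        a2, b2, sds2, w2, degen = _m_step_arrays(ss, z)
        if degen:
            degenerate = True
            break
        a, b, sds, w = a2, b2, sds2, w2
        z, loglik, _ = _e_step_arrays(ss, a, b, sds, w)
        history.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = loglik

    if a is None:  # degenerate before any valid M-step
        raise RuntimeError("EM failed at initialization: degenerate partition")
    model = MixtureModel([MixtureComponent(a[j], b[j], sds[j], w[j]) for j in range(k)])
    labels = np.argmax(z, axis=1)
    assignments = Assignments(ss.patient_ids, z, labels, model.slopes[labels])
    loglik = history[-1]
    ent = posterior_entropy(z)
    p = n_free_params(k)
    bic = -2.0 * loglik + p * np.log(n)
    diag = FitDiagnostics(loglik=loglik, n_params=p, bic=bic, entropy=ent,
                          icl=bic + 2.0 * ent, n_iter=it,
                          converged=converged and not degenerate)
    return EMFit(model, diag, assignments, history)


def information_criteria(fit: EMFit, cohort: Cohort) -> FitDiagnostics:
    """Recompute BIC/entropy/ICL for a fit on a cohort (N = patients)."""
    n = len(cohort)
    p = n_free_params(fit.model.k)
    ent = posterior_entropy(fit.assignments.posteriors)
    bic = -2.0 * fit.diagnostics.loglik + p * np.log(n)
    return FitDiagnostics(loglik=fit.diagnostics.loglik, n_params=p, bic=bic,
                          entropy=ent, icl=bic + 2.0 * ent,
                          n_iter=fit.diagnostics.n_iter,
                          converged=fit.diagnostics.converged,
                          n_restarts_failed=fit.diagnostics.n_restarts_failed)


@dataclass
class RestartReport:
    n_restarts: int
    n_failed: int
    best: Optional[EMFit]


def fit_restarts(cohort_or_ss, k: int, n_restarts: int = 200, seed: int = 0,
                 tol: float = 1e-8, max_iter: int = 500) -> RestartReport:
    """Best converged fit over ``n_restarts`` seeded EM runs.

    Sub-seeds are spawned deterministically from ``seed``.  Zero converged
    restarts yield an explicit no-solution report (``best is None``).
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    ss = cohort_or_ss if isinstance(cohort_or_ss, SuffStats) else cohort_suffstats(cohort_or_ss)
    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best, n_failed = None, 0
    for child in children:
        sub = int(child.generate_state(1)[0] % (2**31))
        try:
            fit = fit_em(ss, k, seed=sub, tol=tol, max_iter=max_iter)
        except RuntimeError:
            n_failed += 1
            continue
        if not fit.diagnostics.converged:
            n_failed += 1
            continue
        if best is None or fit.diagnostics.loglik > best.diagnostics.loglik:
            best = fit
    return RestartReport(n_restarts, n_failed, best)


@dataclass
class ModelSelection:
    """Per-k diagnostics and the ICL-minimizing model."""

    table: dict                      # k -> FitDiagnostics or None
    reports: dict                    # k -> RestartReport
    chosen_k: Optional[int]
    best_fit: Optional[EMFit]        # sorted model, relabeled assignments


def select_k(cohort: Cohort, k_range: Sequence[int] = range(4, 11),
             n_restarts: int = 200, seed: int = 0, tol: float = 1e-8,
             max_iter: int = 500) -> ModelSelection:
    """Fit each k with restarts; choose the converged k minimizing ICL."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    ss = cohort_suffstats(cohort)
    root = np.random.SeedSequence(seed).spawn(len(k_range))
    table, reports = {}, {}
    for k, child in zip(k_range, root):
        sub = int(child.generate_state(1)[0] % (2**31))
        rep = fit_restarts(ss, k, n_restarts=n_restarts, seed=sub, tol=tol, max_iter=max_iter)
        reports[k] = rep
        if rep.best is None:
            table[k] = None
        else:
            diag = rep.best.diagnostics
            diag.n_restarts_failed = rep.n_failed
            table[k] = diag
    converged = {k: d for k, d in table.items() if d is not None}
    if not converged:
        return ModelSelection(table, reports, None, None)
    chosen = min(converged, key=lambda k: converged[k].icl)
    fit = reports[chosen].best
    model, assignments = sort_components(fit.model, fit.assignments)
    best = EMFit(model, fit.diagnostics, assignments, fit.loglik_history)
    return ModelSelection(table, reports, chosen, best)


def sort_components(model: MixtureModel, assignments: Optional[Assignments] = None):
    """Order components ascending by slope (fastest improvement first).

    Ties break ascending by intercept.  If assignments are given they are
    relabeled consistently and returned alongside.
    """
    order = np.lexsort((model.intercepts, model.slopes))
    sorted_model = MixtureModel([model.components[j] for j in order])
    if assignments is None:
        return sorted_model
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    z = assignments.posteriors[:, order]
    labels = np.argmax(z, axis=1)
    relabeled = Assignments(assignments.patient_ids, z, labels,
                            sorted_model.slopes[labels])
    return sorted_model, relabeled
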