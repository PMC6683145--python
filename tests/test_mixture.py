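import json

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from trclust.mixture import (
    Assignments,
    MixtureComponent,
    MixtureModel,
    component_loglik,
    e_step,
    fit_em,
    fit_restarts,
    information_criteria,
    m_step,
    n_free_params,
    posterior_entropy,
    select_k,
    sort_components,
)
from trclust.prep import Cohort, regularize_cohort
from trclust.synthetic import GeneratingComponent, SyntheticSpec, generate_cohort, separated_spec

from conftest import make_series


# --------------------------------------------------------------------------
# Brute-force oracles (independent of the sufficient-statistics code path)
# --------------------------------------------------------------------------

def brute_loglik(series, comp):
    """Sum of Gaussian log-densities evaluated point by point."""
    total = 0.0
    for t, y in zip(series.weeks, series.lnvals):
        total += stats.norm.logpdf(y, loc=comp.intercept + comp.slope * t,
                                   scale=comp.residual_sd)
    return total


def brute_posteriors(model, cohort):
    z = np.zeros((len(cohort), model.k))
    for i, s in enumerate(cohort.series):
        dens = np.array([w * np.exp(brute_loglik(s, c))
                         for c, w in zip(model.components, model.weights)])
        z[i] = dens / dens.sum()
    return z


def brute_wls(cohort, weights_per_patient):
    """Row-expanded weighted least squares via explicit normal equations."""
    rows_t, rows_y, rows_w = [], [], []
    for s, w in zip(cohort.series, weights_per_patient):
        rows_t.extend(s.weeks.astype(float))
        rows_y.extend(s.lnvals)
        rows_w.extend([w] * len(s.weeks))
    t = np.array(rows_t); y = np.array(rows_y); w = np.array(rows_w)
    X = np.column_stack([np.ones_like(t), t])
    A = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ beta
    var = (w * resid**2).sum() / w.sum()
    return beta[0], beta[1], np.sqrt(var)


class TestComponentLoglik:
    def test_single_point_at_mean(self):
        s = make_series("p", [0], [0], regularize=False)
        s.lnvals = np.array([2.0])
        comp = MixtureComponent(2.0, 0.0, 1.0, 1.0)
        assert component_loglik(s, comp) == pytest.approx(-0.9189, abs=1e-4)

    def test_two_points_additivity(self):
        s = make_series("p", [0, 1], [0, 0], regularize=False)
        s.lnvals = np.array([2.0, 2.0])
        comp = MixtureComponent(2.0, 0.0, 1.0, 1.0)
        assert component_loglik(s, comp) == pytest.approx(-1.8379, abs=1e-4)

    def test_matches_pointwise_gaussian_sum(self, toy_cohort):
        comp = MixtureComponent(3.1, -0.12, 0.2, 1.0)
        for s in toy_cohort.series:
            assert component_loglik(s, comp) == pytest.approx(
                brute_loglik(s, comp), abs=1e-10)


class TestEStep:
    def test_k1_posteriors_are_one(self, toy_cohort):
        model = MixtureModel([MixtureComponent(3.0, -0.1, 0.2, 1.0)])
        a = e_step(model, toy_cohort)
        np.testing.assert_allclose(a.posteriors, 1.0, atol=1e-12)

    def test_symmetric_components_split_half(self):
        s = make_series("p", [0, 1, 2], [20, 20, 20])
        cohort = Cohort([s], "MARS")
        y = s.lnvals.mean()
        model = MixtureModel([
            MixtureComponent(y - 0.3, 0.0, 0.2, 0.5),
            MixtureComponent(y + 0.3, 0.0, 0.2, 0.5),
        ])
        # data exactly flat at y: mirrored lines are equidistant
        s.lnvals = np.full(3, y)
        a = e_step(model, cohort)
        np.testing.assert_allclose(a.posteriors[0], [0.5, 0.5], atol=1e-10)

    def test_matches_brute_force(self, toy_cohort, toy_model):
        a = e_step(toy_model, toy_cohort)
        np.testing.assert_allclose(a.posteriors, brute_posteriors(toy_model, toy_cohort),
                                   atol=1e-10)
        assert np.all(np.abs(a.posteriors.sum(axis=1) - 1) < 1e-10)

    def test_labels_are_argmax(self, toy_cohort, toy_model):
        a = e_step(toy_model, toy_cohort)
        np.testing.assert_array_equal(a.labels, np.argmax(a.posteriors, axis=1))


class TestMStep:
    def test_all_mass_recovers_noise_free_line(self):
        t = np.arange(6)
        lnv = 3.0 - 0.1 * t
        series = []
        for i in range(4):
            s = make_series(f"p{i}", t, np.exp(lnv) - 0.5, regularize=False)
            s.lnvals = lnv.copy()
            series.append(s)
        cohort = Cohort(series, "MARS")
        model = m_step(cohort, np.ones((4, 1)))
        assert model.components[0].intercept == pytest.approx(3.0, abs=1e-8)
        assert model.components[0].slope == pytest.approx(-0.1, abs=1e-8)
        assert model.components[0].residual_sd == pytest.approx(1e-4)  # floor

    def test_uniform_posteriors_give_pooled_fit(self, toy_cohort):
        model = m_step(toy_cohort, np.full((5, 2), 0.5))
        c1, c2 = model.components
        assert c1.intercept == pytest.approx(c2.intercept, abs=1e-12)
        assert c1.slope == pytest.approx(c2.slope, abs=1e-12)
        a, b, sd = brute_wls(toy_cohort, np.ones(5))
        assert c1.intercept == pytest.approx(a, abs=1e-10)
        assert c1.slope == pytest.approx(b, abs=1e-10)

    def test_matches_normal_equations_oracle(self, toy_cohort):
        rng = np.random.default_rng(3)
        z = rng.dirichlet(np.ones(2), size=5)
        model = m_step(toy_cohort, z)
        for j, comp in enumerate(model.components):
            a, b, sd = brute_wls(toy_cohort, z[:, j])
            assert comp.intercept == pytest.approx(a, abs=1e-10)
            assert comp.slope == pytest.approx(b, abs=1e-10)
            assert comp.residual_sd == pytest.approx(sd, abs=1e-10)
        np.testing.assert_allclose(model.weights, z.mean(axis=0), atol=1e-12)


class TestFitEM:
    def test_k1_equals_pooled_mle(self, toy_cohort):
        fit = fit_em(toy_cohort, 1, seed=0)
        a, b, sd = brute_wls(toy_cohort, np.ones(5))
        comp = fit.model.components[0]
        assert comp.intercept == pytest.approx(a, abs=1e-8)
        assert comp.slope == pytest.approx(b, abs=1e-8)
        # closed-form Gaussian log-likelihood at the MLE
        n_obs = sum(len(s.weeks) for s in toy_cohort.series)
        expected = -0.5 * n_obs * (np.log(2 * np.pi * sd**2) + 1.0)
        assert fit.diagnostics.loglik == pytest.approx(expected, abs=1e-8)

    def test_separated_clusters_exactly_recovered(self):
        comps = [GeneratingComponent(0.5, 3.2, -0.25, 0.0),
                 GeneratingComponent(0.5, 3.2, -0.01, 0.0)]
        spec = SyntheticSpec(n_patients=60, components=comps, missing_rate=0.0)
        cohort, labels = generate_cohort(spec, seed=5)
        reg = regularize_cohort(cohort)
        rep = fit_restarts(reg, 2, n_restarts=10, seed=1)
        model, a = sort_components(rep.best.model, rep.best.assignments)
        assert np.array_equal(a.labels, labels) or np.array_equal(1 - a.labels, labels)

    def test_loglik_monotone(self, toy_cohort):
        for seed in range(10):
            fit = fit_em(toy_cohort, 2, seed=seed)
            diffs = np.diff(fit.loglik_history)
            assert np.all(diffs >= -1e-9)

    def test_k_exceeding_patients_rejected(self, toy_cohort):
        with pytest.raises(ValueError):
            fit_em(toy_cohort, 6, seed=0)


class TestRestartsAndSelection:
    def test_single_restart_matches_fit_em(self, separated_cohort_7):
        cohort, _, _ = separated_cohort_7
        rep = fit_restarts(cohort, 2, n_restarts=1, seed=3)
        sub = int(np.random.SeedSequence(3).spawn(1)[0].generate_state(1)[0] % 2**31)
        direct = fit_em(cohort, 2, seed=sub)
        assert rep.best.diagnostics.loglik == direct.diagnostics.loglik
        assert rep.best.model.slopes.tolist() == direct.model.slopes.tolist()

    def test_deterministic_across_calls(self, separated_cohort_7):
        cohort, _, _ = separated_cohort_7
        r1 = fit_restarts(cohort, 4, n_restarts=5, seed=11)
        r2 = fit_restarts(cohort, 4, n_restarts=5, seed=11)
        assert r1.best.model.slopes.tolist() == r2.best.model.slopes.tolist()
        assert r1.best.model.intercepts.tolist() == r2.best.model.intercepts.tolist()

    def test_overlarge_k_reports_failures(self, separated_cohort_7):
        cohort, _, _ = separated_cohort_7
        rep = fit_restarts(cohort, 10, n_restarts=10, seed=2)
        assert rep.n_failed > 0

    def test_select_k_single_k(self, toy_cohort):
        sel = select_k(toy_cohort, [2], n_restarts=3, seed=0)
        assert sel.chosen_k == 2

    def test_icl_profile_internally_consistent(self, separated_cohort_7):
        cohort, _, _ = separated_cohort_7
        sel = select_k(cohort, range(2, 6), n_restarts=5, seed=1)
        for k, d in sel.table.items():
            if d is not None:
                assert d.icl == pytest.approx(d.bic + 2 * d.entropy, abs=1e-10)
                assert d.entropy >= 0


class TestInformationCriteria:
    def test_degenerate_posteriors_entropy_zero(self):
        z = np.eye(4)[[0, 1, 0, 1]]
        assert posterior_entropy(z) == 0.0

    def test_uniform_two_patient_entropy(self):
        z = np.full((2, 2), 0.5)
        assert posterior_entropy(z) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_bic_formula(self, toy_cohort):
        fit = fit_em(toy_cohort, 2, seed=0)
        # toy check of the formula with ell = -100, k = 2, N = 50:
        # p = 3k + (k - 1) = 7 free parameters, so BIC = 200 + 7 ln 50
        assert n_free_params(2) == 7
        assert -2 * (-100.0) + n_free_params(2) * np.log(50) == pytest.approx(227.38, abs=0.01)
        d = fit.diagnostics
        assert d.bic == pytest.approx(-2 * d.loglik + d.n_params * np.log(5), abs=1e-10)
        assert d.icl == pytest.approx(d.bic + 2 * d.entropy, abs=1e-10)


class TestSortComponents:
    def _model(self, slopes, intercepts=None):
        intercepts = intercepts or [3.0] * len(slopes)
        k = len(slopes)
        return MixtureModel([MixtureComponent(i, s, 0.1, 1.0 / k)
                             for i, s in zip(intercepts, slopes)])

    def test_ascending_slope_order(self):
        model = sort_components(self._model([-0.1, -0.3, 0.0]))
        assert model.slopes.tolist() == [-0.3, -0.1, 0.0]

    def test_sorted_model_unchanged(self):
        model = self._model([-0.3, -0.1, 0.0])
        assert sort_components(model).slopes.tolist() == [-0.3, -0.1, 0.0]

    def test_slope_tie_broken_by_intercept(self):
        model = sort_components(self._model([-0.1, -0.1], intercepts=[3.0, 2.5]))
        assert model.intercepts.tolist() == [2.5, 3.0]

    def test_permutation_invariance(self, toy_cohort, toy_model):
        a = e_step(toy_model, toy_cohort)
        perm = [1, 0]
        shuffled = MixtureModel([toy_model.components[j] for j in perm])
        az = Assignments(a.patient_ids, a.posteriors[:, perm],
                         np.argmax(a.posteriors[:, perm], axis=1),
                         shuffled.slopes[np.argmax(a.posteriors[:, perm], axis=1)])
        m1, a1 = sort_components(toy_model, a)
        m2, a2 = sort_components(shuffled, az)
        assert m1.slopes.tolist() == m2.slopes.tolist()
        np.testing.assert_array_equal(a1.labels, a2.labels)
        np.testing.assert_allclose(a1.posteriors, a2.posteriors, atol=1e-15)


def match_components(est_slopes, true_slopes):
    """Optimal label matching by slope distance (Hungarian algorithm)."""
    cost = np.abs(np.subtract.outer(est_slopes, true_slopes))
    r, c = linear_sum_assignment(cost)
    return r, c


class TestParameterRecovery:
    def test_recovery_on_separated_cohort(self, separated_cohort_7):
        cohort, labels, spec = separated_cohort_7
        rep = fit_restarts(cohort, 7, n_restarts=40, seed=9)
        model = sort_components(rep.best.model)
        true_slopes = np.array([c.slope for c in spec.components])
        true_intercepts = np.array([c.intercept for c in spec.components])
        r, c = match_components(model.slopes, true_slopes)
        assert np.max(np.abs(model.slopes[r] - true_slopes[c])) < 0.02
        assert np.max(np.abs(model.intercepts[r] - true_intercepts[c])) < 0.05
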