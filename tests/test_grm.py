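"""Graded response model: probabilities, information, MML-EM estimation."""

import math

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

from grmsim import (GeneratorConfig, InestimableItemError, ModelSpec,
                    GradedResponseModel, boundary_probability,
                    category_probabilities, estimate_abilities, fit_grm,
                    fit_matrix, generate_dataset, item_information,
                    marginal_log_likelihood)
from grmsim import test_information as bank_information

D = 1.0  # package-wide scaling constant used throughout the study defaults


# ---------------------------------------------------------------------------
# probability primitives
# ---------------------------------------------------------------------------

class TestBoundaryProbability:
    def test_half_at_location(self):
        assert boundary_probability(2.0, 0.0, 0.0, 1.7) == 0.5

    def test_saturation(self):
        assert boundary_probability(1.0, 0.0, 500.0, 1.7) == 1.0
        assert boundary_probability(1.0, 0.0, -500.0, 1.7) == 0.0

    def test_matches_high_precision_logistic(self):
        # oracle: 50-digit evaluation of 1/(1+exp(-D a (theta-b)))
        a, b, theta, Dv = 2.928, -0.436, 0.5, 1.7
        expr = 1 / (1 + sympy.exp(-sympy.Rational(17, 10)
                                  * sympy.Float(a, 50)
                                  * (sympy.Float(theta, 50) - sympy.Float(b, 50))))
        oracle = float(sympy.N(expr, 50))
        assert boundary_probability(a, b, theta, Dv) == pytest.approx(
            oracle, rel=1e-14)

    @given(st.floats(0.2, 5), st.floats(-2, 2),
           st.floats(-4, 4), st.floats(-4, 4))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_theta(self, a, b, t1, t2):
        lo, hi = sorted((t1, t2))
        assert (boundary_probability(a, b, lo, D)
                <= boundary_probability(a, b, hi, D))


class TestCategoryProbabilities:
    @given(st.floats(0.2, 5), st.floats(-2, 1), st.floats(0.05, 2),
           st.floats(-5, 5))
    @settings(derandomize=True, max_examples=100)
    def test_sum_to_one_and_in_range(self, a, b1, gap, theta):
        p = category_probabilities(a, b1, b1 + gap, theta, D)
        assert p.min() >= 0 and p.max() <= 1
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_item_balance(self):
        p = category_probabilities(2.9, -0.44, 0.44, 0.0, D)
        assert p[0] == pytest.approx(p[2], abs=1e-12)

    def test_cat1_peak_between_thresholds(self):
        # oracle: dense grid search
        grid = np.arange(-4, 4, 1e-3)
        p1 = category_probabilities(2.9, -0.44, 0.45, grid, D)[:, 1]
        peak = grid[np.argmax(p1)]
        assert -0.44 < peak < 0.45

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="b1 < b2"):
            category_probabilities(2.0, 0.5, -0.5, 0.0, D)


class TestInformation:
    def test_vanishes_at_extremes(self):
        assert item_information(2.9, -0.44, 0.45, 40.0, D) == pytest.approx(0, abs=1e-10)
        assert item_information(2.9, -0.44, 0.45, -40.0, D) == pytest.approx(0, abs=1e-10)

    @given(st.floats(0.3, 4), st.floats(-2, 1), st.floats(0.1, 2),
           st.floats(-4, 4))
    @settings(derandomize=True, max_examples=80)
    def test_nonnegative(self, a, b1, gap, theta):
        assert item_information(a, b1, b1 + gap, theta, D) >= 0

    @pytest.mark.parametrize("theta", [-1.0, 0.0, 0.7])
    def test_equals_expected_negative_hessian(self, theta):
        # oracle: I(theta) = sum_c p_c(theta) * (-d^2 log p_c / d theta^2),
        # by central finite differences
        a, b1, b2 = 2.9, -0.44, 0.45
        h = 1e-4
        logp = lambda t: np.log(category_probabilities(a, b1, b2, t, D))
        d2 = (logp(theta + h) - 2 * logp(theta) + logp(theta - h)) / h ** 2
        p = category_probabilities(a, b1, b2, theta, D)
        oracle = float((p * (-d2)).sum())
        ours = float(item_information(a, b1, b2, theta, D))
        assert ours == pytest.approx(oracle, rel=1e-5)

    def test_test_information_additive(self):
        a, b1, b2 = np.array([2.9]), np.array([-0.44]), np.array([0.45])
        single = bank_information(a, b1, b2, 0.3, D)
        assert single == pytest.approx(
            float(item_information(2.9, -0.44, 0.45, 0.3, D)))
        doubled = bank_information(np.repeat(a, 2), np.repeat(b1, 2),
                                   np.repeat(b2, 2), 0.3, D)
        assert doubled == pytest.approx(2 * single)

    def test_tif_peaks_near_zero_on_default_bank(self, default_fit):
        grid = np.arange(-3, 3, 0.01)
        b = default_fit.thresholds_
        tif = bank_information(default_fit.discrimination_, b[:, 0], b[:, 1],
                               grid, default_fit.D)
        assert abs(grid[np.argmax(tif)]) < 0.5


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

class TestMarginalLikelihood:
    def test_flat_item_gives_marginal_frequencies(self):
        # a -> 0+: category probabilities no longer depend on theta, so the
        # per-case likelihood is the (prior-weighted) category probability
        X = np.array([[0], [1], [1], [2]])
        a, b1, b2 = 1e-8, -0.5, 0.5
        ll = marginal_log_likelihood(X, [a], [b1], [b2], ModelSpec())
        p = category_probabilities(a, b1, b2, 0.0, D)
        oracle = sum(math.log(p[x]) for x in (0, 1, 1, 2))
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_matches_dense_trapezoid_integration(self, small_fit_pair):
        matrix, truth, fit2, _ = small_fit_pair
        X = matrix.values[:25]
        p = truth["item_parameters"]
        spec = ModelSpec()
        ours = marginal_log_likelihood(X, p["a"], p["b1"], p["b2"], spec)
        # oracle: direct 1-D integration on a 10x denser grid
        grid = np.linspace(-5, 5, 1001)
        from scipy.stats import norm
        w = norm.pdf(grid)
        w /= w.sum()
        probs = category_probabilities(p["a"].to_numpy()[:, None],
                                       p["b1"].to_numpy()[:, None],
                                       p["b2"].to_numpy()[:, None],
                                       grid[None, :], D)
        oracle = 0.0
        for row in X:
            like = np.ones_like(grid)
            for j, x in enumerate(row):
                like *= probs[j, :, x]
            oracle += np.log((like * w).sum())
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_quadrature_refinement_stable(self, small_fit_pair):
        matrix, truth, _, _ = small_fit_pair
        X = matrix.values[:20, :5]
        p = truth["item_parameters"].iloc[:5]
        lls = [marginal_log_likelihood(X, p["a"], p["b1"], p["b2"],
                                       ModelSpec(n_quadrature=nq))
               for nq in (101, 201, 401)]
        assert abs(lls[1] - lls[0]) / abs(lls[0]) < 1e-6
        assert abs(lls[2] - lls[1]) / abs(lls[1]) < 1e-6

    def test_truth_beats_perturbations_on_large_sample(self):
        cfg = GeneratorConfig(n_cases=2000, n_items=8, ability_scheme="sampled",
                              dependence_pairs=(), seed=13)
        matrix, truth = generate_dataset(cfg)
        p = truth["item_parameters"]
        base = marginal_log_likelihood(matrix.values, p["a"], p["b1"], p["b2"])
        rng = np.random.default_rng(0)
        for _ in range(6):
            da = rng.normal(0, 0.3, len(p))
            db = rng.normal(0, 0.15, len(p))
            pert = marginal_log_likelihood(matrix.values, p["a"] + da,
                                           p["b1"] + db, p["b2"] + db)
            assert pert < base + 2.0  # allow sampling slack near the optimum


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

class TestFit:
    def test_parameter_recovery_large_sample(self):
        cfg = GeneratorConfig(n_cases=2000, n_items=20,
                              difficulty_range=(-1.8, 1.8),
                              ability_scheme="uniform",
                              dependence_pairs=(), seed=17)
        matrix, truth = generate_dataset(cfg)
        fit = fit_matrix(matrix, ModelSpec())
        p = truth["item_parameters"]
        ea = fit.discrimination_ - p["a"].to_numpy()
        eb1 = fit.thresholds_[:, 0] - p["b1"].to_numpy()
        eb2 = fit.thresholds_[:, 1] - p["b2"].to_numpy()
        assert abs(ea.mean()) < 0.1
        assert abs(eb1.mean()) < 0.05
        assert abs(eb2.mean()) < 0.05

    def test_recovery_on_study_defaults(self, default_dataset, default_fit):
        _, truth = default_dataset
        true_mean_a = truth["item_parameters"]["a"].mean()
        assert abs(default_fit.discrimination_.mean() - true_mean_a) < 0.15
        assert abs(default_fit.thresholds_.mean()) < 0.05

    def test_em_loglik_monotone(self, default_fit):
        path = default_fit.loglik_path_
        assert (np.diff(path) >= -1e-6 * np.abs(path[:-1])).all()

    def test_nested_models_loglik(self, small_fit_pair):
        _, _, fit2, fit1 = small_fit_pair
        assert fit1.loglik_ <= fit2.loglik_ + 1e-6

    def test_information_criterion_identities(self, small_fit_pair):
        matrix, _, fit2, fit1 = small_fit_pair
        J, n = matrix.n_items, matrix.n_cases
        assert fit2.n_parameters_ == 3 * J
        assert fit1.n_parameters_ == 2 * J + 1
        for fit in (fit2, fit1):
            assert fit.aic_ == pytest.approx(-2 * fit.loglik_ + 2 * fit.n_parameters_)
            assert fit.bic_ == pytest.approx(
                -2 * fit.loglik_ + fit.n_parameters_ * np.log(n))

    def test_quadrature_refinement_of_fitted_solution(self, default_dataset,
                                                      default_fit):
        matrix, _ = default_dataset
        b = default_fit.thresholds_
        dbl = marginal_log_likelihood(
            matrix.values, default_fit.discrimination_, b[:, 0], b[:, 1],
            ModelSpec(n_quadrature=201))
        assert abs(dbl - default_fit.loglik_) / abs(default_fit.loglik_) < 1e-5

    def test_missing_category_raises_item_diagnostic(self):
        X = np.array([[0, 0], [1, 2], [0, 1], [1, 0]])  # item 1 never shows 2
        with pytest.raises(InestimableItemError, match="item 1"):
            GradedResponseModel().fit(X)

    def test_out_of_range_responses_rejected(self):
        X = np.array([[0, 3], [1, 2], [2, 0]])
        with pytest.raises(ValueError):
            GradedResponseModel().fit(X)

    def test_sklearn_param_interface(self):
        est = GradedResponseModel(model="1pl", D=1.7)
        assert est.get_params()["model"] == "1pl"
        est.set_params(model="2pl")
        assert est.model == "2pl"


class TestAbilities:
    def test_all_ones_on_symmetric_bank_scores_zero(self):
        rng = np.random.default_rng(3)
        n, J = 400, 8
        theta = rng.standard_normal(n)
        a = np.full(J, 2.9)
        b1, b2 = np.full(J, -0.44), np.full(J, 0.44)
        u = rng.uniform(size=(n, J))
        ps1 = boundary_probability(a, b1, theta[:, None], D)
        ps2 = boundary_probability(a, b2, theta[:, None], D)
        X = (u < ps1).astype(int) + (u < ps2).astype(int)
        X[0] = 1  # force an all-ones pattern
        fit = GradedResponseModel().fit(X)
        th, sd = fit.predict_theta(X)
        # a constant-1 pattern on a symmetric bank sits at the centre
        assert abs(th[0]) < 0.1
        assert np.isfinite(th).all() and np.isfinite(sd).all()

    def test_monotone_in_total_score(self, default_dataset, default_fit,
                                     default_theta):
        matrix, _ = default_dataset
        total = matrix.values.sum(axis=1)
        from scipy.stats import spearmanr
        assert spearmanr(total, default_theta).statistic > 0.99
        order = np.argsort(total)
        binned = [default_theta[order][i:i + 30].mean()
                  for i in range(0, len(order) - 30, 30)]
        assert (np.diff(binned) > -0.02).all()

    def test_eap_shrinkage(self, default_theta):
        assert np.std(default_theta, ddof=1) < 1.0

    def test_eap_matches_dense_quadrature(self, default_dataset, default_fit,
                                          default_theta):
        matrix, _ = default_dataset
        fine = GradedResponseModel(n_quadrature=1001)
        fine.discrimination_ = default_fit.discrimination_
        fine.thresholds_ = default_fit.thresholds_
        fine.item_ids_ = default_fit.item_ids_
        from grmsim.grm import _quadrature
        fine._nodes, fine._logw = _quadrature(fine._spec())
        th_fine, _ = fine.predict_theta(matrix.values)
        assert np.abs(th_fine - default_theta).max() < 1e-3

    def test_estimate_abilities_frame(self, default_dataset, default_fit):
        matrix, _ = default_dataset
        df = estimate_abilities(matrix.values, default_fit, matrix.case_ids)
        assert list(df.columns) == ["case_id", "theta_hat", "posterior_sd"]
        assert len(df) == matrix.n_cases
        assert df["posterior_sd"].gt(0).all()
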