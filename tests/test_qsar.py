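import json

import numpy as np
import pytest

from thioqsar.qsar import (
    FitError,
    GAParams,
    ValidationReport,
    coefficient_standard_errors,
    concordance_ccc,
    exhaustive_select,
    external_metrics,
    fit_mlr,
    ga_select,
    loo_q2,
    loo_q2_batch,
    prefilter_descriptors,
    rm2_metrics,
    split_train_test,
    validation_report,
    y_scrambling,
)

from oracles import loo_q2_refits, normal_equations_fit


class TestFitMLR:
    def test_exact_line(self):
        x = np.arange(5.0)
        m = fit_mlr(x[:, None], 2 * x + 1)
        assert m.coefficients[0] == pytest.approx(2.0, abs=1e-10)
        assert m.intercept == pytest.approx(1.0, abs=1e-10)

    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        m = fit_mlr(np.empty((5, 0)), y)
        assert m.intercept == pytest.approx(y.mean())

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            X = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            m = fit_mlr(X, y)
            beta = normal_equations_fit(X, y)
            np.testing.assert_allclose(m.intercept, beta[0], atol=1e-8)
            np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-8)

    def test_residuals_orthogonal_to_columns(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        m = fit_mlr(X, y)
        resid = y - m.predict(X)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_rank_deficiency_names_columns(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(FitError, match="a.*b|collinear"):
            fit_mlr(X, np.random.default_rng(0).normal(size=10), names=["a", "b"])

    def test_zero_variance_column_rejected(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        with pytest.raises(FitError, match="zero-variance"):
            fit_mlr(X, np.arange(8.0), names=["const", "x"])

    def test_standard_errors_match_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 3))
        y = X @ [1.0, -0.5, 0.2] + rng.normal(0, 0.3, 25)
        se = coefficient_standard_errors(X, y)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(se, fit.bse[1:], rtol=1e-8)


class TestLooQ2:
    def test_noiseless_is_one(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 2))
        y = X @ [1.0, 2.0] + 3
        assert loo_q2(X, y) == pytest.approx(1.0, abs=1e-10)

    def test_matches_explicit_refits(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        assert loo_q2(X, y) == pytest.approx(loo_q2_refits(X, y), abs=1e-10)

    def test_pure_noise_typically_negative(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        assert loo_q2(X, y) < 0

    def test_zero_variance_y_errors(self):
        with pytest.raises(FitError, match="variance"):
            loo_q2(np.random.default_rng(0).normal(size=(10, 2)), np.ones(10))

    def test_batch_equals_scalar_path(self):
        rng = np.random.default_rng(21)
        X = rng.poisson(2.0, size=(15, 20)).astype(float)
        y = rng.normal(size=15)
        subsets = [tuple(rng.choice(20, 3, replace=False)) for _ in range(30)]
        batch = loo_q2_batch(X, y, subsets)
        for s, q in zip(subsets, batch):
            assert q == pytest.approx(loo_q2(X[:, s], y), abs=1e-9)


class TestExternalMetrics:
    def _model(self, names=("a",)):
        from thioqsar.qsar import RegressionModel

        return RegressionModel(list(names), np.ones(len(names)), 0.0, 10)

    def test_perfect_predictions(self):
        m = self._model()
        X = np.arange(4.0)[:, None]
        y = m.predict(X)
        out = external_metrics(m, X, y, y_train=np.array([0.0, 1.0, 3.0]))
        for key in ("Q2F1", "Q2F2", "CCC_ex", "k", "k_prime", "R2_ext"):
            assert out[key] == pytest.approx(1.0)
        assert out["RMSE_ex"] == 0 and out["MAE_ex"] == 0

    def test_constant_prediction_at_shared_mean_gives_q2f1_zero(self):
        from thioqsar.qsar import RegressionModel

        y_train = np.array([1.0, 2.0, 3.0])  # mean 2
        m = RegressionModel(["a"], np.array([0.0]), 2.0, 3)
        X_test = np.zeros((4, 1))
        y_test = np.array([1.0, 3.0, 2.5, 1.5])  # mean 2 as well
        out = external_metrics(m, X_test, y_test, y_train)
        assert out["Q2F1"] == pytest.approx(0.0, abs=1e-12)
        assert out["Q2F2"] == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_case(self):
        """All metrics against a hand-computed 3-point arithmetic oracle."""
        from thioqsar.qsar import RegressionModel

        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([1.1, 1.9, 3.2])
        # identity model so predictions == X column
        m = RegressionModel(["a"], np.array([1.0]), 0.0, 5)
        y_train = np.array([1.0, 2.0, 3.0, 4.0])  # mean 2.5, ss 5
        out = external_metrics(m, yhat[:, None], y, y_train)
        press = 0.01 + 0.01 + 0.04
        assert out["PRESS_ex"] == pytest.approx(press)
        assert out["Q2F1"] == pytest.approx(1 - press / (2.25 + 0.25 + 0.25))
        assert out["Q2F2"] == pytest.approx(1 - press / 2.0)
        assert out["Q2F3"] == pytest.approx(1 - (press / 3) / (5.0 / 4))
        assert out["k"] == pytest.approx((1.1 + 3.8 + 9.6) / 14.0)
        assert out["k_prime"] == pytest.approx((1.1 + 3.8 + 9.6) / (1.21 + 3.61 + 10.24))
        assert out["MAE_ex"] == pytest.approx(0.4 / 3)

    def test_zero_test_variance_errors(self):
        m = self._model()
        with pytest.raises(FitError):
            external_metrics(m, np.arange(3.0)[:, None], np.ones(3), np.arange(4.0))

    def test_ccc_penalizes_location_shift(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_ccc(y, y + 1.0) < 1.0
        assert concordance_ccc(y, y) == pytest.approx(1.0)


class TestRm2:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        out = rm2_metrics(y, y)
        assert out["r2m_avg"] == pytest.approx(1.0)
        assert out["r2m_delta"] == pytest.approx(0.0)

    def test_uncorrelated_near_zero(self):
        rng = np.random.default_rng(17)
        out = rm2_metrics(rng.normal(size=50), rng.normal(size=50))
        assert abs(out["r2m_avg"]) < 0.15

    def test_four_point_hand_case(self):
        y_obs = np.array([1.0, 2.0, 3.0, 4.0])
        y_pred = np.array([1.2, 1.8, 3.3, 3.9])

        def hand(y, x):
            r = np.corrcoef(y, x)[0, 1] ** 2
            k = (x * y).sum() / (x * x).sum()
            r0 = 1 - ((y - k * x) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            return r * (1 - np.sqrt(max(r - r0, 0.0)))

        fwd, rev = hand(y_obs, y_pred), hand(y_pred, y_obs)
        out = rm2_metrics(y_obs, y_pred)
        assert out["r2m_avg"] == pytest.approx((fwd + rev) / 2, abs=1e-6)
        assert out["r2m_delta"] == pytest.approx(abs(fwd - rev), abs=1e-6)


class TestYScrambling:
    def test_identity_permutation_equals_unscrambled_r2(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, 0.5, -1.0] + rng.normal(0, 0.1, 20)
        m = fit_mlr(X, y)
        resid = y - m.predict(X)
        r2 = 1 - (resid @ resid) / ((y - y.mean()) ** 2).sum()
        assert y_scrambling(X, y, 1, seed=0, identity_first=True) == pytest.approx(r2)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        assert y_scrambling(X, y, 25, seed=9) == y_scrambling(X, y, 25, seed=9)

    def test_null_mean_matches_chance_level(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(21, 3))
        y = rng.normal(size=21)
        mean_r2 = y_scrambling(X, y, 200, seed=1)
        assert mean_r2 == pytest.approx(3 / 20, abs=0.05)


class TestSplit:
    def test_21_compounds_80_20(self):
        tr, te = split_train_test(21, 0.8, seed=0)
        assert len(tr) == 17 and len(te) == 4

    def test_even_split(self):
        tr, te = split_train_test(10, 0.5, seed=3)
        assert len(tr) == 5 and len(te) == 5

    def test_disjoint_exhaustive_deterministic(self):
        tr1, te1 = split_train_test(21, 0.8, seed=11)
        tr2, te2 = split_train_test(21, 0.8, seed=11)
        np.testing.assert_array_equal(tr1, tr2)
        assert sorted(list(tr1) + list(te1)) == list(range(21))

    def test_degenerate_rejected(self):
        with pytest.raises(FitError):
            split_train_test(3, 0.01, seed=0)


class TestGASelect:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2, size=(12, 1)).astype(float)
        y = 0.5 * X[:, 0] + rng.normal(0, 0.1, 12)
        subset, model, q2 = ga_select(X, y, 1, seed=0)
        assert subset == (0,)

    def test_attains_exhaustive_optimum_small_pool(self):
        rng = np.random.default_rng(33)
        X = rng.poisson(2, size=(15, 8)).astype(float)
        y = X[:, 2] - 0.5 * X[:, 5] + rng.normal(0, 0.2, 15)
        best_exh, q2_exh = exhaustive_select(X, y, 3)
        subset, _, q2 = ga_select(X, y, 3, seed=1, prefilter=False)
        assert q2 == pytest.approx(q2_exh, abs=1e-10)

    def test_too_few_candidates(self):
        X = np.random.default_rng(0).poisson(2, size=(12, 2)).astype(float)
        with pytest.raises(FitError):
            ga_select(X, np.random.default_rng(1).normal(size=12), 3)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(7)
        X = rng.poisson(1.5, size=(14, 30)).astype(float)
        y = X[:, 4] + rng.normal(0, 0.3, 14)
        ga = GAParams(population=20, generations=30)
        a = ga_select(X, y, 2, ga=ga, seed=5)
        b = ga_select(X, y, 2, ga=ga, seed=5)
        assert a[0] == b[0] and a[2] == b[2]

    def test_noise_columns_do_not_help_q2_on_average(self):
        """Adding irrelevant columns never increases Q^2_LOO on average."""
        rng = np.random.default_rng(10)
        diffs = []
        for _ in range(50):
            X = rng.normal(size=(20, 2))
            y = X @ [1.0, -1.0] + rng.normal(0, 0.5, 20)
            noise = rng.normal(size=(20, 2))
            diffs.append(loo_q2(np.column_stack([X, noise]), y) - loo_q2(X, y))
        assert np.mean(diffs) <= 0


class TestPrefilter:
    def test_drops_zero_variance_and_duplicates(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(2, size=(15, 3)).astype(float)
        X = np.column_stack([base, base[:, 0], np.full(15, 7.0)])
        kept = prefilter_descriptors(X)
        assert 4 not in kept  # duplicate of column 0
        assert 3 not in kept or 0 not in kept
        assert 4 not in kept and (X[:, kept].var(axis=0) > 0).all()


class TestValidationReport:
    def _perfect(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(12, 2))
        y = X @ [1.0, 2.0] + 0.5
        return fit_mlr(X, y), X, y

    def test_perfect_data(self):
        m, X, y = self._perfect()
        rep = validation_report(m, X, y, seed=0, n_scrambles=10)
        assert rep.r2_tr == pytest.approx(1.0)
        assert rep.Q2_cv == pytest.approx(1.0, abs=1e-9)
        assert rep.RMSE_tr == pytest.approx(0.0, abs=1e-9)

    def test_internal_consistency(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(18, 3))
        y = X @ [0.5, -1.0, 0.2] + rng.normal(0, 0.4, 18)
        m = fit_mlr(X, y)
        rep = validation_report(m, X, y, X[:4], y[:4], seed=2, n_scrambles=20)
        assert rep.RMSE_tr**2 == pytest.approx(rep.MSE_tr, rel=1e-12)
        assert rep.RMSE_cv**2 == pytest.approx(rep.MSE_cv, rel=1e-12)
        assert rep.RMSE_ex**2 == pytest.approx(rep.MSE_ex, rel=1e-12)
        assert rep.PRESS_cv == pytest.approx(18 * rep.MSE_cv, rel=1e-12)
        assert rep.Q2_cv <= rep.r2_tr
        assert 0 <= rep.r2_tr <= 1

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(16, 2))
        y = X @ [1.0, 1.0] + rng.normal(0, 0.3, 16)
        m = fit_mlr(X, y)
        rep = validation_report(m, X, y, X[:3], y[:3], seed=4, n_scrambles=10)
        path = tmp_path / "report.json"
        rep.to_json(str(path))
        again = ValidationReport.from_json(str(path))
        assert again.to_dict() == pytest.approx(rep.to_dict(), nan_ok=True)

    def test_aic_bic_small_sample_form(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(17, 3))
        y = X @ [1.0, -0.3, 0.6] + rng.normal(0, 0.5, 17)
        m = fit_mlr(X, y)
        rep = validation_report(m, X, y, seed=0, n_scrambles=5)
        n, p = 17, 3
        expected_aic = n * np.log(rep.RSS_tr / n) + 2 * (p + 2)
        expected_bic = n * np.log(rep.RSS_tr / n) + (p + 2) * np.log(n)
        assert rep.AIC == pytest.approx(expected_aic)
        assert rep.BIC == pytest.approx(expected_bic)
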