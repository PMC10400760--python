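"""Elastic-net and neural-net clock correctness: closed-form and
replication-equivalence oracles, KKT conditions, penalty selection,
cross-validation mechanics, and an independent scikit-learn cross-check."""

import numpy as np
import pandas as pd
import pytest

from centiclock import clocks
from centiclock.clocks import (
    AgeStratum,
    ElasticNetClock,
    NeuralNetClock,
    _weighted_design,
    crossvalidate_20fold,
    kkt_violations,
    sample_weights,
    stratified_metrics,
)


class TestSampleWeights:
    def test_centenarian_rule(self):
        w = sample_weights([50, 99.9, 100, 110], 10)
        assert list(w) == [1, 1, 10, 10]

    def test_unit_weight(self):
        assert (sample_weights([50, 105], 1) == 1).all()

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            sample_weights([-1.0], 10)


def _toy_weighted_system():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(6, 2))
    y = 30.0 + 2.0 * X[:, 0] - 1.0 * X[:, 1] + rng.normal(0, 0.1, 6)
    w = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 1.5])
    return X, y, w


class TestElasticNetOracles:
    def test_full_shrinkage_gives_weighted_mean_intercept(self):
        X, y, w = _toy_weighted_system()
        lam = 1e6
        res = ElasticNetClock(X, y, weights=w, lambda_grid=[lam]).fit(lambda_=lam)
        assert (res.coef == 0).all()
        assert res.intercept == pytest.approx(np.average(y, weights=w))
        assert np.allclose(res.predict(X), res.intercept)

    def test_lambda_zero_matches_weighted_normal_equations(self):
        """Unpenalized weighted fit equals the closed-form WLS solution."""
        X, y, w = _toy_weighted_system()
        res = ElasticNetClock(X, y, weights=w, lambda_grid=[0.0],
                              standardize=False, tol=1e-16).fit(lambda_=0.0)
        A = np.column_stack([np.ones(len(y)), X])
        W = np.diag(w)
        coef_ls = np.linalg.solve(A.T @ W @ A, A.T @ W @ y)
        pred_ls = A @ coef_ls
        assert np.abs(res.coef.to_numpy() - coef_ls[1:]).max() < 1e-6
        assert np.abs(res.predict(X) - pred_ls).max() < 1e-6

    def test_weight_ten_equals_tenfold_duplication(self):
        X, y, _ = _toy_weighted_system()
        w = np.ones(6)
        w[2] = 10.0
        lam = 0.05
        res_w = ElasticNetClock(X, y, weights=w,
                                lambda_grid=[lam]).fit(lambda_=lam)
        Xd = np.vstack([X] + [X[2:3]] * 9)
        yd = np.concatenate([y, [y[2]] * 9])
        res_d = ElasticNetClock(Xd, yd, lambda_grid=[lam]).fit(lambda_=lam)
        assert np.abs(res_w.coef.to_numpy() - res_d.coef.to_numpy()).max() < 1e-6
        assert res_w.intercept == pytest.approx(res_d.intercept, abs=1e-6)

    def test_kkt_conditions_exact_on_conditioned_problem(self):
        """At a tight tolerance on a well-conditioned design the stationarity
        conditions hold essentially exactly."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 20))
        y = X[:, 0] * 2 + rng.normal(0, 0.5, 80)
        lam = 0.2
        res = ElasticNetClock(X, y, alpha=0.5, lambda_grid=[lam],
                              tol=1e-14).fit(lambda_=lam)
        Xs, yc, wn, *_ = _weighted_design(X, y, None, True)
        viol = kkt_violations(Xs, yc, wn, 0.5, lam, res.coef.to_numpy())
        assert viol < 1e-6

    def test_kkt_conditions_hold_on_real_fit(self, fitted_weighted_clock,
                                             prefiltered):
        """On the correlated cohort design the violation stays within the
        bound implied by the deviance-scaled stopping rule (a few times
        sqrt(tol * null deviance))."""
        sub, sheet = prefiltered
        res = fitted_weighted_clock
        ages = sheet["age"].to_numpy(float)
        w = sample_weights(ages, 10.0)
        X = sub.to_numpy(float).T
        Xs, yc, wn, *_ = _weighted_design(X, ages, w, True)
        viol = kkt_violations(Xs, yc, wn, res.alpha, res.lambda_,
                              res.coef.to_numpy())
        dev_null = wn @ yc**2
        assert viol < 5.0 * np.sqrt(1e-7 * dev_null)

    def test_matches_sklearn_reference(self):
        """Independent oracle: scikit-learn coordinate descent at a fixed
        penalty on an unstandardized design."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 15))
        y = X[:, 0] * 3 - X[:, 1] + rng.normal(0, 0.5, 80)
        lam = 0.1
        res = ElasticNetClock(X, y, alpha=0.5, standardize=False,
                              lambda_grid=[lam], tol=1e-12).fit(lambda_=lam)
        sk = sklearn.ElasticNet(alpha=lam, l1_ratio=0.5, tol=1e-12,
                                max_iter=500_000).fit(X, y)
        assert np.abs(res.coef.to_numpy() - sk.coef_).max() < 1e-6

    def test_zero_variance_feature_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        with pytest.raises(ValueError, match="zero-variance"):
            ElasticNetClock(X, np.arange(10.0)).fit(lambda_=0.1)


class TestLambdaSelection:
    def test_single_value_grid_returns_it(self):
        X, y, w = _toy_weighted_system()
        lam = clocks.select_lambda_cv(X, y, weights=w, lambda_grid=[0.37])
        assert lam == 0.37

    def test_pure_noise_selects_heavy_shrinkage(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 30))
            y = rng.normal(size=60)
            model = ElasticNetClock(X, y, n_lambdas=30, seed=seed)
            lam, _ = model.select_lambda(n_folds=5)
            Xs, yc, wn, *_ = _weighted_design(X, y, None, True)
            grid = clocks.make_lambda_grid(
                clocks.lambda_max(Xs, yc, wn, 0.5), 30)
            # heavy shrinkage = upper quarter of the penalty grid
            assert lam in grid
            hits += lam >= grid[len(grid) // 4]
        assert hits >= 8

    def test_strong_signal_gives_accurate_oof_predictions(self, prefiltered):
        sub, sheet = prefiltered
        ages = sheet["age"].to_numpy(float)
        model = ElasticNetClock(sub, ages, n_lambdas=50, seed=0)
        res = model.fit(lambda_="cv", cv_folds=5)
        pred = res.predict(sub)
        assert np.corrcoef(pred, ages)[0, 1] > 0.9

    def test_empty_grid_rejected(self):
        X, y, w = _toy_weighted_system()
        with pytest.raises(ValueError, match="empty"):
            ElasticNetClock(X, y, lambda_grid=[])


class TestNeuralNetClock:
    def test_overfits_linear_toy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = 50 + 4 * X[:, 0]
        res = NeuralNetClock(X, y, epochs=2000, seed=0).fit()
        mae = np.mean(np.abs(res.predict(X) - y))
        assert mae < 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        y = rng.normal(60, 10, 15)
        a = NeuralNetClock(X, y, epochs=200, seed=3).fit()
        b = NeuralNetClock(X, y, epochs=200, seed=3).fit()
        assert np.array_equal(a.predict(X), b.predict(X))

    def test_zero_hidden_layers_reduces_to_linear_regression(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = 40 + X @ np.array([3.0, -2.0, 1.0]) + rng.normal(0, 0.3, 50)
        res = NeuralNetClock(X, y, hidden_sizes=(), epochs=5000,
                             learning_rate=0.02, seed=0).fit()
        A = np.column_stack([np.ones(50), X])
        pred_ls = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.abs(res.predict(X) - pred_ls).max() < 0.05


class TestPrediction:
    def test_zero_coefficient_model_predicts_constant(self):
        X, y, w = _toy_weighted_system()
        res = ElasticNetClock(X, y, lambda_grid=[1e6]).fit(lambda_=1e6)
        assert np.allclose(res.predict(X), res.intercept)

    def test_serialization_round_trip(self, tmp_path, fitted_weighted_clock,
                                      prefiltered):
        sub, _ = prefiltered
        res = fitted_weighted_clock
        res.save(tmp_path / "clock")
        loaded = clocks.load_clock(tmp_path / "clock")
        assert np.allclose(res.predict(sub), loaded.predict(sub), atol=1e-10)

    def test_nn_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(0, 1, (5, 30)),
                         index=[f"cg{i}" for i in range(5)])
        y = rng.uniform(40, 100, 30)
        res = NeuralNetClock(X, y, epochs=50, seed=0).fit()
        res.save(tmp_path / "nn")
        loaded = clocks.load_clock(tmp_path / "nn")
        assert np.allclose(res.predict(X), loaded.predict(X), atol=1e-12)

    def test_missing_required_cpg_rejected(self, fitted_weighted_clock,
                                           prefiltered):
        sub, _ = prefiltered
        with pytest.raises(KeyError, match="CpG"):
            fitted_weighted_clock.predict(sub.iloc[:10])

    def test_extra_columns_ignored(self, fitted_weighted_clock, prefiltered):
        sub, _ = prefiltered
        extra = pd.concat([sub, pd.DataFrame(
            np.zeros((3, sub.shape[1])), columns=sub.columns,
            index=["zz1", "zz2", "zz3"])])
        assert np.allclose(fitted_weighted_clock.predict(extra),
                           fitted_weighted_clock.predict(sub))

    def test_unpenalized_training_predictions_match_least_squares(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 3))
        y = 20 + X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.2, 30)
        res = ElasticNetClock(X, y, lambda_grid=[0.0], standardize=False,
                              tol=1e-16).fit(lambda_=0.0)
        A = np.column_stack([np.ones(30), X])
        pred_ls = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert np.abs(res.predict(X) - pred_ls).max() < 1e-6


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, beta):
        return np.full(beta.shape[1], self.value)


class TestCrossValidation:
    def test_fold_sizes_near_equal(self, small_cohort):
        beta, sheet, _, _ = small_cohort
        cv = crossvalidate_20fold(
            lambda b, s, w: _ConstantModel(70.0), beta.iloc[:50], sheet,
            seed=0)
        sizes = cv.fold_assignment.value_counts()
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == len(sheet)

    def test_forty_samples_gives_folds_of_two(self, small_cohort):
        beta, sheet, _, _ = small_cohort
        sheet40 = sheet.iloc[:40].reset_index(drop=True)
        cv = crossvalidate_20fold(lambda b, s, w: _ConstantModel(70.0),
                                  beta[sheet40["sample_id"]], sheet40, seed=1)
        assert (cv.fold_assignment.value_counts() == 2).all()

    def test_constant_predictor_metrics(self, small_cohort):
        beta, sheet, _, _ = small_cohort
        cv = crossvalidate_20fold(lambda b, s, w: _ConstantModel(70.0),
                                  beta, sheet, seed=0)
        ages = sheet.set_index("sample_id")["age"]
        expected_mae = np.median(np.abs(70.0 - ages[cv.oof_prediction.index]))
        row = cv.metrics.set_index("stratum").loc["40plus"]
        assert row["mae_years"] == pytest.approx(expected_mae)
        assert np.isnan(row["pearson_r"])  # zero variance in predictions

    def test_oof_predictions_never_from_own_fold(self, small_cohort):
        beta, sheet, _, _ = small_cohort
        seen = {}

        class Recorder:
            def __init__(self, train_ids):
                self.train_ids = set(train_ids)

            def predict(self, b):
                for sid in b.columns:
                    seen[sid] = sid not in self.train_ids
                return np.zeros(b.shape[1])

        crossvalidate_20fold(lambda b, s, w: Recorder(s["sample_id"]),
                             beta, sheet, seed=0)
        assert all(seen.values()) and len(seen) == len(sheet)


class TestStratifiedMetrics:
    def test_perfect_prediction(self):
        ages = np.array([45.0, 60.0, 85.0, 101.0])
        m = stratified_metrics(ages, ages)
        row = m.set_index("stratum").loc["40plus"]
        assert row["mae_years"] == 0.0 and row["pearson_r"] == pytest.approx(1.0)

    def test_constant_offset(self):
        ages = np.linspace(40, 110, 20)
        m = stratified_metrics(ages + 5.0, ages)
        assert (m["mae_years"] == 5.0).all()
        assert np.allclose(m["pearson_r"], 1.0)

    def test_hand_computed_six_points(self):
        ages = np.array([40.0, 50.0, 60.0, 70.0, 80.0, 90.0])
        pred = np.array([42.0, 49.0, 63.0, 66.0, 85.0, 88.0])
        m = stratified_metrics(pred, ages,
                               [AgeStratum("all", 0.0, 200.0)]).iloc[0]
        diffs = np.abs(pred - ages)  # [2,1,3,4,5,2]
        assert m["mae_years"] == pytest.approx(np.median(diffs))
        r_direct = (((pred - pred.mean()) * (ages - ages.mean())).sum()
                    / np.sqrt(((pred - pred.mean()) ** 2).sum()
                              * ((ages - ages.mean()) ** 2).sum()))
        assert m["pearson_r"] == pytest.approx(r_direct, abs=1e-12)

    def test_empty_stratum_is_nan_not_error(self):
        m = stratified_metrics([50.0, 60.0, 70.0], [50.0, 60.0, 70.0])
        row = m.set_index("stratum").loc["100plus"]
        assert row["n"] == 0 and np.isnan(row["pearson_r"])
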