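"""Splits, MLR/AIC, NIPALS PLSR and the evaluation metrics, checked against
normal-equations and scikit-learn oracles."""

import numpy as np
import pandas as pd
import pytest

from chlorofuse import modeling as mdl
from chlorofuse.errors import (
    DegenerateMetricError,
    SingularDesignError,
    ZeroVarianceError,
)


def _study_table(n=300, seed=0, b=(10.0, 200.0, 1.5, 500.0), noise=5.0):
    """Feature table generated as Chl = b0 + b1*S + b2*DAS + b3*SLW + eps."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "genotype": [f"G{i % 5}" for i in range(n)],
        "water": ["D" if i % 2 else "HW" for i in range(n)],
        "nutrient": ["HN" if (i // 2) % 2 else "LN" for i in range(n)],
        "S": rng.uniform(0.2, 0.8, n),
        "DAS": rng.choice([20, 30, 40, 50, 60], n).astype(float),
        "SLW": rng.uniform(0.003, 0.007, n),
    })
    eps = rng.normal(0, noise, n) if noise > 0 else 0.0
    df["Chl"] = b[0] + b[1] * df["S"] + b[2] * df["DAS"] + b[3] * df["SLW"] + eps
    return df


class TestSplit:
    def test_300_rows_split_240_60_with_4_1_per_stratum(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in range(15):
            for w in ("D", "HW"):
                for nu in ("HN", "LN"):
                    for rep in range(5):
                        rows.append({"genotype": f"G{g:02d}", "water": w,
                                     "nutrient": nu, "Chl": rng.normal()})
        table = pd.DataFrame(rows)
        cal, val = mdl.split_calibration_validation(table, 0.8, seed=1)
        assert len(cal) == 240 and len(val) == 60
        for df, expected in ((cal, 4), (val, 1)):
            counts = df.groupby(["genotype", "water", "nutrient"]).size()
            assert (counts == expected).all()

    def test_frac_one_empties_validation(self):
        table = _study_table(40)
        cal, val = mdl.split_calibration_validation(table, 1.0, seed=0)
        assert len(val) == 0 and len(cal) == 40

    def test_same_seed_same_membership(self):
        table = _study_table(60)
        a = mdl.split_calibration_validation(table, 0.8, seed=9)
        b = mdl.split_calibration_validation(table, 0.8, seed=9)
        assert a[0].index.equals(b[0].index) and a[1].index.equals(b[1].index)

    def test_tiny_stratum_goes_to_calibration_with_warning(self):
        table = _study_table(8)
        table.loc[0, "genotype"] = "LONER"
        with pytest.warns(UserWarning, match="LONER"):
            cal, val = mdl.split_calibration_validation(table, 0.8, seed=0)
        assert 0 in cal.index


class TestMLR:
    def test_noiseless_coefficients_recovered(self):
        table = _study_table(noise=0.0)
        fit = mdl.fit_mlr(table, "S", include_slw=True)
        assert fit.coefficients == pytest.approx([10.0, 200.0, 1.5, 500.0], abs=1e-6)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        table = _study_table(seed=4)
        fit = mdl.fit_mlr(table, "S", include_slw=True)
        X = np.column_stack([np.ones(len(table)), table["S"], table["DAS"], table["SLW"]])
        y = table["Chl"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients == pytest.approx(beta, abs=1e-8)

    def test_permuted_response_has_no_fit(self):
        table = _study_table(seed=5)
        rng = np.random.default_rng(11)
        table["Chl"] = rng.permutation(table["Chl"].to_numpy())
        fit = mdl.fit_mlr(table, "S")
        assert fit.r2 < 0.05

    def test_rank_deficiency_detected(self):
        table = _study_table(30)
        table["S"] = table["DAS"]          # collinear with DAS
        with pytest.raises(SingularDesignError):
            mdl.fit_mlr(table, "S")


class TestAIC:
    def test_equal_rss_penalty_difference_is_two(self):
        assert mdl.gaussian_aic(50.0, 100, 4) - mdl.gaussian_aic(50.0, 100, 3) == 2.0

    def test_closed_form_value(self):
        # n=100, RSS=100 -> n*ln(1) + 2*(3+1) = 8
        assert mdl.gaussian_aic(100.0, 100, 3) == pytest.approx(8.0)

    def test_zero_rss_flagged_degenerate(self):
        assert mdl.gaussian_aic(0.0, 50, 3) == float("-inf")

    def test_adding_slw_lowers_aic_when_generator_uses_slw(self):
        # SLW coefficient scaled so its contribution rivals the other terms
        table = _study_table(seed=8, b=(10.0, 200.0, 1.5, 2e4), noise=10.0)
        without = mdl.fit_mlr(table, "S", include_slw=False)
        with_slw = mdl.fit_mlr(table, "S", include_slw=True)
        assert with_slw.aic < without.aic
        assert with_slw.r2 >= without.r2   # nested models, exact


class TestPLSR:
    def _random_table(self, n=50, p=6, seed=1):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = rng.normal(size=p)
        y = X @ beta + rng.normal(scale=0.1, size=n)
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
        df["Chl"] = y
        return df, [f"x{i}" for i in range(p)]

    def test_full_rank_equals_ols(self):
        df, preds = self._random_table()
        fit = mdl.fit_plsr(df, preds, len(preds))
        X = np.column_stack([np.ones(len(df))] + [df[p] for p in preds])
        beta = np.linalg.solve(X.T @ X, X.T @ df["Chl"].to_numpy())
        assert np.abs(fit.predict(df) - X @ beta).max() < 1e-8

    def test_single_predictor_is_simple_regression(self):
        df, _ = self._random_table(p=1)
        fit = mdl.fit_plsr(df, ["x0"], 1)
        slope, intercept = np.polyfit(df["x0"], df["Chl"], 1)
        assert fit.coefficients[0] == pytest.approx(slope, abs=1e-8)
        assert fit.intercept == pytest.approx(intercept, abs=1e-8)

    def test_matches_sklearn_at_reduced_rank(self):
        from sklearn.cross_decomposition import PLSRegression

        df, preds = self._random_table(seed=6)
        for a in (1, 3, 5):
            fit = mdl.fit_plsr(df, preds, a)
            sk = PLSRegression(n_components=a, scale=True).fit(
                df[preds].to_numpy(), df["Chl"].to_numpy())
            assert np.abs(fit.predict(df) - sk.predict(df[preds].to_numpy()).ravel()).max() < 1e-8

    def test_zero_variance_predictor_named(self):
        df, preds = self._random_table()
        df["x2"] = 3.14
        with pytest.raises(ZeroVarianceError, match="x2"):
            mdl.fit_plsr(df, preds, 2)

    def test_null_response_cv_r2_near_zero(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.normal(size=(200, 6)),
                          columns=[f"x{i}" for i in range(6)])
        df["Chl"] = rng.normal(size=200)
        fit = mdl.cross_validate_plsr(df, [f"x{i}" for i in range(6)], seed=2)
        assert fit.cv_metrics.r2 < 0.05


class TestCrossValidation:
    def test_curve_covers_all_candidates_and_is_deterministic(self):
        table = _study_table(100, seed=2)
        table["S2"] = table["S"] ** 2
        preds = ["S", "S2", "DAS", "SLW"]
        a = mdl.cross_validate_plsr(table, preds, seed=3)
        b = mdl.cross_validate_plsr(table, preds, seed=3)
        assert a.cv_mse.shape == (4,)
        assert np.array_equal(a.cv_mse, b.cv_mse)
        assert a.n_components == b.n_components <= 4

    def test_fused_model_beats_single_channels(self):
        # three channels measuring the same signal with independent noise
        rng = np.random.default_rng(17)
        n = 300
        signal = rng.normal(size=n)
        df = pd.DataFrame({
            f"ch{i}": signal + rng.normal(scale=0.6, size=n) for i in range(3)
        })
        df["Chl"] = 100.0 + 50.0 * signal + rng.normal(scale=5.0, size=n)
        fused = mdl.cross_validate_plsr(df, ["ch0", "ch1", "ch2"], seed=1)
        singles = [mdl.cross_validate_plsr(df, [c], seed=1).cv_metrics.r2
                   for c in ("ch0", "ch1", "ch2")]
        assert fused.cv_metrics.r2 >= max(singles)


class TestImportance:
    def test_absolute_value_sort(self):
        fit = mdl.PLSRFit(
            predictors=["a", "b", "c"], n_components=1,
            x_mean=np.zeros(3), x_std=np.ones(3), y_mean=0.0,
            coefficients=np.array([2.0, -3.0, 1.0]), intercept=0.0,
            std_coefficients=np.array([2.0, -3.0, 1.0]))
        assert mdl.importance_ranking(fit) == ["b", "a", "c"]

    def test_singleton_ranking(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0], "Chl": [1.0, 2.0, 2.9, 4.2]})
        fit = mdl.fit_plsr(df, ["x"], 1)
        assert fit.importance == ["x"]

    def test_uninformative_hue_ranks_last_and_is_droppable(self):
        rng = np.random.default_rng(31)
        n = 1000
        signal = rng.normal(size=n)
        data = {f"f{i}": signal + rng.normal(scale=0.5, size=n) for i in range(9)}
        data["H"] = rng.normal(size=n)           # carries no signal
        df = pd.DataFrame(data)
        df["Chl"] = 200.0 + 80.0 * signal + rng.normal(scale=8.0, size=n)
        preds = list(data)
        fit = mdl.cross_validate_plsr(df, preds, seed=4)
        assert fit.importance[-1] == "H"
        reduced = mdl.cross_validate_plsr(df, [p for p in preds if p != "H"], seed=4)
        assert abs(fit.cv_metrics.r2 - reduced.cv_metrics.r2) < 0.01


class TestEvaluate:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = mdl.evaluate(y, y)
        assert m.r2 == pytest.approx(1.0) and m.rmse == 0.0 and np.isinf(m.rpd)

    def test_hand_computed_rmse(self):
        m = mdl.evaluate(np.array([0.0, 2.0]), np.array([1.0, 1.0]))
        assert m.rmse == pytest.approx(1.0)

    def test_rpd_times_rmse_is_sd(self, rng):
        y = rng.normal(size=100) * 150.0
        yhat = y + rng.normal(size=100) * 50.0
        m = mdl.evaluate(y, yhat)
        assert m.rpd * m.rmse == pytest.approx(m.sd, abs=1e-12)
        assert m.sd == pytest.approx(np.std(y, ddof=1))

    def test_r2_invariant_to_affine_prediction_rescale(self, rng):
        y = rng.normal(size=80)
        yhat = y + rng.normal(scale=0.3, size=80)
        a = mdl.evaluate(y, yhat).r2
        b = mdl.evaluate(y, 3.0 * yhat + 7.0).r2
        assert a == pytest.approx(b, abs=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(DegenerateMetricError):
            mdl.evaluate(np.ones(5), np.arange(5.0))


def test_coefficient_recovery_within_three_se():
    """Coefficients of the SLW generator lie within 3 SE of truth in at
    least 95 % of seeded replicates."""
    truth = np.array([10.0, 200.0, 1.5, 500.0])
    hits = 0
    n_rep = 50
    for rep in range(n_rep):
        table = _study_table(seed=1000 + rep, noise=20.0)
        fit = mdl.fit_mlr(table, "S", include_slw=True)
        X = np.column_stack([np.ones(len(table)), table["S"], table["DAS"], table["SLW"]])
        sigma2 = fit.rss / (len(table) - X.shape[1])
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        if np.all(np.abs(fit.coefficients - truth) <= 3 * se):
            hits += 1
    assert hits / n_rep >= 0.95
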