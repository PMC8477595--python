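import math

import numpy as np
import pandas as pd
import pytest

from rdnaclock import clock, methylation, screen
from rdnaclock.clock import (
    ClockModel,
    fit_final,
    loocv,
    loocv_ols,
    make_lambda_grid,
    precision_sd,
    predict_age,
    reduced_model,
    sex_effects,
    tune,
)


def matrix_from_array(values, prefix="18S"):
    n_s, n_l = values.shape
    ids = [f"{prefix}_{i + 1}" for i in range(n_l)]
    frame = pd.DataFrame(values, index=[f"s{i}" for i in range(n_s)], columns=ids)
    meta = pd.DataFrame(
        {"region": [prefix] * n_l, "position": list(range(1, n_l + 1))},
        index=pd.Index(ids, name="locus_id"),
    )
    return methylation.MethylationMatrix(values=frame, loci=meta)


def ols_coefficients(X, y):
    """Normal-equations oracle with intercept, on standardized X."""
    Xs = (X - X.mean(0)) / X.std(0)
    design = np.column_stack([np.ones(len(X)), Xs])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta  # [intercept, coefs...]


@pytest.fixture
def toy(rng):
    """10 samples x 3 loci with a clean linear signal (n > p)."""
    X = rng.uniform(20, 80, size=(10, 3))
    y = 2.0 + 0.3 * X[:, 0] - 0.1 * X[:, 1] + rng.normal(0, 0.1, 10)
    return matrix_from_array(X), pd.Series(y, index=[f"s{i}" for i in range(10)])


class TestLambdaGrid:
    def test_endpoints_and_length(self):
        grid = make_lambda_grid()
        assert grid[0] == pytest.approx(1e-3)
        assert grid[-1] == pytest.approx(1e3)
        assert len(grid) == 100
        assert np.all(np.diff(grid) > 0)

    def test_log_uniform_spacing(self):
        ratios = np.diff(np.log10(make_lambda_grid()))
        np.testing.assert_allclose(ratios, ratios[0])


class TestTune:
    def test_huge_lambda_predicts_training_mean(self, toy):
        matrix, y = toy
        model = fit_final(matrix, y, alpha=0.5, lambda_=1e9)
        assert model.n_loci_selected == 0
        preds = predict_age(model, matrix)
        np.testing.assert_allclose(preds, y.mean())

    def test_lambda_zero_matches_ols_oracle(self, toy):
        matrix, y = toy
        model = fit_final(matrix, y, alpha=0.5, lambda_=0.0)
        beta = ols_coefficients(matrix.values.to_numpy(), y.to_numpy())
        assert model.intercept == pytest.approx(beta[0], abs=1e-6)
        for i, locus in enumerate(matrix.locus_ids):
            assert model.coefficients[locus] == pytest.approx(beta[i + 1], abs=1e-6)

    def test_deterministic_given_seed(self, toy):
        matrix, y = toy
        a = tune(matrix, y, 0.5, folds=5, seed=3)
        b = tune(matrix, y, 0.5, folds=5, seed=3)
        assert a.lambda_best == b.lambda_best
        pd.testing.assert_frame_equal(a.cv_table, b.cv_table)

    def test_too_few_samples_rejected(self, toy):
        matrix, y = toy
        with pytest.raises(ValueError):
            tune(matrix, y, 0.5, folds=20)

    def test_constant_ages_rejected(self, toy):
        matrix, _ = toy
        with pytest.raises(ValueError, match="constant"):
            tune(matrix, pd.Series(5.0, index=matrix.values.index), 0.5, folds=5)

    def test_training_error_nondecreasing_in_lambda(self, rng):
        # fit error on the training data grows with the penalty
        X = rng.normal(50, 10, size=(30, 8))
        y = X[:, 0] * 0.5 + rng.normal(0, 1, 30)
        matrix = matrix_from_array(X)
        yser = pd.Series(y, index=matrix.values.index)
        grid = np.logspace(-3, 3, 25)
        rmse = []
        for lam in grid:
            model = fit_final(matrix, yser, alpha=0.5, lambda_=lam, tol=1e-8)
            rmse.append(model.training_metrics["rmse"])
        assert all(b >= a - 1e-6 for a, b in zip(rmse, rmse[1:]))

    def test_elastic_net_objective_beats_ols_and_zero(self, toy):
        matrix, y = toy
        lam, alpha = 0.5, 0.5
        model = fit_final(matrix, y, alpha=alpha, lambda_=lam, tol=1e-10)
        X = matrix.values.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y.to_numpy() - y.mean()

        def objective(beta):
            resid = yc - Xs @ beta
            return (
                0.5 * np.mean(resid**2)
                + lam * ((1 - alpha) / 2 * np.sum(beta**2) + alpha * np.sum(np.abs(beta)))
            )

        beta_hat = np.array([model.coefficients.get(l, 0.0) for l in matrix.locus_ids])
        beta_ols = ols_coefficients(X, y.to_numpy())[1:]
        assert objective(beta_hat) <= objective(beta_ols) + 1e-10
        assert objective(beta_hat) <= objective(np.zeros(3)) + 1e-10


class TestFitFinal:
    def test_ridge_keeps_all_loci(self, toy):
        matrix, y = toy
        model = fit_final(matrix, y, alpha=0.0, lambda_=1.0)
        assert model.n_loci_selected == len(matrix.locus_ids)

    def test_sparse_recovery(self):
        # 15 informative of 100 in the cohort design: at an adequate penalty
        # the selection covers most true loci with few false picks
        from rdnaclock import simdata

        cfg = simdata.SimulationConfig(
            n_loci=100, frac_informative=0.15, n_wild=0, missing_rate=0.0,
            sd_individual=2.0, slope_range=(0.5, 1.2), seed=0,
        )
        panel, sheet, table, _ = simdata.simulate_dataset(cfg)
        matrix, _ = methylation.apply_qc(table)
        ages = sheet["age_months"].astype(float)
        model = fit_final(matrix, ages, alpha=0.5, lambda_=1.0, tol=1e-5)
        true_ids = {s.locus_id for s in panel if s.slope_b != 0}
        selected = set(model.loci)
        assert len(selected & true_ids) >= 8  # majority of the 15
        assert len(selected - true_ids) <= 10

    def test_duplicate_columns_grouping_property(self, rng):
        # lasso: duplicating every column leaves the fitted values unchanged
        # (the fit is strictly convex in X @ beta and the L1 norm is
        # split-invariant); elastic net additionally splits the weight
        # equally across the duplicates
        X = rng.uniform(20, 80, size=(25, 4))
        y = 0.4 * X[:, 0] - 0.2 * X[:, 2] + rng.normal(0, 0.5, 25)
        m1 = matrix_from_array(X)
        m2 = matrix_from_array(np.hstack([X, X]))
        y1 = pd.Series(y, index=m1.values.index)
        model1 = fit_final(m1, y1, alpha=1.0, lambda_=0.1, tol=1e-12)
        model2 = fit_final(m2, y1, alpha=1.0, lambda_=0.1, tol=1e-12)
        p1 = predict_age(model1, m1)
        p2 = predict_age(model2, m2)
        np.testing.assert_allclose(p1, p2, atol=1e-5)

        enet = fit_final(m2, y1, alpha=0.5, lambda_=0.1, tol=1e-12)
        for j in range(4):
            a = enet.coefficients.get(f"18S_{j + 1}", 0.0)
            b = enet.coefficients.get(f"18S_{j + 5}", 0.0)
            assert a == pytest.approx(b, abs=1e-5)

    def test_empty_matrix_rejected(self):
        empty = matrix_from_array(np.empty((0, 0)))
        with pytest.raises(ValueError):
            fit_final(empty, pd.Series(dtype=float), lambda_=1.0)


class TestPredictAge:
    def test_arithmetic_example(self):
        model = ClockModel(
            alpha=0.5, lambda_=1.0, intercept=5.0,
            coefficients={"18S_1": 0.5},
            standardization={"18S_1": (20.0, 10.0)},
        )
        matrix = matrix_from_array(np.array([[40.0]]))
        assert predict_age(model, matrix).iloc[0] == pytest.approx(6.0)

    def test_missing_locus_listed_in_error(self):
        model = ClockModel(
            alpha=0.5, lambda_=1.0, intercept=5.0,
            coefficients={"28S_99": 0.5},
            standardization={"28S_99": (20.0, 10.0)},
        )
        matrix = matrix_from_array(np.array([[40.0]]))
        with pytest.raises(KeyError, match="28S_99"):
            predict_age(model, matrix)

    def test_self_consistency_with_training_metrics(self, toy):
        matrix, y = toy
        model = fit_final(matrix, y, alpha=0.5, lambda_=0.01)
        preds = predict_age(model, matrix)
        _, _, r2p, _ = clock._metrics(y.to_numpy(), preds.to_numpy())
        assert r2p == pytest.approx(model.training_metrics["r2_pearson"], abs=1e-12)

    def test_serialization_round_trip(self, toy, tmp_path):
        matrix, y = toy
        model = fit_final(matrix, y, alpha=0.5, lambda_=0.01)
        path = tmp_path / "model.json"
        model.to_json(path)
        reloaded = ClockModel.from_json(path)
        np.testing.assert_allclose(
            predict_age(model, matrix), predict_age(reloaded, matrix), atol=1e-12
        )

    def test_negative_predictions_not_clamped(self):
        model = ClockModel(
            alpha=0.5, lambda_=1.0, intercept=0.0,
            coefficients={"18S_1": -5.0},
            standardization={"18S_1": (0.0, 1.0)},
        )
        matrix = matrix_from_array(np.array([[10.0]]))
        assert predict_age(model, matrix).iloc[0] == pytest.approx(-50.0)


class TestPrecisionSD:
    def test_simple_case(self):
        assert precision_sd([10, 20], [11, 19]) == pytest.approx(math.sqrt(2))

    def test_identical_vectors(self):
        assert precision_sd([5, 6, 7], [5, 6, 7]) == 0.0

    def test_constant_offset_is_bias_blind(self):
        assert precision_sd([10, 20, 30], [8, 18, 28]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            precision_sd([1, 2], [1, 2, 3])


class TestLOOCV:
    def test_perfect_linear_signal_recovered(self, rng):
        # single noiseless locus, tiny n: all held-out errors < 0.5 months
        ages = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        X = (10.0 + 1.5 * ages)[:, None]
        matrix = matrix_from_array(X)
        y = pd.Series(ages, index=matrix.values.index)
        report = loocv(matrix, y, alpha=0.5, folds=3, seed=0, tol=1e-10)
        assert report.table["difference"].abs().max() < 0.5

    def test_each_training_set_excludes_held_out_sample(self, toy):
        matrix, y = toy
        report = loocv(matrix, y.iloc[:5].reindex(matrix.values.index[:5]),
                       alpha=0.5, folds=3, seed=0) if False else loocv(
            matrix_from_array(matrix.values.to_numpy()[:5]),
            pd.Series(y.to_numpy()[:5], index=[f"s{i}" for i in range(5)]),
            alpha=0.5, folds=3, seed=0,
        )
        assert len(report.table) == 5
        for sample, train_ids in zip(report.table.index, report.training_ids):
            assert sample not in train_ids
            assert len(train_ids) == 4

    def test_prediction_invariant_to_sample_order(self, rng):
        X = rng.uniform(20, 80, size=(8, 2))
        y = 0.5 * X[:, 0] + rng.normal(0, 0.2, 8)
        matrix = matrix_from_array(X)
        yser = pd.Series(y, index=matrix.values.index)
        rep1 = loocv(matrix, yser, alpha=0.5, folds=4, seed=0)
        perm = list(matrix.values.index[::-1])
        matrix2 = methylation.MethylationMatrix(
            values=matrix.values.loc[perm], loci=matrix.loci
        )
        rep2 = loocv(matrix2, yser.loc[perm], alpha=0.5, folds=4, seed=0)
        s0 = matrix.values.index[0]
        assert rep1.table.at[s0, "predicted"] == pytest.approx(
            rep2.table.at[s0, "predicted"], abs=1e-9
        )

    def test_intercept_only_equals_loo_mean_oracle(self, rng):
        # lambda so large that every model is intercept-only: held-out
        # prediction must equal the leave-one-out training mean
        X = rng.uniform(20, 80, size=(9, 3))
        y = rng.uniform(0, 50, 9)
        matrix = matrix_from_array(X)
        yser = pd.Series(y, index=matrix.values.index)
        report = loocv(matrix, yser, alpha=0.5, lambdas=np.array([1e9]), folds=3, seed=0)
        n = len(y)
        for i, sample in enumerate(matrix.values.index):
            loo_mean = (y.sum() - y[i]) / (n - 1)
            assert report.table.at[sample, "predicted"] == pytest.approx(loo_mean, abs=1e-9)

    def test_cohort_anova_and_tukey_produced(self, tiny_matrix):
        matrix, ages, sheet = tiny_matrix
        report = loocv(
            matrix, ages, alpha=0.5, folds=5, seed=0, tol=1e-3,
            cohorts=sheet.loc[matrix.values.index, "cohort"],
        )
        assert report.anova is not None and "F" in report.anova
        assert report.per_cohort_mean_difference is not None
        assert report.tukey is not None


class TestCompareModels:
    def test_sparse_truth_favours_sparse_models(self, rng):
        n = 60
        X = rng.uniform(20, 80, size=(n, 40))
        beta = np.zeros(40)
        beta[:8] = rng.uniform(0.3, 0.8, 8) * rng.choice([-1, 1], 8)
        y = X @ beta + rng.normal(0, 1.0, n)
        matrix = matrix_from_array(X)
        yser = pd.Series(y, index=matrix.values.index)
        comp = clock.compare_models(matrix, yser, folds=5, seed=0, tol=1e-3)
        table = comp.table.set_index("alpha")
        assert table.at[0.5, "median_mae"] < table.at[0.0, "median_mae"]
        assert table.at[1.0, "median_mae"] < table.at[0.0, "median_mae"]
        assert table.at[0.0, "n_loci"] == 40  # ridge never zeroes out
        assert comp.chosen_alpha in (0.5, 1.0)

    def test_pure_noise_panel_near_zero_r2(self, rng):
        X = rng.uniform(20, 80, size=(40, 10))
        y = rng.uniform(0, 50, 40)
        matrix = matrix_from_array(X)
        yser = pd.Series(y, index=matrix.values.index)
        comp = clock.compare_models(matrix, yser, folds=5, seed=0, tol=1e-3)
        assert (comp.table["mean_r2"] < 0.3).all()


class TestReducedModel:
    def _screen_frame(self, matrix, ages):
        frame, _ = screen.screen_all(matrix, ages)
        return frame

    def test_recovers_informative_loci(self, rng):
        ages = np.linspace(0, 51, 60)
        X = 50.0 + rng.normal(0, 0.5, size=(60, 30))
        informative = list(range(15))
        for j in informative:
            X[:, j] = 20 + (0.5 + 0.05 * j) * ages + rng.normal(0, 0.5, 60)
        matrix = matrix_from_array(X)
        yser = pd.Series(ages, index=matrix.values.index)
        frame = self._screen_frame(matrix, yser)
        selected = [f"18S_{j + 1}" for j in range(30)]
        model = reduced_model(matrix, yser, frame, selected, k=15)
        chosen = {int(l.split("_")[1]) - 1 for l in model.loci}
        assert chosen == set(informative)

    def test_k_exceeding_selection_rejected(self, toy):
        matrix, y = toy
        frame = self._screen_frame(matrix, y)
        with pytest.raises(ValueError):
            reduced_model(matrix, y, frame, matrix.locus_ids, k=10)

    def test_k1_equals_single_locus_regression(self, rng):
        ages = np.linspace(0, 50, 20)
        X = np.column_stack([10 + 2 * ages + rng.normal(0, 0.5, 20),
                             50 + rng.normal(0, 0.5, 20)])
        matrix = matrix_from_array(X)
        yser = pd.Series(ages, index=matrix.values.index)
        frame = self._screen_frame(matrix, yser)
        model = reduced_model(matrix, yser, frame, matrix.locus_ids, k=1)
        assert model.loci == ["18S_1"]
        from scipy import stats as sps
        lin = sps.linregress(X[:, 0], ages)
        preds = predict_age(model, matrix)
        np.testing.assert_allclose(preds, lin.intercept + lin.slope * X[:, 0], atol=1e-8)

    def test_full_ols_beats_penalized_training_mae(self, toy):
        matrix, y = toy
        frame = self._screen_frame(matrix, y)
        penalized = fit_final(matrix, y, alpha=0.5, lambda_=1.0)
        full_ols = reduced_model(matrix, y, frame, matrix.locus_ids, k=len(matrix.locus_ids))
        assert full_ols.training_metrics["mae"] <= penalized.training_metrics["mae"] + 1e-9


class TestSexEffects:
    def test_deterministic_shift_detected(self, rng):
        # females = males + 5% at every locus -> all signs positive, ANOVA hits
        n_per, n_loci = 8, 10
        base = rng.uniform(30, 60, size=n_loci)
        rows, sexes = [], []
        for i in range(2 * n_per):
            female = i < n_per
            noise = rng.normal(0, 0.3, n_loci)
            rows.append(base + (5.0 if female else 0.0) + noise)
            sexes.append("F" if female else "M")
        matrix = matrix_from_array(np.array(rows))
        sheet = pd.DataFrame(
            {"sex": sexes, "cohort": ["c1"] * 2 * n_per}, index=matrix.values.index
        )
        model = ClockModel(
            alpha=0.5, lambda_=1.0, intercept=10.0,
            coefficients={l: 1.0 for l in matrix.locus_ids},
            standardization={l: (45.0, 10.0) for l in matrix.locus_ids},
        )
        report = sex_effects(matrix, sheet, model, cohorts=["c1"])
        assert report.sign_counts["c1"] == (n_loci, n_loci)
        assert report.anova is not None and report.anova["p"] < 0.01

    def test_single_sex_cohort_skipped_with_warning(self, rng):
        matrix = matrix_from_array(rng.uniform(30, 60, size=(4, 3)))
        sheet = pd.DataFrame(
            {"sex": ["F"] * 4, "cohort": ["c1"] * 4}, index=matrix.values.index
        )
        model = ClockModel(
            alpha=0.5, lambda_=1.0, intercept=10.0,
            coefficients={l: 1.0 for l in matrix.locus_ids},
            standardization={l: (45.0, 10.0) for l in matrix.locus_ids},
        )
        with pytest.warns(UserWarning, match="skipped"):
            report = sex_effects(matrix, sheet, model, cohorts=["c1"])
        assert report.skipped_cohorts == ["c1"]
        assert report.anova is None


class TestLoocvOLS:
    def test_protocol_and_training_exclusion(self, rng):
        X = rng.uniform(20, 80, size=(6, 2))
        y = 0.5 * X[:, 0] + rng.normal(0, 0.2, 6)
        matrix = matrix_from_array(X)
        yser = pd.Series(y, index=matrix.values.index)
        report = loocv_ols(matrix, yser, matrix.locus_ids)
        assert len(report.table) == 6
        for sample, train_ids in zip(report.table.index, report.training_ids):
            assert sample not in train_ids
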