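"""Split contract, classifiers, PLSR vs OLS oracle, metrics, results grid."""

import numpy as np
import pytest

from seedvigor import (
    SimConfig,
    SpectralDataset,
    SplitSpec,
    evaluate_classifier,
    evaluate_regression,
    generate_spectra,
    plsr_fit,
    run_grid,
    split_dataset,
    train_classifier,
    train_regressor,
)
from seedvigor.models import CLASSIFIER_ALGORITHMS


def _labelled_dataset(n=400, seed=0):
    ds, _ = generate_spectra(SimConfig(n_per_group=n // 5, rng_seed=seed))
    return ds


class TestSplit:
    def test_400_seeds_split_280_120(self):
        ds = _labelled_dataset(400)
        cal, pred = split_dataset(ds, SplitSpec(rng_seed=0))
        assert cal.n_seeds == 280
        assert pred.n_seeds == 120

    def test_deterministic_membership(self):
        ds = _labelled_dataset(200)
        a_cal, _ = split_dataset(ds, SplitSpec(rng_seed=5))
        b_cal, _ = split_dataset(ds, SplitSpec(rng_seed=5))
        np.testing.assert_array_equal(a_cal.seed_id, b_cal.seed_id)

    def test_disjoint_and_exhaustive(self):
        ds = _labelled_dataset(200)
        cal, pred = split_dataset(ds, SplitSpec(rng_seed=1))
        ids = set(cal.seed_id) | set(pred.seed_id)
        assert len(set(cal.seed_id) & set(pred.seed_id)) == 0
        assert ids == set(ds.seed_id)

    def test_stratification_within_one_sample(self, rng):
        # 60/40 label mix: each part's class counts within 1 of proportional
        n = 200
        labels = np.array([True] * 120 + [False] * 80)
        ds = SpectralDataset(
            spectra=rng.standard_normal((n, 8)),
            wavelengths=np.arange(8, dtype=float),
            group=np.repeat(["A0"], n),
            viable=labels,
            sod=np.zeros(n),
        )
        cal, pred = split_dataset(ds, SplitSpec(rng_seed=2))
        assert abs(cal.viable.sum() - 0.6 * cal.n_seeds) <= 1
        assert abs(pred.viable.sum() - 0.6 * pred.n_seeds) <= 1

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(ratio=1.0)


class TestClassifiers:
    @pytest.mark.parametrize("algorithm", CLASSIFIER_ALGORITHMS)
    def test_separable_toy_set_is_learned_perfectly(self, rng, algorithm):
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 2)) * 0.1
        X[:, 0] += 5.0 * y  # wide margin on the first band
        model = train_classifier(X, y, algorithm, seed=0)
        rep = evaluate_classifier(model, X, y)
        assert rep.prediction["accuracy"] == 100.0

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        ds = _labelled_dataset(300, seed=2)
        y = rng.permutation(ds.viable.astype(int))
        cal_idx, pred_idx = np.arange(0, 200), np.arange(200, 300)
        model = train_classifier(ds.spectra[cal_idx], y[cal_idx], "xgboost", seed=0)
        rep = evaluate_classifier(model, ds.spectra[pred_idx], y[pred_idx])
        majority = max(y[pred_idx].mean(), 1 - y[pred_idx].mean())
        band = 100 * 3.0 * np.sqrt(0.25 / len(pred_idx))
        assert rep.prediction["accuracy"] <= 100 * majority + band

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(rng.standard_normal((10, 3)), np.ones(10), "xgboost")

    def test_unknown_algorithm_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            train_classifier(rng.standard_normal((10, 3)),
                             np.repeat([0, 1], 5), "catboost!")


class TestEvaluateClassifier:
    class _Fixed:
        def __init__(self, out):
            self.out = np.asarray(out)

        def predict(self, X):
            return self.out

    def test_255_of_280_gives_9107(self):
        y = np.zeros(280, dtype=int)
        pred = y.copy()
        pred[:25] = 1  # 25 mistakes
        rep = evaluate_classifier(self._Fixed(pred), np.zeros((280, 1)), y)
        assert rep.prediction["accuracy"] == 91.07
        assert rep.prediction["n_correct"] == 255

    def test_all_correct_diagonal_matrix(self):
        y = np.array([0, 0, 1, 1])
        rep = evaluate_classifier(self._Fixed(y), np.zeros((4, 1)), y)
        assert rep.prediction["accuracy"] == 100.0
        np.testing.assert_array_equal(
            rep.confusion_prediction, np.array([[2, 0], [0, 2]])
        )

    def test_all_wrong_zero_accuracy(self):
        y = np.array([0, 0, 1, 1])
        rep = evaluate_classifier(self._Fixed(1 - y), np.zeros((4, 1)), y)
        assert rep.prediction["accuracy"] == 0.0
        assert np.trace(rep.confusion_prediction) == 0

    def test_confusion_total_equals_set_size(self, rng):
        y = rng.integers(0, 2, 37)
        rep = evaluate_classifier(self._Fixed(rng.integers(0, 2, 37)),
                                  np.zeros((37, 1)), y)
        assert rep.confusion_prediction.sum() == 37


class TestPLSR:
    def test_one_component_univariate_equals_simple_regression(self, rng):
        x = rng.uniform(0, 1, 30)
        y = 2.0 * x + 0.5 + 0.05 * rng.standard_normal(30)
        model = plsr_fit(x[:, None], y, n_components=1)
        # closed-form simple regression oracle
        slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        intercept = y.mean() - slope * x.mean()
        np.testing.assert_allclose(
            model.predict(x[:, None]), slope * x + intercept, atol=1e-8
        )

    def test_full_rank_equals_ols(self, rng):
        n, p = 40, 6
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + 0.1 * rng.standard_normal(n)
        model = plsr_fit(X, y, n_components=p)
        # normal-equations oracle on centered data
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols_pred = Xc @ beta + y.mean()
        np.testing.assert_allclose(model.predict(X), ols_pred, atol=1e-8)

    def test_constant_target_predicts_constant(self, rng):
        X = rng.standard_normal((20, 5))
        model = plsr_fit(X, np.full(20, 3.3))
        np.testing.assert_allclose(model.predict(X), 3.3, atol=1e-10)

    def test_cv_component_choice_bounded(self, rng):
        X = rng.standard_normal((30, 50))
        y = X[:, 0] + 0.1 * rng.standard_normal(30)
        model = plsr_fit(X, y, max_components=15, seed=0)
        assert 1 <= model.n_components <= 15

    def test_zero_variance_X_rejected(self):
        with pytest.raises(ValueError):
            plsr_fit(np.ones((10, 3)), np.arange(10.0), n_components=1)

    def test_latent_structure_exposed(self, rng):
        X = rng.standard_normal((25, 8))
        y = X @ rng.standard_normal(8)
        model = plsr_fit(X, y, n_components=3)
        assert model.x_scores_.shape == (25, 3)
        assert model.x_loadings_.shape == (8, 3)
        assert model.coef_.shape == (8,)


class TestEvaluateRegression:
    class _Fixed:
        def __init__(self, out):
            self.out = np.asarray(out)

        def predict(self, X):
            return self.out

    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = evaluate_regression(self._Fixed(y), np.zeros((3, 1)), y)
        assert rep.prediction["r2"] == pytest.approx(1.0)
        assert rep.prediction["rmse"] == pytest.approx(0.0)

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = evaluate_regression(self._Fixed(np.full(4, 2.5)),
                                  np.zeros((4, 1)), y)
        assert rep.prediction["r2"] == pytest.approx(0.0)

    def test_hand_table(self):
        # y/yhat pairs: residuals (.1, -.2, .1, .1, -.3); SSres = 0.16,
        # SStot = 2.468 -> R2 = 0.93517018, RMSE = sqrt(0.032) = 0.17888544
        y = np.array([3.1, 2.4, 1.8, 2.9, 1.2])
        yhat = np.array([3.0, 2.6, 1.7, 2.8, 1.5])
        rep = evaluate_regression(self._Fixed(yhat), np.zeros((5, 1)), y)
        assert rep.prediction["r2"] == pytest.approx(0.9351701782, abs=1e-9)
        assert rep.prediction["rmse"] == pytest.approx(0.1788854382, abs=1e-9)


@pytest.fixture(scope="module")
def tiny():
    cfg = SimConfig(
        n_per_group=12,
        rng_seed=6,
        wavelength_grid=np.linspace(384, 1034, 48),
    )
    ds, _ = generate_spectra(cfg)
    return ds


class TestRunGrid:
    def test_full_product_of_cells(self, tiny):
        result = run_grid(
            tiny, target="viability", k=8, seed=0,
            split=SplitSpec(rng_seed=0),
        )
        assert len(result.reports) == 4 * 3 * 4  # preprocess x bands x model
        assert len(result.table) == 48

    def test_grid_deterministic(self, tiny):
        kw = dict(target="viability", preprocess_list=("raw", "MF"),
                  selector_list=("full", "catboost"),
                  model_list=("lightgbm",), k=8, seed=1,
                  split=SplitSpec(rng_seed=1))
        a = run_grid(tiny, **kw)
        b = run_grid(tiny, **kw)
        assert a.table.equals(b.table)

    def test_best_cell_is_argmax_of_prediction_metric(self, tiny):
        result = run_grid(
            tiny, target="viability", preprocess_list=("raw", "MF"),
            selector_list=("full",), model_list=("lightgbm", "svm-rbf"),
            seed=0, split=SplitSpec(rng_seed=0),
        )
        best_acc = max(r.prediction["accuracy"] for r in result.reports)
        assert result.best.prediction["accuracy"] == best_acc

    def test_regression_grid_metrics(self, tiny):
        result = run_grid(
            tiny, target="sod", preprocess_list=("MSC",),
            selector_list=("full",), model_list=("plsr",),
            seed=0, split=SplitSpec(rng_seed=0),
        )
        rep = result.reports[0]
        assert set(rep.prediction) >= {"r2", "rmse"}
        assert rep.prediction["rmse"] >= 0
        assert rep.prediction["r2"] <= 1

    def test_empty_axis_rejected(self, tiny):
        with pytest.raises(ValueError):
            run_grid(tiny, preprocess_list=())

    def test_regressor_dispatch(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 0]
        assert train_regressor(X, y, "plsr").predict(X).shape == (30,)
        assert train_regressor(X, y, "xgboost").predict(X).shape == (30,)
        with pytest.raises(ValueError):
            train_regressor(X, y, "mlp")
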