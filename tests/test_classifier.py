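"""Classifiers and metrics: formula arithmetic, separable sanity, protocol."""

import numpy as np
import pytest

from hitfinder.classify import (
    ClassifierSpec,
    ConfusionCounts,
    confusion,
    cross_dataset_eval,
    evaluate,
    load_model,
    metrics,
    metrics_table,
    predict,
    save_model,
    train,
    tune_hyperparameters,
)

KINDS = ["mlp", "svm", "rf", "nb"]


def toy_separable(n_per_class=40, seed=0):
    """Miss rows all-zero, hit rows with 20 counts in one region."""
    rng = np.random.default_rng(seed)
    miss = np.zeros((n_per_class, 8))
    hit = rng.poisson(0.3, (n_per_class, 8)).astype(float)
    for i in range(n_per_class):
        hit[i, rng.integers(0, 8)] += 20
    X = np.vstack([hit, miss])
    y = np.array(["hit"] * n_per_class + ["miss"] * n_per_class)
    return X, y


class TestConfusionAndMetrics:
    def test_hand_tally(self):
        y_true = list("hhhhmmmmmm")
        y_pred = list("hhhmhmmmmm")
        c = confusion(y_true, y_pred, positive_label="h")
        assert (c.TP, c.FN, c.FP, c.TN) == (3, 1, 1, 5)

    def test_perfect_predictions(self):
        c = confusion(["hit"] * 4, ["hit"] * 4)
        assert c.FP == 0 and c.FN == 0
        m = metrics(ConfusionCounts(TP=4, TN=0, FP=0, FN=0))
        assert (m.f1, m.precision, m.recall, m.accuracy) == (100, 100, 100, 100)

    def test_empty_inputs_all_zero(self):
        c = confusion([], [])
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 0, 0)

    def test_metric_arithmetic_from_tally(self):
        m = metrics(ConfusionCounts(TP=3, FN=1, FP=1, TN=5))
        assert m.precision == 75.0
        assert m.recall == 75.0
        assert m.f1 == 75.0
        assert m.accuracy == 80.0

    def test_zero_division_conventions(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, FN=3, TN=2))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_f1_is_harmonic_mean_and_accuracy_label_symmetric(self, rng):
        y_true = rng.choice(["hit", "miss"], 200)
        y_pred = rng.choice(["hit", "miss"], 200)
        m_hit = metrics(confusion(y_true, y_pred, "hit"))
        m_miss = metrics(confusion(y_true, y_pred, "miss"))
        assert m_hit.accuracy == pytest.approx(m_miss.accuracy)
        if m_hit.precision + m_hit.recall > 0:
            hm = (
                2 * m_hit.precision * m_hit.recall
                / (m_hit.precision + m_hit.recall)
            )
            assert m_hit.f1 == pytest.approx(hm)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import (
            accuracy_score,
            f1_score,
            precision_score,
            recall_score,
        )

        y_true = rng.choice(["hit", "miss"], 300)
        y_pred = rng.choice(["hit", "miss"], 300)
        m = metrics(confusion(y_true, y_pred))
        assert m.precision == pytest.approx(
            100 * precision_score(y_true, y_pred, pos_label="hit")
        )
        assert m.recall == pytest.approx(
            100 * recall_score(y_true, y_pred, pos_label="hit")
        )
        assert m.f1 == pytest.approx(
            100 * f1_score(y_true, y_pred, pos_label="hit")
        )
        assert m.accuracy == pytest.approx(
            100 * accuracy_score(y_true, y_pred)
        )


class TestTraining:
    @pytest.mark.parametrize("kind", KINDS)
    def test_separable_data_fits_perfectly(self, kind):
        X, y = toy_separable()
        model = train(X, y, ClassifierSpec(kind=kind, random_seed=0))
        assert np.mean(predict(model, X) == y) == 1.0

    def test_same_seed_identical_predictions(self):
        X, y = toy_separable()
        grid = np.array(
            [[i, j, 0, 0, 0, 0, 0, 0] for i in range(0, 25, 4)
             for j in range(0, 25, 4)],
            dtype=float,
        )
        m1 = train(X, y, ClassifierSpec(kind="mlp", random_seed=3))
        m2 = train(X, y, ClassifierSpec(kind="mlp", random_seed=3))
        assert np.array_equal(predict(m1, grid), predict(m2, grid))

    def test_zero_vector_predicted_miss(self):
        X, y = toy_separable()
        model = train(X, y, ClassifierSpec(kind="rf"))
        assert predict(model, np.zeros((1, 8)))[0] == "miss"

    def test_single_class_rejected(self):
        X = np.zeros((10, 8))
        with pytest.raises(ValueError):
            train(X, ["miss"] * 10)

    def test_wrong_width_rejected(self):
        X, y = toy_separable()
        model = train(X, y)
        with pytest.raises(ValueError):
            predict(model, np.zeros((2, 5)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((10, 8)), ["hit"] * 9)

    def test_model_round_trip(self, tmp_path):
        X, y = toy_separable()
        model = train(X, y, ClassifierSpec(kind="svm"))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(predict(loaded, X), predict(model, X))
        assert loaded.spec == model.spec


class TestCrossDataset:
    def test_identical_sets_match_off_diagonal(self):
        X, y = toy_separable()
        table = cross_dataset_eval(
            {"a": (X, y), "b": (X, y)}, ClassifierSpec(kind="rf")
        )
        assert table.loc["a", "b"] == 100.0
        assert table.loc["a", "a"] == 100.0

    def test_single_dataset_rejected(self):
        X, y = toy_separable()
        with pytest.raises(ValueError):
            cross_dataset_eval({"a": (X, y)})

    def test_incompatible_widths_rejected(self):
        X, y = toy_separable()
        with pytest.raises(ValueError):
            cross_dataset_eval({"a": (X, y), "b": (X[:, :5], y)})


class TestTuning:
    def test_grid_of_one_returns_that_spec(self):
        X, y = toy_separable()
        spec = ClassifierSpec(kind="nb")
        out = tune_hyperparameters(X, y, [spec], cv_folds=3, seed=0)
        assert out.kind == "nb"

    def test_crippled_spec_loses_to_defaults(self):
        X, y = toy_separable()
        good = ClassifierSpec(kind="mlp")
        crippled = ClassifierSpec(
            kind="mlp", hyperparams={"hidden_layer_sizes": (1,), "max_iter": 5}
        )
        out = tune_hyperparameters(X, y, [crippled, good], cv_folds=3, seed=0)
        assert out.resolved_hyperparams()["hidden_layer_sizes"] == (50, 30, 20, 20)

    def test_too_many_folds_rejected(self):
        X, y = toy_separable(n_per_class=3)
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, [ClassifierSpec()], cv_folds=5, seed=0)

    def test_empty_grid_rejected(self):
        X, y = toy_separable()
        with pytest.raises(ValueError):
            tune_hyperparameters(X, y, [], cv_folds=2, seed=0)


class TestMulticlassAndTables:
    def test_macro_average_over_three_classes(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "b", "b", "b", "c", "a"]
        m = evaluate(y_true, y_pred)
        assert m.accuracy == pytest.approx(100 * 4 / 6)
        assert 0 < m.f1 < 100

    def test_metrics_table_shape(self):
        m = metrics(ConfusionCounts(TP=3, FN=1, FP=1, TN=5))
        table = metrics_table({"mlp": m, "svm": m})
        assert list(table.columns) == ["F1", "Precision", "Recall", "Accuracy"]
        assert table.loc["mlp", "Accuracy"] == 80.0


def test_separation_growth_improves_accuracy():
    """Held-out accuracy rises toward 100% as class separation grows."""
    rng = np.random.default_rng(0)
    accs = []
    for separation in (0.5, 2.0, 8.0):
        n = 120
        miss = rng.poisson(2.0, (n, 8)).astype(float)
        hit = miss.copy()
        hit[np.arange(n), rng.integers(0, 8, n)] += separation
        X = np.vstack([hit, miss])
        y = np.array(["hit"] * n + ["miss"] * n)
        idx = rng.permutation(len(X))
        cut = int(0.8 * len(X))
        tr_idx, te_idx = idx[:cut], idx[cut:]
        model = train(X[tr_idx], y[tr_idx], ClassifierSpec(kind="rf"))
        accs.append(float(np.mean(predict(model, X[te_idx]) == y[te_idx])))
    assert accs[0] <= accs[1] <= accs[2] + 1e-9
    assert accs[2] > 0.95
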