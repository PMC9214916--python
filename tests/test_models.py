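import numpy as np
import pytest

from mole8.models import (
    ModelConfig, KRRConfig, NNConfig, MLRConfig,
    train, predict, evaluate_mae, learning_curve,
    save_model, load_model,
)
from mole8.fixtures import make_linear_problem


@pytest.fixture(scope="module")
def linear_problem():
    X, y, coef, b = make_linear_problem(300, 12, noise_sd=0.0, seed=5)
    return X, y, coef, b


class TestTrainPredict:
    def test_mlr_recovers_generating_coefficients(self, linear_problem):
        X, y, coef, b = linear_problem
        model = train(X, y, ModelConfig("mlr", mlr=MLRConfig(l2=1e-12)))
        rel = np.abs(model.coefficients - coef) / np.abs(coef)
        assert rel.max() < 0.01

    def test_krr_interpolates_training_data_with_tiny_alpha(self, linear_problem):
        X, y, _, _ = linear_problem
        Xu, idx = np.unique(X, axis=0, return_index=True)
        model = train(Xu, y[idx],
                      ModelConfig("krr", krr=KRRConfig(sigma=200.0, alpha=1e-12)))
        assert evaluate_mae(predict(model, Xu), y[idx]) < 1e-6

    @pytest.mark.parametrize("family", ["krr", "nn", "mlr", "rfr"])
    def test_constant_target_predicted_by_all_families(self, family, linear_problem):
        X, _, _, _ = linear_problem
        y = np.full(60, -3.25)
        model = train(X[:60], y, ModelConfig(family, nn=NNConfig(hidden_width=32,
                                                                 epochs=150)))
        assert np.abs(predict(model, X[:60]) - (-3.25)).max() < 1e-3

    def test_nan_input_rejected(self, linear_problem):
        X, y, _, _ = linear_problem
        Xb = X.copy()
        Xb[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(Xb, y, ModelConfig("mlr"))

    def test_empty_prediction(self, linear_problem):
        X, y, _, _ = linear_problem
        model = train(X, y, ModelConfig("krr"))
        assert predict(model, np.empty((0, X.shape[1]))).size == 0

    def test_duplicated_row_gives_identical_predictions(self, linear_problem):
        X, y, _, _ = linear_problem
        model = train(X, y, ModelConfig("krr"))
        two = np.vstack([X[3], X[3]])
        p = predict(model, two)
        assert p[0] == p[1]

    def test_feature_length_mismatch_rejected(self, linear_problem):
        X, y, _, _ = linear_problem
        model = train(X, y, ModelConfig("krr"))
        with pytest.raises(ValueError, match="feature length"):
            predict(model, X[:, :-1])

    def test_dictionary_fingerprint_mismatch_rejected(self, linear_problem):
        X, y, _, _ = linear_problem
        model = train(X, y, ModelConfig("krr"), dictionary_fingerprint="abc")
        with pytest.raises(ValueError, match="fingerprint"):
            predict(model, X, dictionary_fingerprint="def")
        assert predict(model, X, dictionary_fingerprint="abc").shape == y.shape

    def test_krr_invariant_under_training_row_permutation(self, linear_problem):
        X, y, _, _ = linear_problem
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        a = train(X, y, ModelConfig("krr", krr=KRRConfig(sigma=500, alpha=1e-8)))
        b = train(X[perm], y[perm], ModelConfig("krr", krr=KRRConfig(sigma=500, alpha=1e-8)))
        assert np.allclose(predict(a, X[:20]), predict(b, X[:20]), atol=1e-6)

    def test_save_load_round_trip(self, linear_problem, tmp_path):
        X, y, _, _ = linear_problem
        model = train(X, y, ModelConfig("krr"))
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        assert np.array_equal(predict(back, X[:5]), predict(model, X[:5]))


class TestEvaluate:
    def test_mae_definition(self):
        assert evaluate_mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert evaluate_mae([3.0, 4.0], [1.0, 2.0]) == 2.0
        assert evaluate_mae([1.0, -3.0], [0.0, 0.0]) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_mae([], [])


class TestLearningCurve:
    def test_full_pool_matches_direct_training(self):
        X, y, _, _ = make_linear_problem(120, 8, noise_sd=0.5, seed=2)
        cfg = ModelConfig("krr", krr=KRRConfig(sigma=500, alpha=1e-8))
        table = learning_curve(X[:80], y[:80], X[80:], y[80:], [80], cfg, seed=0)
        direct = evaluate_mae(predict(train(X[:80], y[:80], cfg), X[80:]), y[80:])
        assert table[0] == (80, pytest.approx(direct))

    def test_seed_determinism_and_size_validation(self):
        X, y, _, _ = make_linear_problem(120, 8, noise_sd=0.5, seed=2)
        cfg = ModelConfig("krr", krr=KRRConfig(sigma=500, alpha=1e-8))
        t1 = learning_curve(X[:80], y[:80], X[80:], y[80:], [20, 60], cfg, seed=4)
        t2 = learning_curve(X[:80], y[:80], X[80:], y[80:], [20, 60], cfg, seed=4)
        assert t1 == t2
        with pytest.raises(ValueError):
            learning_curve(X[:80], y[:80], X[80:], y[80:], [81], cfg, seed=0)

    def test_error_shrinks_with_training_size_on_linear_task(self):
        X, y, _, _ = make_linear_problem(500, 10, noise_sd=0.5, seed=7)
        cfg = ModelConfig("krr", krr=KRRConfig(sigma=500, alpha=1e-8))
        maes = []
        for seed in (0, 1, 2):
            t = learning_curve(X[:400], y[:400], X[400:], y[400:],
                               [40, 150, 400], cfg, seed=seed)
            maes.append([mae for _, mae in t])
        med = np.median(maes, axis=0)
        assert med[-1] < med[0]
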