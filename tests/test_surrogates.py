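"""Surrogate methods: split protocol, loss, fitting contracts, benchmark."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caresim.errors import DataError, SpecError
from caresim.surrogates import (
    METHODS,
    SurrogateSpec,
    benchmark_all,
    fit_surrogate,
    mse,
    predict,
    three_way_split,
)


def toy_data(n=60, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, 10))
    beta = rng.normal(size=10)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(200, (128, 32, 40)), (10, (7, 1, 2))])
    def test_floor_sizes(self, n, expected):
        s = three_way_split(n, 0)
        assert (s.train.size, s.validation.size, s.test.size) == expected

    @given(n=st.integers(3, 5000), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_disjoint_and_exhaustive(self, n, seed):
        s = three_way_split(n, seed)
        allidx = np.concatenate([s.train, s.validation, s.test])
        assert np.array_equal(np.sort(allidx), np.arange(n))
        assert s.test.size == int(np.floor(0.2 * n))
        assert s.validation.size == int(np.floor(0.2 * (n - s.test.size)))

    def test_deterministic(self):
        a, b = three_way_split(57, 4), three_way_split(57, 4)
        np.testing.assert_array_equal(a.test, b.test)
        np.testing.assert_array_equal(a.train, b.train)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            three_way_split(2, 0)


class TestMSE:
    def test_identity_and_example(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mse([1, 2], [2, 4]) == 2.5

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(1)
        y, yhat = rng.normal(size=100), rng.normal(size=100)
        manual = sum((b - a) ** 2 for a, b in zip(y, yhat)) / 100
        assert mse(y, yhat) == pytest.approx(manual, rel=1e-12)

    def test_shape_error(self):
        with pytest.raises(ValueError):
            mse([1, 2, 3], [1, 2])


class TestFitContracts:
    def test_linear_recovers_linear_map(self):
        X, y = toy_data(80)
        f = fit_surrogate(SurrogateSpec("linear_regression"), X[:60], y[:60])
        assert mse(y[60:], predict(f, X[60:])) < 1e-16

    def test_one_nn_reproduces_training_labels(self):
        X, y = toy_data(30)
        f = fit_surrogate(SurrogateSpec("knn", {"k_grid": (1,)}), X, y)
        np.testing.assert_allclose(predict(f, X), y)

    def test_gp_interpolates_smooth_function(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 10))
        y = np.sin(X.sum(axis=1))
        f = fit_surrogate(
            SurrogateSpec("gaussian_process",
                          {"nugget": 1e-8, "estimate_noise": False}),
            X, y,
        )
        assert mse(y, predict(f, X)) < 1e-6

    @pytest.mark.parametrize("method", ["decision_tree", "knn", "linear_regression"])
    def test_constant_target_degeneracy(self, method):
        X, _ = toy_data(30)
        y = np.full(30, 3.7)
        f = fit_surrogate(SurrogateSpec(method), X[:20], y[:20], X[20:25], y[20:25])
        np.testing.assert_allclose(predict(f, X[25:]), 3.7, rtol=1e-9)

    def test_prediction_is_pure(self):
        X, y = toy_data(40)
        f = fit_surrogate(SurrogateSpec("random_forest", {"n_estimators": 20}),
                          X[:30], y[:30])
        p1, p2 = predict(f, X[30:]), predict(f, X[30:])
        np.testing.assert_array_equal(p1, p2)
        assert np.all(np.isfinite(p1))

    def test_empty_and_mismatched_inputs(self):
        X, y = toy_data(20)
        f = fit_surrogate(SurrogateSpec("linear_regression"), X, y)
        assert predict(f, np.empty((0, 10))).size == 0
        with pytest.raises(ValueError):
            predict(f, X[:, :9])

    def test_validation_selects_hyperparameters(self):
        X, y = toy_data(100, noise=0.05)
        f = fit_surrogate(SurrogateSpec("knn"), X[:64], y[:64], X[64:80], y[64:80])
        assert f.selected["k"] in (3, 5, 7, 10)
        assert f.trainingSeconds >= 0

    def test_unknown_method_and_bad_targets(self):
        with pytest.raises(SpecError):
            SurrogateSpec("extreme_gradient_boosting")
        X, y = toy_data(10)
        y[0] = np.nan
        with pytest.raises(DataError):
            fit_surrogate(SurrogateSpec("linear_regression"), X, y)


class TestBenchmark:
    def fast_specs(self, seed=0):
        hp = {
            "random_forest": {"n_estimators": 20},
            "gradient_boosted_trees": {"n_estimators": 50},
            "gaussian_process": {"n_restarts": 0},
            "svm_linear": {"C_grid": (1.0,), "epsilon_grid": (0.1,)},
            "svm_rbf": {"C_grid": (1.0,), "epsilon_grid": (0.1,),
                        "gamma_grid": ("scale",)},
            "neural_network": {"epochs": 200, "hidden_grid": (1,)},
        }
        return [SurrogateSpec(m, hp.get(m, {}), seed=seed) for m in METHODS]

    def test_nine_rows_and_internal_consistency(self):
        X, y = toy_data(60, noise=0.1)
        runs = type("Runs", (), {"X": X, "y": y})()
        board = benchmark_all(runs, self.fast_specs(), split_seed=0)
        assert len(board.rows) == 9
        for row in board.rows:
            assert not row.failed
            recomputed = mse(y[board.split.test], row.test_predictions)
            assert row.mse_test == pytest.approx(recomputed, rel=1e-12)

    def test_deterministic_modulo_time(self):
        X, y = toy_data(50, noise=0.1)
        runs = type("Runs", (), {"X": X, "y": y})()
        specs = [SurrogateSpec("linear_regression"),
                 SurrogateSpec("decision_tree"),
                 SurrogateSpec("knn")]
        a = benchmark_all(runs, specs, split_seed=1)
        b = benchmark_all(runs, specs, split_seed=1)
        for ra, rb in zip(a.rows, b.rows):
            assert ra.mse_test == rb.mse_test
            assert ra.selected == rb.selected

    def test_failed_method_isolated(self):
        X, y = toy_data(12)
        runs = type("Runs", (), {"X": X, "y": y})()
        specs = [
            SurrogateSpec("knn", {"k_grid": (50,)}),  # more neighbours than rows
            SurrogateSpec("linear_regression"),
        ]
        board = benchmark_all(runs, specs, split_seed=0)
        assert board["knn"].failed
        assert not board["linear_regression"].failed

    def test_no_leakage_from_test_rows(self):
        """Changing test-row outputs must not change any model's predictions."""
        X, y = toy_data(60, noise=0.1)
        split = three_way_split(60, 2)
        y2 = y.copy()
        y2[split.test] = 999.0
        runs_a = type("Runs", (), {"X": X, "y": y})()
        runs_b = type("Runs", (), {"X": X, "y": y2})()
        specs = [SurrogateSpec("linear_regression"), SurrogateSpec("decision_tree")]
        a = benchmark_all(runs_a, specs, split_seed=2)
        b = benchmark_all(runs_b, specs, split_seed=2)
        for ra, rb in zip(a.rows, b.rows):
            np.testing.assert_array_equal(ra.test_predictions, rb.test_predictions)


class TestUniversalApproximation:
    def test_tuned_network_beats_linear_on_smooth_nonlinear_target(self):
        """A tanh network approximates a smooth nonlinear map far better
        than least squares (kept small: reduced epochs and grid)."""
        rng = np.random.default_rng(0)
        X = rng.random((800, 10))
        y = (np.sin(2 * np.pi * X[:, 0]) * X[:, 1]
             + np.exp(X[:, 2] * X[:, 3])
             + 0.5 * np.abs(4 * X[:, 4] - 2))
        s = three_way_split(800, 0)
        lin = fit_surrogate(SurrogateSpec("linear_regression"),
                            X[s.train], y[s.train])
        nn = fit_surrogate(
            SurrogateSpec("neural_network", {"epochs": 3000, "hidden_grid": (2, 4)}),
            X[s.train], y[s.train], X[s.validation], y[s.validation],
        )
        m_lin = mse(y[s.test], predict(lin, X[s.test]))
        m_nn = mse(y[s.test], predict(nn, X[s.test]))
        assert m_nn < 0.1 * m_lin
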