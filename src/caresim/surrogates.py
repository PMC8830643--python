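"""Surrogate regression methods and the benchmark harness.

Nine regression families are trained as surrogates of the simulator:
linear regression, a decision tree, a random forest, gradient-boosted
trees, k-nearest neighbours, a Gaussian-process regressor, linear- and
RBF-kernel support vector machines, and a deep fully-connected neural
network.  All methods share one three-way split of the run table: 20% of
the rows are held out as the test set, 20% of the remainder form the
validation set, and the rest train the model.  Hyperparameters (the KNN
neighbour count, SVM grids, the neural network's hidden-layer count) are
selected on the validation set only; the test set is touched exactly once,
to compute the final mean-squared error.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .errors import DataError, SpecError

__all__ = [
    "METHODS",
    "SplitIndices",
    "SurrogateSpec",
    "FittedSurrogate",
    "Leaderboard",
    "three_way_split",
    "mse",
    "fit_surrogate",
    "predict",
    "benchmark_all",
]

METHODS = (
    "linear_regression",
    "decision_tree",
    "random_forest",
    "gradient_boosted_trees",
    "knn",
    "gaussian_process",
    "svm_linear",
    "svm_rbf",
    "neural_network",
)

N_FEATURES = 10  # the ten swept simulator parameters


# --------------------------------------------------------------------------
# split protocol and loss
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation/test row indices over a run table."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self):
        n = self.train.size + self.validation.size + self.test.size
        all_idx = np.concatenate([self.train, self.validation, self.test])
        if np.unique(all_idx).size != n:
            raise ValueError("split index sets overlap")


def three_way_split(n: int, seed: int) -> SplitIndices:
    """Random 64/16/20 split: test = 20% of n, validation = 20% of the rest.

    Sizes use floor arithmetic (e.g. n=200 gives 128/32/40); the row
    permutation is deterministic per seed.
    """
    if n < 3:
        raise ValueError(f"need at least 3 rows to split, got {n}")
    n_test = int(np.floor(0.2 * n))
    n_val = int(np.floor(0.2 * (n - n_test)))
    perm = np.random.default_rng(int(seed)).permutation(n)
    return SplitIndices(
        train=np.sort(perm[n_test + n_val:]),
        validation=np.sort(perm[n_test:n_test + n_val]),
        test=np.sort(perm[:n_test]),
        seed=int(seed),
    )


def mse(actual, predicted=None) -> float:
    """Mean squared error between actual and predicted value vectors.

    Accepts either two vectors or a single object with ``actual`` /
    ``predicted`` attributes (a :class:`PredictionSet`).
    """
    if predicted is None:
        actual, predicted = actual.actual, actual.predicted
    y = np.asarray(actual, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("need at least one value")
    return float(np.mean((yhat - y) ** 2))


@dataclass(frozen=True)
class PredictionSet:
    """Paired actual/predicted values for one evaluation set."""

    actual: np.ndarray
    predicted: np.ndarray

    def __post_init__(self):
        if self.actual.shape != self.predicted.shape:
            raise ValueError("actual and predicted must have equal length")
        if not (np.all(np.isfinite(self.actual)) and np.all(np.isfinite(self.predicted))):
            raise DataError("non-finite values in prediction set")


# --------------------------------------------------------------------------
# method construction
# --------------------------------------------------------------------------

def _scaled(est):
    return Pipeline([("scale", StandardScaler()), ("est", est)])


def _scaled_xy(est):
    """Standardise both features and target (SVM epsilon, NN step sizes)."""
    return TransformedTargetRegressor(
        regressor=_scaled(est), transformer=StandardScaler()
    )


def _make_linear(hp, seed):
    yield {}, LinearRegression()


def _make_tree(hp, seed):
    yield {}, DecisionTreeRegressor(
        min_samples_leaf=hp.get("min_samples_leaf", 5), random_state=seed
    )


def _make_forest(hp, seed):
    yield {}, RandomForestRegressor(
        n_estimators=hp.get("n_estimators", 500),
        max_features=hp.get("max_features", 4),  # ceil(10 / 3)
        random_state=seed,
        n_jobs=1,
    )


def _make_gbt(hp, seed):
    yield {}, GradientBoostingRegressor(
        n_estimators=hp.get("n_estimators", 500),
        max_depth=hp.get("max_depth", 3),
        learning_rate=hp.get("learning_rate", 0.05),
        random_state=seed,
    )


def _make_knn(hp, seed):
    for k in hp.get("k_grid", (3, 5, 7, 10)):
        yield {"k": k}, _scaled(KNeighborsRegressor(n_neighbors=k))


def _make_gp(hp, seed):
    nugget = hp.get("nugget", 1e-8)
    estimate_noise = hp.get("estimate_noise", True)
    kernel = ConstantKernel(1.0, (1e-3, 1e4)) * RBF(
        length_scale=np.ones(N_FEATURES), length_scale_bounds=(1e-2, 1e3)
    )
    if estimate_noise:
        kernel = kernel + WhiteKernel(1e-2, (1e-10, 1e2))
    yield {"nugget": nugget}, _scaled(
        GaussianProcessRegressor(
            kernel=kernel,
            alpha=nugget,
            normalize_y=True,
            n_restarts_optimizer=hp.get("n_restarts", 1),
            random_state=seed,
        )
    )


def _svm_grid(hp, kernel):
    cs = hp.get("C_grid", (0.1, 1.0, 10.0, 100.0))
    eps = hp.get("epsilon_grid", (0.01, 0.1, 0.5))
    gammas = hp.get("gamma_grid", ("scale", 0.01, 0.1, 1.0)) if kernel == "rbf" else (None,)
    for c in cs:
        for e in eps:
            for g in gammas:
                sel = {"C": c, "epsilon": e}
                kw = dict(kernel=kernel, C=c, epsilon=e)
                if g is not None:
                    sel["gamma"] = g
                    kw["gamma"] = g
                yield sel, _scaled_xy(SVR(**kw))


def _make_svm_linear(hp, seed):
    yield from _svm_grid(hp, "linear")


def _make_svm_rbf(hp, seed):
    yield from _svm_grid(hp, "rbf")


def _make_nn(hp, seed):
    """Deep tanh networks: input(10) -> k hidden layers of 50 units -> scalar.

    The hidden-layer count is grid-searched on the validation set.  Training
    uses an adaptive-gradient (Adam) optimiser at learning rate 3e-4 with an
    L2 penalty of 0.03 for up to ``epochs`` full-batch epochs; features and
    target are standardised in lieu of the batch-normalisation layers of the
    reference architecture.
    """
    epochs = hp.get("epochs", 15_000)
    width = hp.get("width", 50)
    for k in hp.get("hidden_grid", tuple(range(1, 13))):
        est = MLPRegressor(
            hidden_layer_sizes=(width,) * k,
            activation="tanh",
            solver="adam",
            learning_rate_init=hp.get("learning_rate", 3e-4),
            alpha=hp.get("l2", 0.03),
            max_iter=epochs,
            batch_size=hp.get("batch_size", "auto"),  # toolchain default
            tol=0.0,
            n_iter_no_change=epochs,
            random_state=seed,
        )
        yield {"hidden_layers": k, "epochs": epochs}, _scaled_xy(est)


_FACTORIES = {
    "linear_regression": _make_linear,
    "decision_tree": _make_tree,
    "random_forest": _make_forest,
    "gradient_boosted_trees": _make_gbt,
    "knn": _make_knn,
    "gaussian_process": _make_gp,
    "svm_linear": _make_svm_linear,
    "svm_rbf": _make_svm_rbf,
    "neural_network": _make_nn,
}


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class SurrogateSpec:
    """A surrogate method name, hyperparameter overrides and training seed."""

    method: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise SpecError(
                f"unknown method {self.method!r}; choose from {METHODS}"
            )


@dataclass
class FittedSurrogate:
    """A trained surrogate with its selection record and training time."""

    spec: SurrogateSpec
    model: object
    selected: dict
    trainingSeconds: float
    validation_mse: float

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def _check_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"X must have {N_FEATURES} columns, got shape {X.shape}")
    return X


def fit_surrogate(
    spec: SurrogateSpec,
    trainX, trainY,
    valX=None, valY=None,
) -> FittedSurrogate:
    """Train one surrogate, selecting hyperparameters on the validation set.

    Candidates produced by the method's grid are fitted on the training rows
    and scored by validation MSE; the best candidate is returned.  When no
    validation set is given the first (default) candidate is used.  Wall
    clock training time across the whole grid is recorded.
    """
    trainX = _check_X(trainX)
    trainY = np.asarray(trainY, dtype=float).ravel()
    if not np.all(np.isfinite(trainY)):
        raise DataError("training targets contain non-finite values")
    if trainX.shape[0] != trainY.size:
        raise ValueError("trainX and trainY length mismatch")

    factory = _FACTORIES[spec.method]
    t0 = time.perf_counter()
    best = None
    first_error = None
    for selected, est in factory(spec.hyperparameters, spec.seed):
        try:
            est.fit(trainX, trainY)
            if valX is not None and len(np.asarray(valX)) > 0:
                score = mse(valY, est.predict(_check_X(valX)))
            else:
                score = float("nan")
        except Exception as exc:  # an infeasible grid point; try the rest
            first_error = first_error or exc
            continue
        if best is None or (score == score and not best[2] <= score):
            best = (est, selected, score)
    if best is None:
        raise first_error if first_error is not None else SpecError(
            f"no candidate model for {spec.method}"
        )
    seconds = time.perf_counter() - t0
    model, selected, val_mse = best
    return FittedSurrogate(
        spec=spec,
        model=model,
        selected=selected,
        trainingSeconds=seconds,
        validation_mse=val_mse,
    )


def predict(model: FittedSurrogate, X) -> np.ndarray:
    """Pure prediction: same inputs always give the same outputs."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.empty(0)
    X = _check_X(X)
    return np.asarray(model.model.predict(X), dtype=float).ravel()


# --------------------------------------------------------------------------
# benchmark harness
# --------------------------------------------------------------------------

@dataclass
class LeaderboardRow:
    method: str
    n_runs: int
    mse_test: float | None
    training_seconds: float | None
    selected: dict
    failed: bool = False
    error: str | None = None
    test_predictions: np.ndarray | None = None


@dataclass
class Leaderboard:
    """Per-method test MSE and training time for one run table."""

    rows: list
    split: SplitIndices

    def as_records(self) -> list[dict]:
        return [
            {
                "method": r.method,
                "n_runs": r.n_runs,
                "mse_test": r.mse_test,
                "training_seconds": r.training_seconds,
                "selected_hyperparameters": r.selected,
                "failed": r.failed,
            }
            for r in self.rows
        ]

    def best(self, among=None):
        rows = [
            r for r in self.rows
            if not r.failed and (among is None or r.method in among)
        ]
        return min(rows, key=lambda r: r.mse_test)

    def __getitem__(self, method: str) -> LeaderboardRow:
        for r in self.rows:
            if r.method == method:
                return r
        raise KeyError(method)


def benchmark_all(runs, specs, split_seed: int = 0) -> Leaderboard:
    """Fit every spec on one shared split of the run table; score test MSE.

    ``runs`` is a RunTable (or any object with ``X`` and ``y``).  A method
    that fails to train is flagged in its row; the others are unaffected.
    """
    X, y = np.asarray(runs.X, dtype=float), np.asarray(runs.y, dtype=float)
    split = three_way_split(len(y), split_seed)
    rows = []
    for spec in specs:
        if isinstance(spec, str):
            spec = SurrogateSpec(method=spec)
        try:
            fitted = fit_surrogate(
                spec,
                X[split.train], y[split.train],
                X[split.validation], y[split.validation],
            )
            yhat = predict(fitted, X[split.test])
            rows.append(LeaderboardRow(
                method=spec.method,
                n_runs=len(y),
                mse_test=mse(y[split.test], yhat),
                training_seconds=fitted.trainingSeconds,
                selected=fitted.selected,
                test_predictions=yhat,
            ))
        except Exception as exc:  # noqa: BLE001 - isolate per-method failures
            rows.append(LeaderboardRow(
                method=spec.method, n_runs=len(y), mse_test=None,
                training_seconds=None, selected={}, failed=True, error=str(exc),
            ))
    return Leaderboard(rows=rows, split=split)
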