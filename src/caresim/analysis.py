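"""Variance analyses of simulator outputs.

Two complementary analyses are provided.

*Principal component analysis* of the z-scored run table (inputs, and
optionally the output) identifies directions of greatest joint variation.
Components are retained by the Kaiser criterion (eigenvalue of the
correlation matrix greater than one), extended in order until at least 70%
of total variance is explained; a variable contributes significantly to a
component when the magnitude of its correlation-scaled loading exceeds 0.5.

*Main effects* decompose a fitted surrogate's output variance by input:
the main effect of parameter ``i`` at value ``v`` is the expected surrogate
prediction when the other nine parameters are drawn uniformly from their
ranges; its variance across the range of ``i``, divided by the total
prediction variance, estimates the first-order (Sobol) variance share.
Expectations are taken by quasi-Monte-Carlo over a scrambled Sobol sample,
so the same analysis applies to any of the nine surrogate methods.  The
analytic Sobol g-function is included as a ground-truth testbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc

from .errors import DataError, InvalidSpaceError, ZeroVarianceError
from .space import ParameterSpace

__all__ = [
    "StandardizedTable",
    "PCAResult",
    "SensitivityResult",
    "zscore",
    "pca_with_retention",
    "main_effects",
    "sobol_g_function",
    "g_function_indices",
]


# --------------------------------------------------------------------------
# z-score standardisation
# --------------------------------------------------------------------------

@dataclass
class StandardizedTable:
    """Column-wise z-scores with the means and (n-1) deviations used."""

    z: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    columns: tuple

    def inverse(self) -> np.ndarray:
        return self.z * self.std + self.mean


def zscore(table, columns=None) -> StandardizedTable:
    """Standardise each column to mean 0, sample (n-1) standard deviation 1.

    ``table`` may be a 2-D array or a DataFrame (whose column names are
    kept).  A constant column raises :class:`ZeroVarianceError` naming it.
    """
    if hasattr(table, "to_numpy"):
        if columns is None:
            columns = tuple(table.columns)
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
        if columns is None:
            columns = tuple(range(x.shape[1]))
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataError("need a 2-D table with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise DataError("table contains non-finite values")
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=1)
    for j, s in enumerate(std):
        if s == 0.0:
            raise ZeroVarianceError(str(columns[j]))
    return StandardizedTable(z=(x - mean) / std, mean=mean, std=std,
                             columns=tuple(columns))


# --------------------------------------------------------------------------
# PCA with retention rules
# --------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Eigenstructure of the correlation matrix plus retention decisions."""

    eigenvalues: np.ndarray          # descending
    explained_pct: np.ndarray        # percentages summing to 100
    loadings: np.ndarray             # variables x components, correlation-scaled
    components: np.ndarray           # variables x components, unit eigenvectors
    retained: int
    significant: list                # per retained component: significant columns
    columns: tuple

    def scree(self) -> np.ndarray:
        return self.explained_pct


def pca_with_retention(
    z: StandardizedTable, kaiser: float = 1.0, target_pct: float = 70.0,
    loading_threshold: float = 0.5,
) -> PCAResult:
    """Eigendecompose the correlation matrix and apply the retention rules.

    Retains every component with eigenvalue > ``kaiser`` (the Kaiser
    criterion), then extends in order until the cumulative explained
    variance reaches ``target_pct`` percent.  Loadings are reported as
    variable-component correlations (eigenvector * sqrt(eigenvalue)); a
    variable is significant on a component when |loading| is strictly
    greater than ``loading_threshold``.
    """
    zmat = z.z
    n, p = zmat.shape
    if n <= p:
        warnings.warn(
            f"PCA on {n} rows x {p} columns: fewer rows than recommended",
            stacklevel=2,
        )
    if not np.all(np.isfinite(zmat)):
        raise DataError("z-scores contain non-finite values")
    corr = (zmat.T @ zmat) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    explained = 100.0 * eigval / eigval.sum()

    retained = int(np.sum(eigval > kaiser))
    retained = max(retained, 1)
    while retained < p and explained[:retained].sum() < target_pct:
        retained += 1

    loadings = eigvec * np.sqrt(eigval)
    significant = [
        [z.columns[j] for j in np.flatnonzero(np.abs(loadings[:, c]) > loading_threshold)]
        for c in range(retained)
    ]
    return PCAResult(
        eigenvalues=eigval,
        explained_pct=explained,
        loadings=loadings,
        components=eigvec,
        retained=retained,
        significant=significant,
        columns=z.columns,
    )


# --------------------------------------------------------------------------
# main effects / first-order variance shares
# --------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Main-effect curves and first-order variance shares per parameter."""

    grid: dict                 # name -> grid of parameter values
    effects: dict              # name -> mean prediction at each grid value
    shares: dict               # name -> first-order variance share
    total_variance: float
    n_mc: int


def _predict_fn(model):
    if hasattr(model, "predict"):
        return lambda X: np.asarray(model.predict(X), dtype=float).ravel()
    if callable(model):
        return lambda X: np.asarray(model(X), dtype=float).ravel()
    raise TypeError("model must be callable or expose .predict")


def main_effects(
    model,
    space: ParameterSpace,
    grid_size: int = 32,
    n_mc: int = 2 ** 13,
    seed: int = 0,
) -> SensitivityResult:
    """Quasi-Monte-Carlo main effects of each input on the model output.

    For parameter ``i`` and grid value ``v``, the main effect is the mean
    prediction over ``n_mc`` scrambled-Sobol draws of the other parameters,
    uniform on their ranges.  Grid values sit at the midpoints of
    ``grid_size`` equal-width bins, so the empirical variance of the curve
    is an (almost) unbiased estimate of the variance of the main effect
    under a uniform input.  The first-order share divides that variance by
    the variance of predictions over the full quasi-random sample.
    Deterministic per seed.
    """
    if n_mc < 64:
        raise ValueError("n_mc must be >= 64")
    lo, hi = space.lowers, space.uppers
    if np.any(hi <= lo):
        raise InvalidSpaceError("degenerate parameter range (lower >= upper)")
    f = _predict_fn(model)
    d = space.dim

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        sampler = qmc.Sobol(d=d, scramble=True, rng=int(seed))
        base = sampler.random(n_mc)
    X_base = lo + base * (hi - lo)
    preds = f(X_base)
    total_var = float(np.var(preds))

    grid, effects, shares = {}, {}, {}
    mids = (np.arange(grid_size) + 0.5) / grid_size
    for i, p in enumerate(space.parameters):
        vals = lo[i] + mids * (hi[i] - lo[i])
        if p.integer:
            vals = np.round(vals)
        curve = np.empty(grid_size)
        X = X_base.copy()
        for g, v in enumerate(vals):
            X[:, i] = v
            curve[g] = f(X).mean()
        grid[p.name] = vals
        effects[p.name] = curve
        shares[p.name] = float(np.var(curve) / total_var) if total_var > 0 else 0.0
    return SensitivityResult(
        grid=grid, effects=effects, shares=shares,
        total_variance=total_var, n_mc=n_mc,
    )


# --------------------------------------------------------------------------
# analytic testbed: the Sobol g-function
# --------------------------------------------------------------------------

def sobol_g_function(x, a) -> np.ndarray:
    """g(x) = prod_i (|4 x_i - 2| + a_i) / (1 + a_i) on the unit cube.

    Vectorised over rows of ``x``.  Larger ``a_i`` makes input ``i`` less
    influential; the first-order variance shares have the closed form
    returned by :func:`g_function_indices`.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise ValueError("g-function coefficients must be >= 0")
    if x.shape[1] != a.size:
        raise ValueError("x and a dimension mismatch")
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("x must lie in the unit cube")
    vals = np.prod((np.abs(4.0 * x - 2.0) + a) / (1.0 + a), axis=1)
    return vals if vals.size > 1 else float(vals[0])


def g_function_indices(a) -> np.ndarray:
    """Closed-form first-order Sobol indices of the g-function.

    ``V_i = (1/3) / (1 + a_i)^2``, ``V = prod(1 + V_i) - 1``,
    ``S_i = V_i / V``.
    """
    a = np.asarray(a, dtype=float)
    vi = (1.0 / 3.0) / (1.0 + a) ** 2
    v = np.prod(1.0 + vi) - 1.0
    return vi / v
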