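"""Space-filling experimental designs over the swept parameter space.

Two generators are provided: the Sobol low-discrepancy sequence (the
quasi-random design known in the Gaussian-process emulation literature as
LP-tau) and a maximin-optimised Latin hypercube.  Unit-cube points are
scaled affinely onto the parameter ranges; integer-valued parameters are
rounded after scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import InvalidSpaceError, SchemaError
from .space import ParameterSpace, default_space

__all__ = [
    "DesignMatrix",
    "sobol_unit_points",
    "scale_to_space",
    "lptau_design",
    "maximin_lhd",
    "write_design",
    "read_design",
]


@dataclass
class DesignMatrix:
    """An n x d experimental design with provenance metadata."""

    frame: pd.DataFrame
    provenance: str            # "lp-tau" or "maximin-lhd"
    seed: int | None = None    # generator seed (LHD) or Sobol skip

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)


def sobol_unit_points(n: int, d: int, skip: int = 1) -> np.ndarray:
    """The Sobol (LP-tau) sequence: n points in [0, 1)^d.

    Deterministic for fixed ``(n, d, skip)``.  The sequence's initial
    all-zero point is skipped by default (``skip=1``); larger skips drop
    more leading points.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if d < 1:
        raise ValueError("d must be >= 1")
    if skip < 0:
        raise ValueError("skip must be >= 0")
    try:
        engine = qmc.Sobol(d=d, scramble=False)
    except ValueError as exc:  # dimension beyond available direction numbers
        raise ValueError(f"unsupported dimension {d}: {exc}") from exc
    if n == 0:
        return np.empty((0, d))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non power-of-two draws
        if skip:
            engine.fast_forward(skip)
        return engine.random(n)


def scale_to_space(unit_points: np.ndarray, space: ParameterSpace) -> DesignMatrix:
    """Affinely map unit-cube points onto the parameter ranges.

    Integer-flagged parameters are rounded to the nearest integer after
    scaling (half away from zero would need care only at .5 exactly, which
    quasi-random points never produce for these ranges).
    """
    u = np.atleast_2d(np.asarray(unit_points, dtype=float))
    if u.size and (np.any(u < 0.0) or np.any(u >= 1.0)):
        raise ValueError("unit points must lie in [0, 1)")
    if u.shape[1] != space.dim:
        raise InvalidSpaceError(
            f"expected {space.dim} columns, got {u.shape[1]}"
        )
    lo, hi = space.lowers, space.uppers
    vals = lo + u * (hi - lo)
    int_cols = np.flatnonzero(space.integer_mask)
    for j in int_cols:
        vals[:, j] = np.round(vals[:, j])
    frame = pd.DataFrame(vals, columns=list(space.names))
    return DesignMatrix(frame=frame, provenance="scaled")


def lptau_design(n: int, space: ParameterSpace | None = None, skip: int = 1) -> DesignMatrix:
    """An LP-tau (Sobol) design of n rows over the parameter space."""
    space = space or default_space()
    pts = sobol_unit_points(n, space.dim, skip=skip)
    design = scale_to_space(pts, space)
    design.provenance = "lp-tau"
    design.seed = skip
    return design


def _min_pairwise_dist(x: np.ndarray) -> float:
    if x.shape[0] < 2:
        return np.inf
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.sqrt(d2.min()))


def maximin_lhd(
    n: int,
    space: ParameterSpace | None = None,
    iterations: int = 200,
    seed: int = 0,
) -> DesignMatrix:
    """A maximin-optimised Latin hypercube design.

    Starts from a random Latin hypercube (one point per equal-width bin per
    column) and hill-climbs: each iteration proposes swapping two entries
    within one column, accepting the swap only if the minimum pairwise
    distance (in unit-cube coordinates) does not decrease.  Deterministic
    per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    space = space or default_space()
    rng = np.random.default_rng(seed)
    d = space.dim
    # classic LHS: random permutation of bins per column, random point in bin
    u = np.empty((n, d))
    for j in range(d):
        perm = rng.permutation(n)
        u[:, j] = (perm + rng.random(n)) / n
    if n >= 2:
        best = _min_pairwise_dist(u)
        for _ in range(iterations):
            j = int(rng.integers(d))
            a, b = rng.choice(n, size=2, replace=False)
            u[[a, b], j] = u[[b, a], j]
            cand = _min_pairwise_dist(u)
            if cand >= best:
                best = cand
            else:  # revert
                u[[a, b], j] = u[[b, a], j]
    design = scale_to_space(u, space)
    design.provenance = "maximin-lhd"
    design.seed = seed
    return design


def write_design(design: DesignMatrix, path) -> None:
    """Write a design as CSV at full precision (lossless round trip)."""
    design.frame.to_csv(path, index=False, float_format="%.17g")


def read_design(path, space: ParameterSpace | None = None) -> DesignMatrix:
    """Read a design CSV, enforcing the canonical column schema."""
    space = space or default_space()
    frame = pd.read_csv(path, float_precision="round_trip")
    if tuple(frame.columns) != tuple(space.names):
        raise SchemaError(
            f"design columns must be {list(space.names)}, got {list(frame.columns)}"
        )
    return DesignMatrix(frame=frame.astype(float), provenance="file")
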