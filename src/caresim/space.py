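"""The swept parameter space of the social-care simulator.

Ten policy-relevant parameters control care need, care supply and
retirement behaviour.  Each has a default (the simulator's baseline) and a
sweep range chosen so the simulated population neither collapses nor
explodes.  The ordered list of names doubles as the feature schema for the
surrogate models and the column schema of every design/run CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpaceError

__all__ = ["Parameter", "ParameterSpace", "PARAM_NAMES", "default_space"]


@dataclass(frozen=True)
class Parameter:
    """One swept simulator input: a name, bounds and an integrality flag."""

    name: str
    lower: float
    upper: float
    default: float
    integer: bool = False

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InvalidSpaceError(
                f"{self.name}: lower bound {self.lower} must be < upper {self.upper}"
            )


#: (name, lower, upper, default, integer) for the ten swept parameters.
_TABLE = [
    ("ageingParentsMoveInWithKids", 0.1, 0.8, 0.1, False),
    ("baseCareProb", 0.0002, 0.0016, 0.0002, False),
    ("retiredHours", 40.0, 80.0, 60.0, False),
    ("ageOfRetirement", 55, 75, 65, True),
    ("personCareProb", 0.0002, 0.0016, 0.0008, False),
    ("maleAgeCareScaling", 10.0, 25.0, 18.0, False),
    ("femaleAgeCareScaling", 10.0, 25.0, 19.0, False),
    ("childHours", 1.0, 10.0, 5.0, False),
    ("homeAdultHours", 5.0, 50.0, 30.0, False),
    ("workingAdultHours", 5.0, 40.0, 25.0, False),
]

PARAM_NAMES: tuple[str, ...] = tuple(row[0] for row in _TABLE)


@dataclass(frozen=True)
class ParameterSpace:
    """An ordered collection of :class:`Parameter` bounds.

    The default instance (see :func:`default_space`) carries the ten swept
    simulator parameters in canonical column order.
    """

    parameters: tuple[Parameter, ...] = field(
        default_factory=lambda: tuple(
            Parameter(name, lo, hi, d, i) for name, lo, hi, d, i in _TABLE
        )
    )

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise InvalidSpaceError("parameter names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def dim(self) -> int:
        return len(self.parameters)

    @property
    def lowers(self) -> np.ndarray:
        return np.array([p.lower for p in self.parameters], dtype=float)

    @property
    def uppers(self) -> np.ndarray:
        return np.array([p.upper for p in self.parameters], dtype=float)

    @property
    def defaults(self) -> np.ndarray:
        return np.array([p.default for p in self.parameters], dtype=float)

    @property
    def integer_mask(self) -> np.ndarray:
        return np.array([p.integer for p in self.parameters], dtype=bool)

    def __iter__(self):
        return iter(self.parameters)

    def __len__(self) -> int:
        return len(self.parameters)

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Row-wise check that ``values`` (n x dim) lies inside the bounds."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        return np.all(
            (values >= self.lowers) & (values <= self.uppers), axis=1
        )


def default_space() -> ParameterSpace:
    """The canonical ten-parameter sweep space of the care simulator."""
    return ParameterSpace()
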