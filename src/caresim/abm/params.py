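"""The ten swept care-policy parameters."""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from ..errors import InvalidParameterError
from ..space import ParameterSpace, default_space

__all__ = ["CareParams"]


@dataclass(frozen=True)
class CareParams:
    """The policy parameters swept when generating simulator run data.

    Probabilities are annual and dimensionless; the ``*Hours`` parameters
    are weekly hours of informal care a person in that situation can offer;
    the two ``*AgeCareScaling`` values are e-folding ages (years) of the
    exponential age gradient of care need.
    """

    ageingParentsMoveInWithKids: float = 0.1
    baseCareProb: float = 0.0002
    retiredHours: float = 60.0
    ageOfRetirement: int = 65
    personCareProb: float = 0.0008
    maleAgeCareScaling: float = 18.0
    femaleAgeCareScaling: float = 19.0
    childHours: float = 5.0
    homeAdultHours: float = 30.0
    workingAdultHours: float = 25.0

    def __post_init__(self):
        for prob_name in ("ageingParentsMoveInWithKids", "baseCareProb", "personCareProb"):
            v = getattr(self, prob_name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{prob_name}={v} outside [0, 1]")
        for hours_name in ("retiredHours", "childHours", "homeAdultHours", "workingAdultHours"):
            v = getattr(self, hours_name)
            if v < 0:
                raise InvalidParameterError(f"{hours_name}={v} must be >= 0")
        for scale_name in ("maleAgeCareScaling", "femaleAgeCareScaling"):
            v = getattr(self, scale_name)
            if v <= 0:
                raise InvalidParameterError(f"{scale_name}={v} must be > 0")
        if self.ageOfRetirement < 16:
            raise InvalidParameterError(
                f"ageOfRetirement={self.ageOfRetirement} must be >= 16"
            )

    def as_array(self) -> np.ndarray:
        """The parameter vector in canonical column order."""
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, values) -> "CareParams":
        values = np.asarray(values, dtype=float).ravel()
        names = [f.name for f in fields(cls)]
        if values.size != len(names):
            raise InvalidParameterError(
                f"expected {len(names)} parameter values, got {values.size}"
            )
        kwargs = dict(zip(names, values.tolist()))
        kwargs["ageOfRetirement"] = int(round(kwargs["ageOfRetirement"]))
        return cls(**kwargs)

    def in_range(self, space: ParameterSpace | None = None) -> bool:
        """Whether every value lies inside its sweep range."""
        space = space or default_space()
        return bool(space.contains(self.as_array())[0])
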