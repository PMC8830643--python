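"""Demographic configuration of the simulator.

Everything that is *not* swept by the surrogate experiments lives here:
vital rates, household formation rules, the synthetic town grid, the care
need schedule and the pricing of unmet need.  The values are deliberately
stylised — they describe a self-contained synthetic population, not any
particular country — and were chosen so that a simulation started in 1860
carries a stable population through to 2050.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import InvalidConfigError

__all__ = ["DemographyConfig", "default_density_weights"]

#: Weekly care hours required at need levels 0..4.
CARE_NEED_HOURS = (0.0, 8.0, 16.0, 30.0, 80.0)


def default_density_weights(rows: int = 8, cols: int = 8) -> np.ndarray:
    """A smooth unimodal density surface over the town grid.

    Towns near the grid centre are more populous, mimicking the clustering
    of households into cities.  Weights are normalised to sum to one.
    """
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    w = np.exp(-0.35 * np.sqrt(r**2 + c**2))
    return w / w.sum()


@dataclass
class DemographyConfig:
    """Fixed (non-swept) parameters of the demographic simulator.

    Mortality follows a Makeham–Gompertz hazard
    ``A + B * exp(C * age)`` per year, amplified 5% per care-need level.
    ``careNeedHours`` maps need level 0..4 to weekly hours of care
    required.  ``kinProvisionScaleSameTown`` / ``OtherTown`` multiply
    ``baseCareProb`` to give the annual probability that an out-of-household
    parent/adult-child kin pair provides care.
    """

    startYear: int = 1860
    endYear: int = 2050
    initialCouples: int = 200
    townRows: int = 8
    townCols: int = 8
    densityWeights: np.ndarray | None = None

    makehamA: float = 1e-4
    gompertzB: float = 8e-6
    gompertzC: float = 0.095

    birthProb: float = 0.13
    fertileAgeMin: int = 17
    fertileAgeMax: int = 42

    partnerFormProb: float = 0.12
    partnerDissolveProb: float = 0.015
    leaveHomeProb: float = 0.3
    householdMigrationProb: float = 0.04

    employmentEntryProb: float = 0.75
    jobLossProb: float = 0.05
    reemploymentProb: float = 0.35

    careNeedHours: tuple = CARE_NEED_HOURS
    kinProvisionScaleSameTown: float = 400.0
    kinProvisionScaleOtherTown: float = 80.0
    outOfHouseholdCapacityFactor: float = 0.5

    pricePerHour: float = 16.7
    seed: int = 0

    def __post_init__(self):
        if self.endYear <= self.startYear:
            raise InvalidConfigError(
                f"endYear {self.endYear} must be > startYear {self.startYear}"
            )
        if self.initialCouples <= 0:
            raise InvalidConfigError("initialCouples must be positive")
        if self.densityWeights is None:
            self.densityWeights = default_density_weights(self.townRows, self.townCols)
        else:
            self.densityWeights = np.asarray(self.densityWeights, dtype=float)
            if self.densityWeights.shape != (self.townRows, self.townCols):
                raise InvalidConfigError(
                    "densityWeights shape must match townRows x townCols"
                )
            if np.any(self.densityWeights < 0):
                raise InvalidConfigError("densityWeights must be non-negative")
            total = self.densityWeights.sum()
            if not np.isclose(total, 1.0, atol=1e-8):
                raise InvalidConfigError("densityWeights must sum to 1")
        hours = tuple(float(h) for h in self.careNeedHours)
        if len(hours) != 5 or hours[0] != 0.0 or any(
            b <= a for a, b in zip(hours, hours[1:])
        ):
            raise InvalidConfigError(
                "careNeedHours must be strictly increasing with 0 at level 0"
            )
        self.careNeedHours = hours
        for name in ("birthProb", "partnerFormProb", "partnerDissolveProb",
                     "leaveHomeProb", "householdMigrationProb",
                     "employmentEntryProb", "jobLossProb", "reemploymentProb"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        if self.pricePerHour < 0:
            raise InvalidConfigError("pricePerHour must be >= 0")

    @property
    def nTowns(self) -> int:
        return self.townRows * self.townCols

    @property
    def townProbs(self) -> np.ndarray:
        return self.densityWeights.ravel()

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["densityWeights"] = np.asarray(self.densityWeights).tolist()
        d["careNeedHours"] = list(self.careNeedHours)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "densityWeights" in d and d["densityWeights"] is not None:
            d["densityWeights"] = np.asarray(d["densityWeights"], dtype=float)
        if "careNeedHours" in d:
            d["careNeedHours"] = tuple(d["careNeedHours"])
        return cls(**d)
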