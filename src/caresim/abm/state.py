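"""Population state: a structure-of-arrays over agents plus a household table.

Agents are stored column-wise in flat numpy arrays so that the yearly update
can be fully vectorised.  An agent's id is its index; ids are never reused,
and new agents (births) are appended, so ascending id equals creation order.
Households are likewise a flat table of town ids; a household with no living
members is inactive by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidConfigError
from .config import DemographyConfig
from .params import CareParams

__all__ = ["PopulationState", "init_population"]

# employment codes
MINOR, EMPLOYED, UNEMPLOYED, RETIRED = 0, 1, 2, 3
# sex codes
MALE, FEMALE = 0, 1


@dataclass
class PopulationState:
    """Mutable simulation state (arrays indexed by agent id)."""

    year: int
    sex: np.ndarray        # int8, 0 male / 1 female
    age: np.ndarray        # int32 years
    alive: np.ndarray      # bool
    care: np.ndarray       # int8 need level 0..4
    emp: np.ndarray        # int8 employment code
    hh: np.ndarray         # int32 household id (-1 once dead)
    partner: np.ndarray    # int32 agent id or -1
    mother: np.ndarray     # int32 agent id or -1
    father: np.ndarray     # int32 agent id or -1
    hh_town: np.ndarray    # int32, town id per household
    # per-year care accounting (filled by allocate_care / step_year)
    required: np.ndarray | None = None
    met: np.ndarray | None = None
    last_cost: float = 0.0

    @property
    def n_agents(self) -> int:
        return self.age.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def alive_ids(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def household_sizes(self) -> np.ndarray:
        """Living members per household id."""
        return np.bincount(self.hh[self.alive], minlength=self.hh_town.size)

    def append_agents(self, sex, age, care, emp, hh, mother, father) -> np.ndarray:
        """Append new agents; returns their ids."""
        k = len(sex)
        start = self.n_agents
        self.sex = np.concatenate([self.sex, np.asarray(sex, np.int8)])
        self.age = np.concatenate([self.age, np.asarray(age, np.int32)])
        self.alive = np.concatenate([self.alive, np.ones(k, bool)])
        self.care = np.concatenate([self.care, np.asarray(care, np.int8)])
        self.emp = np.concatenate([self.emp, np.asarray(emp, np.int8)])
        self.hh = np.concatenate([self.hh, np.asarray(hh, np.int32)])
        self.partner = np.concatenate([self.partner, np.full(k, -1, np.int32)])
        self.mother = np.concatenate([self.mother, np.asarray(mother, np.int32)])
        self.father = np.concatenate([self.father, np.asarray(father, np.int32)])
        return np.arange(start, start + k)

    def new_households(self, towns) -> np.ndarray:
        """Create households in the given towns; returns their ids."""
        towns = np.asarray(towns, np.int32)
        start = self.hh_town.size
        self.hh_town = np.concatenate([self.hh_town, towns])
        return np.arange(start, start + towns.size)

    def copy(self) -> "PopulationState":
        return PopulationState(
            year=self.year,
            sex=self.sex.copy(), age=self.age.copy(), alive=self.alive.copy(),
            care=self.care.copy(), emp=self.emp.copy(), hh=self.hh.copy(),
            partner=self.partner.copy(), mother=self.mother.copy(),
            father=self.father.copy(), hh_town=self.hh_town.copy(),
            required=None if self.required is None else self.required.copy(),
            met=None if self.met is None else self.met.copy(),
            last_cost=self.last_cost,
        )


def init_population(
    config: DemographyConfig,
    rng: np.random.Generator,
    params: CareParams | None = None,
) -> PopulationState:
    """Build the random initial population.

    ``initialCouples`` two-person households of partnered adults.  Partner
    ages are uniform on [20, 40] with an age gap of at most 5 years;
    households are placed on towns with probability proportional to the
    density weights; everyone starts care-free.
    """
    if config.initialCouples <= 0:
        raise InvalidConfigError("initialCouples must be positive")
    params = params or CareParams()
    n_couples = config.initialCouples
    n = 2 * n_couples

    age_f = rng.integers(20, 41, size=n_couples)
    gap = rng.integers(-5, 6, size=n_couples)
    age_m = np.clip(age_f + gap, 20, 40)

    towns = rng.choice(config.nTowns, size=n_couples, p=config.townProbs)

    sex = np.empty(n, np.int8)
    sex[0::2] = FEMALE
    sex[1::2] = MALE
    age = np.empty(n, np.int32)
    age[0::2] = age_f
    age[1::2] = age_m

    emp = np.where(rng.random(n) < config.employmentEntryProb, EMPLOYED, UNEMPLOYED)
    retired = age >= params.ageOfRetirement  # possible only if ageOfRetirement <= 40
    emp[retired] = RETIRED

    hh = np.repeat(np.arange(n_couples, dtype=np.int32), 2)
    partner = np.empty(n, np.int32)
    partner[0::2] = np.arange(1, n, 2)
    partner[1::2] = np.arange(0, n, 2)

    return PopulationState(
        year=config.startYear,
        sex=sex,
        age=age,
        alive=np.ones(n, bool),
        care=np.zeros(n, np.int8),
        emp=emp.astype(np.int8),
        hh=hh,
        partner=partner,
        mother=np.full(n, -1, np.int32),
        father=np.full(n, -1, np.int32),
        hh_town=towns.astype(np.int32),
    )
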