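"""The yearly update loop and run-level drivers.

A simulation starts from a random initial population (default year 1860)
and advances in one-year steps to the end year (default 2050).  Each step
applies, in a fixed order and with all draws taken from a single seeded RNG
stream, ageing, mortality, births, partnership formation and dissolution,
home-leaving, household migration, employment transitions, care-need
progression, elderly parents moving in with adult children, care
allocation and cost accounting.  The fixed order and single stream make the
simulator deterministic given its seed: identical (parameters, config,
seed) always yield identical runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InvalidConfigError, SchemaError
from ..space import PARAM_NAMES, default_space
from .care import allocate_care, annual_cost, care_need_transition_prob
from .config import DemographyConfig
from .params import CareParams
from .state import (EMPLOYED, FEMALE, MALE, MINOR, RETIRED, UNEMPLOYED,
                    PopulationState, init_population)

__all__ = ["RunRecord", "RunTable", "step_year", "run_simulation", "batch_run",
           "RUN_COLUMNS"]

log = logging.getLogger(__name__)

#: Canonical run-table schema: ten parameters, the seed, the scalar output.
RUN_COLUMNS = tuple(PARAM_NAMES) + ("seed", "output")


# --------------------------------------------------------------------------
# yearly step
# --------------------------------------------------------------------------

def _mortality(state, config, rng):
    alive = state.alive
    ids = np.flatnonzero(alive)
    if ids.size == 0:
        return
    age = state.age[ids]
    hazard = np.minimum(
        1.0, config.makehamA + config.gompertzB * np.exp(config.gompertzC * age)
    )
    p = np.minimum(1.0, hazard * (1.0 + 0.05 * state.care[ids]))
    dead = ids[rng.random(ids.size) < p]
    if dead.size == 0:
        return
    state.alive[dead] = False
    widowed = state.partner[dead]
    widowed = widowed[widowed >= 0]
    state.partner[widowed] = -1
    state.partner[dead] = -1


def _births(state, config, rng):
    mothers = np.flatnonzero(
        state.alive
        & (state.sex == FEMALE)
        & (state.partner >= 0)
        & (state.age >= config.fertileAgeMin)
        & (state.age <= config.fertileAgeMax)
    )
    if mothers.size == 0:
        return
    mothers = mothers[rng.random(mothers.size) < config.birthProb]
    k = mothers.size
    if k == 0:
        return
    state.append_agents(
        sex=rng.integers(0, 2, k).astype(np.int8),
        age=np.zeros(k, np.int32),
        care=np.zeros(k, np.int8),
        emp=np.full(k, MINOR, np.int8),
        hh=state.hh[mothers],
        mother=mothers,
        father=state.partner[mothers],
    )


def _match_pools(males, females, towns_m, towns_f, rng):
    """Pair male/female candidates, same-town first, leftovers globally."""
    pairs_m, pairs_f = [], []
    used_m = np.zeros(males.size, bool)
    used_f = np.zeros(females.size, bool)
    common = np.intersect1d(towns_m, towns_f)
    for t in common:
        mi = np.flatnonzero((towns_m == t) & ~used_m)
        fi = np.flatnonzero((towns_f == t) & ~used_f)
        k = min(mi.size, fi.size)
        if k == 0:
            continue
        mi = mi[rng.permutation(mi.size)[:k]]
        fi = fi[rng.permutation(fi.size)[:k]]
        used_m[mi] = True
        used_f[fi] = True
        pairs_m.append(males[mi])
        pairs_f.append(females[fi])
    mi = np.flatnonzero(~used_m)
    fi = np.flatnonzero(~used_f)
    k = min(mi.size, fi.size)
    if k:
        mi = mi[rng.permutation(mi.size)[:k]]
        fi = fi[rng.permutation(fi.size)[:k]]
        pairs_m.append(males[mi])
        pairs_f.append(females[fi])
    if not pairs_m:
        return (np.empty(0, np.int64),) * 2
    return np.concatenate(pairs_m), np.concatenate(pairs_f)


def _partnership_formation(state, config, rng):
    eligible = np.flatnonzero(state.alive & (state.age >= 18) & (state.partner < 0))
    if eligible.size == 0:
        return
    pool = eligible[rng.random(eligible.size) < config.partnerFormProb]
    males = pool[state.sex[pool] == MALE]
    females = pool[state.sex[pool] == FEMALE]
    if males.size == 0 or females.size == 0:
        return
    towns_m = state.hh_town[state.hh[males]]
    towns_f = state.hh_town[state.hh[females]]
    m_arr, f_arr = _match_pools(males, females, towns_m, towns_f, rng)
    if m_arr.size == 0:
        return
    old_hh_f = state.hh[f_arr].copy()
    new_hh = state.new_households(state.hh_town[old_hh_f])
    state.partner[m_arr] = f_arr
    state.partner[f_arr] = m_arr
    state.hh[m_arr] = new_hh
    state.hh[f_arr] = new_hh
    # the female partner's co-resident minor children move with her
    kids = np.flatnonzero(state.alive & (state.age < 18) & (state.mother >= 0))
    if kids.size:
        pos = np.full(state.n_agents, -1, np.int64)
        pos[f_arr] = np.arange(f_arr.size)
        mp = pos[state.mother[kids]]
        sel = (mp >= 0) & (state.hh[kids] == old_hh_f[np.maximum(mp, 0)])
        state.hh[kids[sel]] = new_hh[mp[sel]]


def _partnership_dissolution(state, config, rng):
    ids = np.flatnonzero(state.alive & (state.partner >= 0))
    ids = ids[ids < state.partner[ids]]  # one entry per couple
    if ids.size == 0:
        return
    split = ids[rng.random(ids.size) < config.partnerDissolveProb]
    if split.size == 0:
        return
    a, b = split, state.partner[split]
    # the male partner leaves and forms a new household in the same town
    leaver = np.where(state.sex[a] == MALE, a, b)
    state.partner[a] = -1
    state.partner[b] = -1
    new_hh = state.new_households(state.hh_town[state.hh[leaver]])
    state.hh[leaver] = new_hh


def _home_leaving(state, config, rng):
    ids = np.flatnonzero(state.alive & (state.age >= 18) & (state.partner < 0))
    if ids.size == 0:
        return
    with_parent = np.zeros(ids.size, bool)
    for parent in (state.mother, state.father):
        p = parent[ids]
        ok = p >= 0
        with_parent |= ok & state.alive[np.maximum(p, 0)] & (
            state.hh[np.maximum(p, 0)] == state.hh[ids]
        )
    ids = ids[with_parent]
    if ids.size == 0:
        return
    leavers = ids[rng.random(ids.size) < config.leaveHomeProb]
    if leavers.size:
        new_hh = state.new_households(state.hh_town[state.hh[leavers]])
        state.hh[leavers] = new_hh


def _migration(state, config, rng):
    sizes = state.household_sizes()
    active = np.flatnonzero(sizes > 0)
    if active.size == 0:
        return
    movers = active[rng.random(active.size) < config.householdMigrationProb]
    if movers.size:
        state.hh_town[movers] = rng.choice(
            config.nTowns, size=movers.size, p=config.townProbs
        ).astype(np.int32)


def _employment(state, params, config, rng):
    # labour-market entry at 16
    entering = np.flatnonzero(state.alive & (state.emp == MINOR) & (state.age >= 16))
    if entering.size:
        employed = rng.random(entering.size) < config.employmentEntryProb
        state.emp[entering] = np.where(employed, EMPLOYED, UNEMPLOYED)
    # job loss / re-employment for working-age adults
    working_age = state.alive & (state.age < params.ageOfRetirement)
    losers = np.flatnonzero(working_age & (state.emp == EMPLOYED))
    if losers.size:
        hit = losers[rng.random(losers.size) < config.jobLossProb]
        state.emp[hit] = UNEMPLOYED
    seekers = np.flatnonzero(working_age & (state.emp == UNEMPLOYED))
    if seekers.size:
        hired = seekers[rng.random(seekers.size) < config.reemploymentProb]
        state.emp[hired] = EMPLOYED
    # retirement
    retiring = state.alive & (state.emp != MINOR) & (
        state.age >= params.ageOfRetirement
    )
    state.emp[retiring] = RETIRED


def _care_progression(state, params, rng):
    ids = np.flatnonzero(state.alive & (state.age >= 16) & (state.care < 4))
    if ids.size == 0:
        return
    p = care_need_transition_prob(state.age[ids], state.sex[ids], params)
    worsen = ids[rng.random(ids.size) < p]
    state.care[worsen] += 1


def _parents_move_in(state, params, rng):
    n_hh = state.hh_town.size
    adults = state.alive & (state.age >= 18)
    sizes = state.household_sizes()
    has_adult = np.bincount(state.hh[adults], minlength=n_hh) > 0
    young = adults & (state.age < params.ageOfRetirement)
    has_young = np.bincount(state.hh[young], minlength=n_hh) > 0
    needy = state.alive & (state.care >= 2)
    has_need = np.bincount(state.hh[needy], minlength=n_hh) > 0
    cands = np.flatnonzero((sizes > 0) & has_adult & ~has_young & has_need)
    if cands.size == 0:
        return
    draws = rng.random(cands.size)
    moving = cands[draws < params.ageingParentsMoveInWithKids]
    if moving.size == 0:
        return
    # household id of each agent's living parents (-1 if none)
    adult_ids = np.flatnonzero(adults)
    parent_hh = np.full((2, adult_ids.size), -1, np.int64)
    for row, parent in enumerate((state.mother, state.father)):
        p = parent[adult_ids]
        ok = (p >= 0) & state.alive[np.maximum(p, 0)]
        parent_hh[row, ok] = state.hh[p[ok]]
    own_hh = state.hh[adult_ids]
    for h in moving:
        kids = adult_ids[
            ((parent_hh[0] == h) | (parent_hh[1] == h)) & (own_hh != h)
        ]
        if kids.size == 0:
            continue
        target = kids[rng.integers(kids.size)]
        members = np.flatnonzero(state.alive & (state.hh == h))
        state.hh[members] = state.hh[target]


def step_year(
    state: PopulationState,
    params: CareParams,
    config: DemographyConfig,
    rng: np.random.Generator,
    care_rng: np.random.Generator | None = None,
    allocate: bool = True,
) -> PopulationState:
    """Advance the population by one year (in place; returns the state).

    Demographic draws come from ``rng``; the probabilistic kin-provision
    draws of care allocation come from ``care_rng`` (default: the same
    stream).  Because allocation does not feed back into the demography,
    drivers that only need the end-year cost may skip intermediate-year
    allocation (``allocate=False``) without changing the trajectory,
    provided they give allocation its own stream.
    """
    state.year += 1
    state.age[state.alive] += 1
    _mortality(state, config, rng)
    _births(state, config, rng)
    _partnership_formation(state, config, rng)
    _partnership_dissolution(state, config, rng)
    _home_leaving(state, config, rng)
    _migration(state, config, rng)
    _employment(state, params, config, rng)
    _care_progression(state, params, rng)
    _parents_move_in(state, params, rng)
    if allocate:
        allocate_care(state, params, config, care_rng if care_rng is not None else rng)
        state.last_cost = annual_cost(state, config)
    return state


# --------------------------------------------------------------------------
# run-level drivers
# --------------------------------------------------------------------------

@dataclass
class RunRecord:
    """One simulator execution: inputs, seed, and the scalar cost output."""

    params: CareParams
    seed: int
    output: float  # per-capita annual cost of unmet care at the end year
    finalPopulation: int
    yearlySeries: np.ndarray | None = None


@dataclass
class RunTable:
    """An ordered collection of runs in the canonical 12-column schema."""

    frame: pd.DataFrame

    def __post_init__(self):
        if tuple(self.frame.columns) != RUN_COLUMNS:
            raise SchemaError(
                f"run table columns must be {list(RUN_COLUMNS)}, "
                f"got {list(self.frame.columns)}"
            )

    @classmethod
    def from_records(cls, records: list[RunRecord]) -> "RunTable":
        rows = [
            list(r.params.as_array()) + [r.seed, r.output] for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(RUN_COLUMNS))
        frame["seed"] = frame["seed"].astype(int)
        return cls(frame)

    @property
    def X(self) -> np.ndarray:
        """The n x 10 feature matrix of swept parameters."""
        return self.frame[list(PARAM_NAMES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """The per-capita annual cost outputs."""
        return self.frame["output"].to_numpy(dtype=float)

    @property
    def seeds(self) -> np.ndarray:
        return self.frame["seed"].to_numpy(dtype=int)

    def __len__(self) -> int:
        return len(self.frame)


def run_simulation(
    params: CareParams,
    config: DemographyConfig,
    seed: int,
    record_series: bool = False,
) -> RunRecord:
    """Execute one full run and record the end-year per-capita cost.

    Parameters outside their sweep ranges are allowed but logged: outside
    those bounds the population can collapse or explode.
    """
    if config.endYear <= config.startYear:
        raise InvalidConfigError("endYear must be > startYear")
    if not params.in_range(default_space()):
        log.warning("run %s: parameters outside sweep ranges", seed)
    seed = int(seed)
    rng = np.random.default_rng(seed)
    state = init_population(config, rng, params)
    series = []
    for year in range(config.startYear + 1, config.endYear + 1):
        do_alloc = record_series or year == config.endYear
        care_rng = np.random.default_rng([seed, year]) if do_alloc else None
        step_year(state, params, config, rng, care_rng=care_rng, allocate=do_alloc)
        if record_series:
            series.append(state.last_cost)
    return RunRecord(
        params=params,
        seed=int(seed),
        output=float(state.last_cost),
        finalPopulation=state.n_alive,
        yearlySeries=np.asarray(series) if record_series else None,
    )


def _design_values(design) -> np.ndarray:
    """Accept a DesignMatrix or a DataFrame with the canonical ten columns."""
    if hasattr(design, "frame"):
        frame = design.frame
    elif isinstance(design, pd.DataFrame):
        frame = design
    else:
        return np.atleast_2d(np.asarray(design, dtype=float))
    if tuple(frame.columns) != tuple(PARAM_NAMES):
        raise SchemaError(
            f"design columns must be {list(PARAM_NAMES)}, got {list(frame.columns)}"
        )
    return frame.to_numpy(dtype=float)


def batch_run(design, config: DemographyConfig, seeds) -> RunTable:
    """Run the simulator once per design row, preserving row order.

    ``seeds`` is either a sequence with one seed per row or a single base
    seed that expands deterministically to ``base + row_index``.
    """
    values = _design_values(design)
    n = values.shape[0]
    if np.isscalar(seeds):
        seeds = [int(seeds) + i for i in range(n)]
    seeds = [int(s) for s in seeds]
    if len(seeds) != n:
        raise InvalidConfigError(f"need {n} seeds, got {len(seeds)}")
    records = []
    for row, seed in zip(values, seeds):
        records.append(run_simulation(CareParams.from_array(row), config, seed))
    return RunTable.from_records(records)
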