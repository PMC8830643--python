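"""Care need, care supply and the yearly allocation of informal care.

Need follows an exponential age gradient: the annual probability that an
adult develops (or worsens) a long-term limiting condition is
``min(1, personCareProb * exp(age / S_sex))`` where ``S_sex`` is the
sex-specific age-scaling parameter.  Supply depends on employment status
and own health.  Allocation happens in two passes: co-resident carers pool
their capacity for the neediest household members first; then
parent/adult-child kin pairs that span households provide care
probabilistically, at reduced capacity, with the probability scaled down
for kin living in a different town.
"""

from __future__ import annotations

import logging

import numpy as np

from ..errors import InvalidParameterError
from .config import DemographyConfig
from .params import CareParams
from .state import EMPLOYED, FEMALE, MALE, MINOR, RETIRED, UNEMPLOYED, PopulationState

__all__ = [
    "care_need_transition_prob",
    "weekly_supply_capacity",
    "supply_capacities",
    "allocate_care",
    "annual_cost",
]

log = logging.getLogger(__name__)

_SEX_CODES = {"male": MALE, "female": FEMALE, MALE: MALE, FEMALE: FEMALE}


def care_need_transition_prob(age, sex, params: CareParams):
    """Annual probability that an agent's care need rises one level.

    Vectorised over ``age``.  ``sex`` is ``"male"``/``"female"`` (or the
    integer codes 0/1).  Minors (< 16) never transition; callers filter them
    out before drawing.
    """
    code = _SEX_CODES[sex] if not isinstance(sex, np.ndarray) else sex
    scale = np.where(
        np.asarray(code) == MALE, params.maleAgeCareScaling, params.femaleAgeCareScaling
    )
    if np.any(scale <= 0):
        raise InvalidParameterError("age-care scaling must be > 0")
    p = np.minimum(1.0, params.personCareProb * np.exp(np.asarray(age) / scale))
    return float(p) if p.ndim == 0 else p


def supply_capacities(state: PopulationState, params: CareParams) -> np.ndarray:
    """Weekly care-supply capacity (hours) for every agent; 0 for the dead.

    Retired agents offer ``retiredHours``; unemployed adults
    ``homeAdultHours``; employed adults ``workingAdultHours``; minors aged
    10-15 who live with a parent ``childHours``; younger children nothing.
    Own need discounts capacity: level 1 halves it, level >= 2 removes it.
    """
    cap = np.zeros(state.n_agents)
    cap[state.emp == RETIRED] = params.retiredHours
    cap[state.emp == UNEMPLOYED] = params.homeAdultHours
    cap[state.emp == EMPLOYED] = params.workingAdultHours

    helper_kid = (state.emp == MINOR) & (state.age >= 10) & (state.age <= 15)
    if np.any(helper_kid):
        ids = np.flatnonzero(helper_kid)
        with_parent = np.zeros(ids.size, bool)
        for parent in (state.mother, state.father):
            p = parent[ids]
            ok = p >= 0
            with_parent |= ok & state.alive[np.maximum(p, 0)] & (
                state.hh[np.maximum(p, 0)] == state.hh[ids]
            )
        cap[ids[with_parent]] = params.childHours

    cap[state.care == 1] *= 0.5
    cap[state.care >= 2] = 0.0
    cap[~state.alive] = 0.0
    return cap


def weekly_supply_capacity(agent, params: CareParams) -> float:
    """Capacity of a single agent (an object with the agent fields).

    Convenience scalar form of :func:`supply_capacities`; ``agent`` needs
    ``alive``, ``employment``, ``age``, ``careNeedLevel`` and
    ``livesWithParent`` attributes.
    """
    if not agent.alive:
        return 0.0
    emp = agent.employment
    if emp == "retired" or emp == RETIRED:
        cap = params.retiredHours
    elif emp == "unemployed" or emp == UNEMPLOYED:
        cap = params.homeAdultHours
    elif emp == "employed" or emp == EMPLOYED:
        cap = params.workingAdultHours
    else:  # minor
        if 10 <= agent.age <= 15 and getattr(agent, "livesWithParent", False):
            cap = params.childHours
        else:
            cap = 0.0
    if agent.careNeedLevel == 1:
        cap *= 0.5
    elif agent.careNeedLevel >= 2:
        cap = 0.0
    return float(cap)


def _household_pass(state, req, cap):
    """Greedy within-household allocation, neediest members first.

    Returns (met, remaining_capacity_per_agent).
    """
    n_hh = state.hh_town.size
    met = np.zeros_like(req)

    needy = np.flatnonzero(state.alive & (req > 0))
    carers = np.flatnonzero(cap > 0)
    if needy.size == 0 or carers.size == 0:
        return met, cap.copy()

    hh_cap = np.bincount(state.hh[carers], weights=cap[carers], minlength=n_hh)

    # sort needy by household, then need level descending, then id
    order = np.lexsort((needy, -state.care[needy], state.hh[needy]))
    needy = needy[order]
    hh_n = state.hh[needy]
    # cumulative need before each needy agent within its household:
    # global cumsum minus the cumsum value at the household's first member
    cum = np.cumsum(req[needy])
    first = np.r_[True, hh_n[1:] != hh_n[:-1]]
    base = np.maximum.accumulate(np.where(first, cum - req[needy], 0.0))
    before = cum - req[needy] - base
    met[needy] = np.clip(hh_cap[hh_n] - before, 0.0, req[needy])

    # charge capacity use to carers within each household, ascending id
    used_hh = np.bincount(hh_n, weights=met[needy], minlength=n_hh)
    order_c = np.lexsort((carers, state.hh[carers]))
    carers = carers[order_c]
    hh_c = state.hh[carers]
    cum_c = np.cumsum(cap[carers])
    first_c = np.r_[True, hh_c[1:] != hh_c[:-1]]
    base_c = np.where(first_c, cum_c - cap[carers], 0.0)
    base_c = np.maximum.accumulate(base_c)
    before_c = cum_c - cap[carers] - base_c
    used = np.clip(used_hh[hh_c] - before_c, 0.0, cap[carers])
    remaining = cap.copy()
    remaining[carers] = cap[carers] - used
    return met, remaining


def _kin_pairs(state, unmet_mask):
    """Ordered (needy, carer) pairs: parent/adult-child links across households."""
    pairs = []
    alive = state.alive
    ids = np.flatnonzero(alive)
    for parent in (state.mother, state.father):
        p = parent[ids]
        ok = (p >= 0)
        child = ids[ok]
        par = p[ok]
        ok2 = alive[par] & (state.hh[child] != state.hh[par])
        child, par = child[ok2], par[ok2]
        adult_child = state.age[child] >= 18
        # parent cares for needy adult child
        m = unmet_mask[child] & adult_child
        pairs.append(np.stack([child[m], par[m]], axis=1))
        # adult child cares for needy parent
        m = unmet_mask[par] & adult_child
        pairs.append(np.stack([par[m], child[m]], axis=1))
    if not pairs:
        return np.empty((0, 2), np.int64)
    out = np.concatenate(pairs, axis=0)
    if out.size:
        out = out[np.lexsort((out[:, 1], out[:, 0]))]
    return out


def allocate_care(
    state: PopulationState,
    params: CareParams,
    config: DemographyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allocate informal care for the current year; returns met weekly hours.

    Also stores ``required`` and ``met`` on the state.  Met hours never
    exceed required hours and no carer supplies more than their capacity.
    """
    hours = np.asarray(config.careNeedHours)
    req = np.where(state.alive, hours[state.care], 0.0)
    cap = supply_capacities(state, params)

    met, remaining = _household_pass(state, req, cap)

    unmet = req - met
    pairs = _kin_pairs(state, unmet > 0)
    if pairs.shape[0]:
        p_same = min(1.0, config.kinProvisionScaleSameTown * params.baseCareProb)
        p_other = min(1.0, config.kinProvisionScaleOtherTown * params.baseCareProb)
        town = state.hh_town[state.hh]
        same = town[pairs[:, 0]] == town[pairs[:, 1]]
        p_pair = np.where(same, p_same, p_other)
        active = pairs[rng.random(pairs.shape[0]) < p_pair]
        factor = config.outOfHouseholdCapacityFactor
        for needy, carer in active:
            if unmet[needy] <= 0 or remaining[carer] <= 0:
                continue
            give = min(factor * remaining[carer], unmet[needy])
            met[needy] += give
            unmet[needy] -= give
            remaining[carer] -= give

    state.required = req
    state.met = met
    return met


def annual_cost(state: PopulationState, config: DemographyConfig) -> float:
    """Per-capita annual cost of unmet care: unmet weekly hours x 52 x price."""
    n_alive = state.n_alive
    if n_alive == 0:
        log.warning("annual_cost: no alive agents in %d; cost defined as 0", state.year)
        return 0.0
    if state.required is None or state.met is None:
        raise InvalidParameterError("allocate_care must run before annual_cost")
    unmet = np.maximum(0.0, state.required - state.met)
    return float(unmet[state.alive].sum() * 52.0 * config.pricePerHour / n_alive)
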