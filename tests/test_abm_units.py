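"""Unit behaviour of the care functions and population initialisation."""

import numpy as np
import pytest
from scipy.stats import chisquare

from caresim.abm.care import (
    allocate_care,
    annual_cost,
    care_need_transition_prob,
    supply_capacities,
)
from caresim.abm.config import DemographyConfig
from caresim.abm.params import CareParams
from caresim.abm.state import (EMPLOYED, FEMALE, MALE, MINOR, RETIRED,
                               UNEMPLOYED, PopulationState, init_population)
from caresim.errors import InvalidConfigError, InvalidParameterError


def make_state(*, sex, age, care, emp, hh, partner=None, mother=None,
               father=None, n_hh=None, towns=None, year=2000):
    """Hand-build a small population state for allocation tests."""
    n = len(age)
    n_hh = n_hh if n_hh is not None else max(hh) + 1
    return PopulationState(
        year=year,
        sex=np.array(sex, np.int8),
        age=np.array(age, np.int32),
        alive=np.ones(n, bool),
        care=np.array(care, np.int8),
        emp=np.array(emp, np.int8),
        hh=np.array(hh, np.int32),
        partner=np.array(partner if partner is not None else [-1] * n, np.int32),
        mother=np.array(mother if mother is not None else [-1] * n, np.int32),
        father=np.array(father if father is not None else [-1] * n, np.int32),
        hh_town=np.array(towns if towns is not None else [0] * n_hh, np.int32),
    )


class TestCareNeedTransition:
    def test_zero_base_rate(self):
        p = CareParams(personCareProb=0.0)
        assert care_need_transition_prob(80, "male", p) == 0.0
        assert care_need_transition_prob(30, "female", p) == 0.0

    def test_default_values_at_80(self):
        p = CareParams()
        male = care_need_transition_prob(80, "male", p)
        female = care_need_transition_prob(80, "female", p)
        assert male == pytest.approx(0.0008 * np.exp(80 / 18.0))
        assert male == pytest.approx(0.0681, abs=5e-4)
        assert female == pytest.approx(0.0539, abs=5e-4)
        assert female < male  # larger e-folding age means slower onset

    def test_monotonicity(self):
        p = CareParams()
        ages = np.arange(16, 100)
        probs = care_need_transition_prob(ages, np.zeros_like(ages), p)
        assert np.all(np.diff(probs) >= 0)
        assert care_need_transition_prob(
            80, "male", CareParams(personCareProb=0.0016)
        ) > care_need_transition_prob(80, "male", CareParams(personCareProb=0.0002))
        assert care_need_transition_prob(
            80, "male", CareParams(maleAgeCareScaling=25)
        ) < care_need_transition_prob(80, "male", CareParams(maleAgeCareScaling=10))

    def test_capped_at_one(self):
        assert care_need_transition_prob(500, "male", CareParams()) == 1.0

    def test_invalid_scaling_rejected(self):
        with pytest.raises(InvalidParameterError):
            CareParams(maleAgeCareScaling=0.0)


class TestSupplyCapacity:
    def test_employment_status_rates(self):
        p = CareParams()
        s = make_state(
            sex=[MALE] * 4, age=[70, 40, 40, 40], care=[0] * 4,
            emp=[RETIRED, EMPLOYED, UNEMPLOYED, MINOR], hh=[0, 0, 0, 0],
        )
        cap = supply_capacities(s, p)
        assert cap[0] == 60.0   # retired
        assert cap[1] == 25.0   # employed adult
        assert cap[2] == 30.0   # unemployed adult

    def test_own_need_discount(self):
        p = CareParams()
        s = make_state(sex=[MALE, MALE], age=[70, 70], care=[1, 3],
                       emp=[RETIRED, RETIRED], hh=[0, 0])
        cap = supply_capacities(s, p)
        assert cap[0] == 30.0  # level 1 halves
        assert cap[1] == 0.0   # substantial own need zeroes capacity

    def test_minor_helpers(self):
        p = CareParams()
        # child 12 living with its mother supplies childHours; child 8 none
        s = make_state(
            sex=[FEMALE, MALE, MALE], age=[40, 12, 8], care=[0, 0, 0],
            emp=[EMPLOYED, MINOR, MINOR], hh=[0, 0, 0],
            mother=[-1, 0, 0],
        )
        cap = supply_capacities(s, p)
        assert cap[1] == 5.0
        assert cap[2] == 0.0


class TestAllocation:
    def test_household_carer_meets_need(self):
        p, c = CareParams(), DemographyConfig()
        s = make_state(sex=[FEMALE, MALE], age=[80, 68], care=[2, 0],
                       emp=[RETIRED, RETIRED], hh=[0, 0])
        met = allocate_care(s, p, c, np.random.default_rng(0))
        assert met[0] == 16.0  # level-2 need fully met by 60 h of capacity
        assert annual_cost(s, c) == 0.0

    def test_capacity_shortfall(self):
        p, c = CareParams(), DemographyConfig()
        s = make_state(sex=[FEMALE, MALE], age=[85, 50], care=[4, 0],
                       emp=[RETIRED, EMPLOYED], hh=[0, 0])
        s.emp[0] = RETIRED
        met = allocate_care(s, p, c, np.random.default_rng(0))
        assert met[0] == 25.0          # employed adult supplies all 25 h
        assert s.required[0] - met[0] == 55.0

    def test_no_supply(self):
        p, c = CareParams(), DemographyConfig()
        s = make_state(sex=[FEMALE], age=[85], care=[3], emp=[RETIRED], hh=[0])
        s.emp[0] = RETIRED  # needy herself; level >= 2 removes her capacity
        met = allocate_care(s, p, c, np.random.default_rng(0))
        assert met[0] == 0.0

    def test_conservation_on_random_states(self):
        """Met <= required per agent; total met <= total capacity."""
        p, c = CareParams(), DemographyConfig()
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = 30
            s = make_state(
                sex=rng.integers(0, 2, n), age=rng.integers(0, 95, n),
                care=rng.integers(0, 5, n), emp=rng.integers(0, 4, n),
                hh=rng.integers(0, 8, n), n_hh=8,
                mother=rng.integers(-1, n, n), father=[-1] * n,
            )
            cap = supply_capacities(s, p)
            met = allocate_care(s, p, c, rng)
            assert np.all(met <= s.required + 1e-9)
            assert met.sum() <= cap.sum() + 1e-9
            assert annual_cost(s, c) >= 0.0


class TestAnnualCost:
    def test_priced_unmet_need(self):
        c = DemographyConfig()
        n = 100
        s = make_state(sex=[MALE] * n, age=[40] * n, care=[0] * n,
                       emp=[EMPLOYED] * n, hh=list(range(n)))
        s.required = np.zeros(n)
        s.met = np.zeros(n)
        s.required[0] = 50.0  # 50 unmet weekly hours in total
        assert annual_cost(s, c) == pytest.approx(50 * 52 * 16.7 / 100)
        assert annual_cost(s, c) == pytest.approx(434.2)

    def test_linear_in_price(self):
        base = DemographyConfig()
        double = DemographyConfig(pricePerHour=base.pricePerHour * 2)
        s = make_state(sex=[MALE], age=[80], care=[0], emp=[RETIRED], hh=[0])
        s.required, s.met = np.array([30.0]), np.array([10.0])
        assert annual_cost(s, double) == pytest.approx(2 * annual_cost(s, base))

    def test_empty_population_warns_zero(self, caplog):
        s = make_state(sex=[MALE], age=[80], care=[0], emp=[RETIRED], hh=[0])
        s.alive[:] = False
        s.required, s.met = np.zeros(1), np.zeros(1)
        with caplog.at_level("WARNING"):
            assert annual_cost(s, DemographyConfig()) == 0.0
        assert "cost defined as 0" in caplog.text


class TestInitPopulation:
    def test_counts_and_ages(self):
        cfg = DemographyConfig(initialCouples=200)
        s = init_population(cfg, np.random.default_rng(1))
        assert s.n_alive == 400
        assert np.unique(s.hh[s.alive]).size == 200
        assert np.all((s.age >= 20) & (s.age <= 40))
        gaps = np.abs(s.age[0::2] - s.age[1::2])
        assert np.all(gaps <= 5)
        assert np.all(s.care == 0)
        # partnership symmetry at construction
        assert np.all(s.partner[s.partner] == np.arange(s.n_agents))

    def test_invalid_couples(self):
        with pytest.raises(InvalidConfigError):
            DemographyConfig(initialCouples=0)

    def test_town_placement_frequencies(self):
        """Household placement follows the density weights (multinomial GOF)."""
        w = np.array([[0.4, 0.3], [0.2, 0.1]])
        cfg = DemographyConfig(initialCouples=5, townRows=2, townCols=2,
                               densityWeights=w)
        counts = np.zeros(4)
        for seed in range(1000):
            s = init_population(cfg, np.random.default_rng(seed))
            counts += np.bincount(s.hh_town, minlength=4)
        res = chisquare(counts, f_exp=counts.sum() * w.ravel())
        assert res.pvalue > 0.01
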