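"""Unit and property tests of the cohort Markov engine."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smokesim as ss
from smokesim.errors import HorizonError, ValidationError
from smokesim.grid import CURRENT, NEVER, N_AGES, PopulationGrid

from conftest import zero_demo, zero_rates


def uniform_grid(count=100.0):
    g = PopulationGrid(2022)
    g.counts[:, :, NEVER] = count
    return g


class TestEvolvePopulation:
    def test_pure_aging_conserves_everyone(self):
        g = uniform_grid()
        out = ss.evolve_population(g, zero_demo())
        assert out.year == 2023
        assert out.total() == pytest.approx(g.total())
        # each single-year cohort shifted up; the 85+ bin absorbed age 84
        assert np.all(out.counts[1:85] == g.counts[0:84])
        assert np.all(out.counts[85] == g.counts[85] + g.counts[84])
        assert out.counts[0].sum() == 0.0  # no fertility, no newborns

    def test_total_mortality_extinguishes_population(self):
        g = uniform_grid()
        demo = ss.DemographicRates(np.zeros(86), np.ones((86, 2)))
        out = ss.evolve_population(g, demo)
        assert out.total() == 0.0

    def test_two_age_toy_update_by_hand(self):
        # ages 0 and 1, 100 persons per sex per age; flat mortality 0.1;
        # fertility 0.5 at age 1; equal sex ratio at birth
        g = PopulationGrid(2022)
        g.counts[0, :, NEVER] = 100.0
        g.counts[1, :, NEVER] = 100.0
        fert = np.zeros(86)
        fert[1] = 0.5
        demo = ss.DemographicRates(fert, np.full((86, 2), 0.1),
                                   sex_ratio_at_birth=0.5)
        out = ss.evolve_population(g, demo)
        # births: 0.5 * (100 + 100 females at ages 0 and 1 -> only age-1 row)
        assert out.counts[0, 0, NEVER] == pytest.approx(0.5 * 100 * 0.5)  # 25 boys
        assert out.counts[0, 1, NEVER] == pytest.approx(25.0)
        assert out.counts[1, 0, NEVER] == pytest.approx(90.0)  # survivors of age 0
        assert out.counts[2, 0, NEVER] == pytest.approx(90.0)  # survivors of age 1

    def test_mortality_multiplier_is_state_specific(self):
        g = PopulationGrid(2022)
        g.counts[40, 0, NEVER] = 100.0
        g.counts[40, 0, CURRENT] = 100.0
        demo = ss.DemographicRates(
            np.zeros(86), np.full((86, 2), 0.1),
            mortality_multiplier=np.array([1.0, 2.0, 1, 1, 1, 1, 1.0]),
        )
        out = ss.evolve_population(g, demo)
        assert out.counts[41, 0, NEVER] == pytest.approx(90.0)
        assert out.counts[41, 0, CURRENT] == pytest.approx(80.0)

    def test_horizon_overflow_raises(self):
        with pytest.raises(HorizonError):
            ss.evolve_population(uniform_grid(), zero_demo(), max_year=2022)

    def test_invalid_rates_raise(self):
        demo = zero_demo()
        demo.fertility = demo.fertility - 1.0
        with pytest.raises(ValidationError):
            ss.evolve_population(uniform_grid(), demo)


class TestSmokingTransitions:
    def test_zero_rates_are_identity(self, toy_grid):
        out = ss.apply_smoking_transitions(toy_grid, zero_rates())
        assert np.array_equal(out.counts, toy_grid.counts)

    def test_single_initiation_flow(self):
        g = PopulationGrid(2022)
        g.counts[20, 0, NEVER] = 1000.0
        rates = zero_rates()
        rates.initiation[20, 0] = 0.1
        out = ss.apply_smoking_transitions(g, rates)
        assert out.counts[20, 0, NEVER] == pytest.approx(900.0)
        assert out.counts[20, 0, CURRENT] == pytest.approx(100.0)

    def test_cessation_relapse_progression_by_hand(self):
        # 500 current with 20% cessation; 200 recent quitters with 30% relapse.
        # Hand expansion: 100 quit; 60 relapse; of the 140 non-relapsing
        # recent quitters half progress to the 3-5y bin.
        g = PopulationGrid(2022)
        g.counts[40, 0, CURRENT] = 500.0
        g.counts[40, 0, 2] = 200.0
        rates = zero_rates()
        rates.cessation[40, 0] = 0.2
        rates.relapse[0, :] = 0.3
        out = ss.apply_smoking_transitions(g, rates)
        assert out.counts[40, 0, CURRENT] == pytest.approx(460.0)
        assert out.counts[40, 0, 2] == pytest.approx(170.0)  # 70 stayers + 100 new
        assert out.counts[40, 0, 3] == pytest.approx(70.0)
        assert out.counts[40, 0].sum() == pytest.approx(700.0)

    def test_closed_form_never_fraction(self):
        # with constant initiation i, the never fraction decays as (1-i)^t
        g = PopulationGrid(2022)
        g.counts[19, :, NEVER] = 1000.0
        init = np.zeros((86, 2))
        init[15:25, :] = 0.05
        rates = ss.TransitionRates(init, np.zeros((86, 2)), np.zeros((5, 2)))
        out = ss.project_raw(g, zero_demo(), rates, 5)
        assert out["male"][-1] == pytest.approx(100 * (1 - 0.95**5), abs=1e-9)
        assert out["both"][-1] == pytest.approx(100 * (1 - 0.95**5), abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        i=st.floats(0, 1), c=st.floats(0, 1),
        r=st.floats(0, 1),
        never=st.floats(0, 1e5), cur=st.floats(0, 1e5), former=st.floats(0, 1e5),
    )
    def test_transitions_conserve_each_cohort(self, i, c, r, never, cur, former):
        g = PopulationGrid(2022)
        g.counts[20, 1, NEVER] = never
        g.counts[20, 1, CURRENT] = cur
        g.counts[20, 1, 4] = former
        rates = zero_rates()
        rates.initiation[20, 1] = i
        rates.cessation[20, 1] = c
        rates.relapse[:, 1] = r
        out = ss.apply_smoking_transitions(g, rates)
        assert np.all(out.counts >= 0)
        assert out.counts[20, 1].sum() == pytest.approx(never + cur + former, rel=1e-12)


class TestAdultPrevalence:
    def test_zero_and_full_prevalence(self):
        g = uniform_grid()
        assert ss.adult_prevalence(g) == 0.0
        g.counts[:, :, CURRENT] = g.counts[:, :, NEVER]
        g.counts[:, :, NEVER] = 0.0
        assert ss.adult_prevalence(g) == 100.0

    def test_printed_starting_prevalence_fraction(self):
        # 353 of 1000 adult males smoke -> 35.3%
        g = PopulationGrid(2022)
        g.counts[30, 0, CURRENT] = 353.0
        g.counts[30, 0, NEVER] = 647.0
        assert ss.adult_prevalence(g, sex="male") == pytest.approx(35.3)

    def test_sex_weighting_lies_between(self, quick_baseline):
        g = quick_baseline.grid
        male = ss.adult_prevalence(g, sex="male")
        female = ss.adult_prevalence(g, sex="female")
        both = ss.adult_prevalence(g, sex="both")
        assert min(male, female) <= both <= max(male, female)

    def test_empty_denominator_raises(self):
        with pytest.raises(ValidationError):
            ss.adult_prevalence(PopulationGrid(2022))

    def test_unknown_selector_raises(self, quick_baseline):
        with pytest.raises(ValidationError):
            ss.adult_prevalence(quick_baseline.grid, sex="all")


class TestPrevalenceAdjustment:
    def test_reduction_moves_smokers_to_settled_former(self):
        g = PopulationGrid(2022)
        g.counts[40, 0, CURRENT] = 100.0
        out = ss.apply_prevalence_adjustment(g, np.full(N_AGES, 0.9))
        assert out.counts[40, 0, CURRENT] == pytest.approx(90.0)
        assert out.counts[40, 0, -1] == pytest.approx(10.0)
        assert out.total() == pytest.approx(g.total())

    def test_increase_bounded_by_available_former(self):
        g = PopulationGrid(2022)
        g.counts[40, 0, CURRENT] = 100.0
        g.counts[40, 0, 3] = 5.0
        out = ss.apply_prevalence_adjustment(g, np.full(N_AGES, 1.5))
        assert out.counts[40, 0, CURRENT] == pytest.approx(105.0)  # capped
        assert out.counts[40, 0, 3] == pytest.approx(0.0)
        assert out.total() == pytest.approx(g.total())

    def test_invalid_multiplier_raises(self, toy_grid):
        with pytest.raises(ValidationError):
            ss.apply_prevalence_adjustment(toy_grid, np.zeros(N_AGES))


class TestGridIO:
    def test_csv_round_trip_identity(self, tmp_path, quick_baseline):
        path = tmp_path / "grid.csv"
        quick_baseline.grid.to_csv(path)
        back = PopulationGrid.from_csv(path)
        assert back.year == quick_baseline.grid.year
        np.testing.assert_allclose(back.counts, quick_baseline.grid.counts)

    def test_rates_round_trips(self, tmp_path, quick_baseline):
        r = quick_baseline.rates
        back = ss.TransitionRates.from_frames(
            r.to_frame(), r.relapse_frame(), r.initiation_window
        )
        np.testing.assert_allclose(back.initiation, r.initiation)
        np.testing.assert_allclose(back.cessation, r.cessation)
        np.testing.assert_allclose(back.relapse, r.relapse)
        back2 = ss.TransitionRates.from_json(r.to_json())
        np.testing.assert_allclose(back2.initiation, r.initiation)
        d = quick_baseline.demo
        back3 = ss.DemographicRates.from_frame(
            d.to_frame(), d.sex_ratio_at_birth, d.mortality_multiplier
        )
        np.testing.assert_allclose(back3.mortality, d.mortality)
        np.testing.assert_allclose(back3.fertility, d.fertility)

    def test_negative_counts_rejected(self):
        g = PopulationGrid(2022)
        g.counts[3, 0, 0] = -1.0
        with pytest.raises(ValidationError):
            g.validate()

    def test_juvenile_smokers_rejected(self):
        g = PopulationGrid(2022)
        g.counts[10, 0, CURRENT] = 5.0
        with pytest.raises(ValidationError):
            g.validate(min_initiation_age=15)
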