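"""Tests of scenario construction and the projection loop."""
import numpy as np
import pytest

import smokesim as ss
from smokesim.errors import HorizonError, ValidationError
from smokesim.grid import NEVER
from smokesim.scenarios import POLICY_YEAR, TFG_CUTOFF, build_scenario

from conftest import zero_rates


class TestBuildScenario:
    @pytest.mark.parametrize("name", ss.SCENARIO_NAMES)
    def test_all_seven_names_build(self, name):
        sc = build_scenario(name)
        assert sc.name == name
        assert sc.start_year == 2022 and sc.horizon_end == 2050

    def test_report_style_aliases(self):
        sc = build_scenario("POWE+TFG+R8000+R10%")
        assert sc.name == "powe_tfg_r8000_r10"
        assert sc.tfg_cutoff_birth_year == TFG_CUTOFF
        assert sc.price_rule == "jump_8000_growth_10"

    def test_status_quo_holds_2022_policy(self):
        sc = build_scenario("status_quo")
        assert sc.policy_schedule == {}
        for year in (2023, 2035, 2050):
            assert sc.state_at(year) == ss.KOREA_2022
            assert sc.nominal_price(year) == 4500.0

    def test_combined_scenario_switches(self):
        sc = build_scenario("powe_tfg_r8000_r10")
        assert sc.state_at(2023) == ss.FULL_POWE
        assert sc.nominal_price(2023) == 8000.0
        assert sc.nominal_price(2024) == pytest.approx(8800.0)

    def test_unknown_name_raises(self):
        with pytest.raises(ValidationError):
            build_scenario("prohibition")

    def test_yaml_round_trip(self, tmp_path):
        text = """
name: custom
price_rule: jump_8000
tfg_cutoff_birth_year: 2003
schedule:
  2023:
    clean_air: complete
    cessation_support: full
    warnings: high
    warnings_enforced: true
    ad_ban: comprehensive
    ad_ban_enforced: true
"""
        path = tmp_path / "scenario.yaml"
        path.write_text(text)
        sc = ss.scenario_from_yaml(path)
        assert sc.name == "custom"
        assert sc.state_at(2023) == ss.FULL_POWE
        assert sc.nominal_price(2030) == 8000.0
        (tmp_path / "builtin.yaml").write_text("builtin: powe_tfg\n")
        assert ss.scenario_from_yaml(tmp_path / "builtin.yaml").name == "powe_tfg"


class TestApplyTfg:
    def test_ban_boundary_at_start(self):
        rates = zero_rates()
        rates.initiation[15:25, :] = 0.1
        out = ss.apply_tfg(rates, 2023, 2003)
        # born after 2003 => aged 19 or less in 2023
        assert np.all(out.initiation[:20] == 0.0)
        assert np.all(out.initiation[20:25] == 0.1)

    def test_ban_boundary_widens_with_time(self):
        rates = zero_rates()
        rates.initiation[15:25, :] = 0.1
        out = ss.apply_tfg(rates, 2050, 2003)
        assert np.all(out.initiation[:47] == 0.0)

    def test_no_cutoff_is_identity(self):
        rates = zero_rates()
        rates.initiation[20, 0] = 0.3
        out = ss.apply_tfg(rates, 2030, None)
        assert out is rates

    def test_other_rates_untouched(self):
        rates = zero_rates()
        rates.cessation[:, :] = 0.2
        out = ss.apply_tfg(rates, 2030, 2003)
        np.testing.assert_array_equal(out.cessation, rates.cessation)


class TestRunScenario:
    def test_determinism_bit_identical(self, quick_baseline):
        a = ss.run_scenario(quick_baseline, build_scenario("powe_tfg_r8000_r10"))
        b = ss.run_scenario(quick_baseline, build_scenario("powe_tfg_r8000_r10"))
        assert np.array_equal(a.male, b.male)
        assert np.array_equal(a.female, b.female)
        assert np.array_equal(a.total, b.total)

    def test_projection_bounds_and_weighting(self, quick_baseline):
        s = ss.run_scenario(quick_baseline, build_scenario("powe"))
        for arr in (s.male, s.female, s.total):
            assert np.all((arr >= 0) & (arr <= 100))
        assert np.all(s.total <= np.maximum(s.male, s.female) + 1e-9)
        assert np.all(s.total >= np.minimum(s.male, s.female) - 1e-9)

    def test_scenario_nesting_everywhere(self, quick_baseline):
        runs = {
            n: ss.run_scenario(quick_baseline, build_scenario(n))
            for n in ss.SCENARIO_NAMES
        }
        stronger_pairs = [
            ("powe", "status_quo"),
            ("powe_r8000", "powe"),
            ("powe_r8000_r10", "powe_r8000"),
            ("powe_tfg", "powe"),
            ("powe_tfg_r8000", "powe_tfg"),
            ("powe_tfg_r8000_r10", "powe_tfg_r8000"),
            ("powe_tfg_r8000", "powe_r8000"),
            ("powe_tfg_r8000_r10", "powe_r8000_r10"),
        ]
        for strong, weak in stronger_pairs:
            for sex in ("male", "female", "total"):
                diff = getattr(runs[strong], sex) - getattr(runs[weak], sex)
                assert np.all(diff <= 1e-9), (strong, weak, sex)

    def test_tfg_cohorts_never_initiate(self, quick_baseline):
        s = ss.run_scenario(quick_baseline, build_scenario("powe_tfg"))
        assert s.metadata["tfg_cutoff"] == 2003
        # re-run manually to inspect the final grid: cohorts born after the
        # last pre-ban initiation opportunity must still be all never-smokers
        sc = build_scenario("powe_tfg")
        final = _final_grid(quick_baseline, sc)
        ages = np.arange(86)
        birth_year = 2050 - ages
        # born >= 2008: younger than the initiation window throughout 2022
        fresh = (birth_year >= 2008) & (ages >= 15)
        smoked = final.counts[fresh][:, :, 1:].sum()
        assert smoked == pytest.approx(0.0, abs=1e-9)

    def test_null_policy_limit_changes_only_by_turnover(self, quick_baseline):
        # all policy effects zeroed: the status-quo projection reduces to
        # bare demographic + smoking-rate dynamics
        table = ss.PolicyEffectTable.default()
        for comp in ("P", "O", "W", "E", "R"):
            table = table.scaled(comp, 0.0)
        s = ss.run_scenario(quick_baseline, build_scenario("status_quo"), table)
        raw = ss.project_raw(
            quick_baseline.grid, quick_baseline.demo, quick_baseline.rates, 28
        )
        np.testing.assert_allclose(s.male, raw["male"], atol=1e-9)

    def test_wrong_start_year_raises(self, quick_baseline):
        bad = ss.Baseline(
            ss.PopulationGrid(2021, quick_baseline.grid.counts.copy()),
            quick_baseline.demo,
            quick_baseline.rates,
        )
        with pytest.raises(HorizonError):
            ss.run_scenario(bad, build_scenario("status_quo"))


def _final_grid(baseline, scenario, table=None):
    """Replicate the projection loop, returning the final-year grid."""
    from smokesim.markov import (
        apply_prevalence_adjustment,
        apply_smoking_transitions,
        evolve_population,
    )
    from smokesim.policy import PolicyMultipliers, level_change_multipliers, price_multipliers

    table = table or ss.PolicyEffectTable.default()
    grid = baseline.grid.copy()
    persistent = PolicyMultipliers.identity()
    prev_state = scenario.state_at(2022)
    real_prev = scenario.nominal_price(2022)
    for year in range(2023, 2051):
        grid = evolve_population(grid, baseline.demo)
        stock = np.ones(86)
        state = scenario.state_at(year)
        if state != prev_state:
            lvl = level_change_multipliers(prev_state, state, table)
            persistent = persistent * lvl
            stock = stock * lvl.prevalence
            prev_state = state
        real_now = scenario.nominal_price(year) / 1.03 ** (year - 2022)
        pm = price_multipliers(real_prev, real_now, table)
        real_prev = real_now
        eff = baseline.rates.copy()
        eff.initiation = np.clip(
            eff.initiation * (persistent.initiation * pm.initiation)[:, None], 0, 1
        )
        eff.cessation = np.clip(
            eff.cessation * (persistent.cessation * pm.cessation)[:, None], 0, 1
        )
        eff = ss.apply_tfg(eff, year, scenario.tfg_cutoff_birth_year)
        grid = apply_smoking_transitions(grid, eff)
        grid = apply_prevalence_adjustment(grid, stock * pm.prevalence)
    return grid


class TestScenarioDelta:
    def test_identical_series_is_zero(self, quick_baseline):
        s = ss.run_scenario(quick_baseline, build_scenario("status_quo"))
        assert ss.scenario_delta(s, s, 2030, "male") == 0.0

    def test_sign_convention(self, quick_baseline):
        sq = ss.run_scenario(quick_baseline, build_scenario("status_quo"))
        powe = ss.run_scenario(quick_baseline, build_scenario("powe"))
        assert ss.scenario_delta(sq, powe, 2030, "male") > 0

    def test_year_outside_horizon_raises(self, quick_baseline):
        s = ss.run_scenario(quick_baseline, build_scenario("status_quo"))
        with pytest.raises(HorizonError):
            ss.scenario_delta(s, s, 2060, "male")
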