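"""Policy scenarios and the yearly projection loop.

Seven scenarios are built in: the status quo and six strengthening
combinations of full non-price policies (POWE), a one-time nominal price
jump to KRW 8000 in 2023 with optional 10% annual growth thereafter, and a
tobacco-free-generation (TFG) sales ban for everyone born after 2003,
modelled as zero smoking initiation for those birth cohorts from 2023.

The yearly update order is: demography, then smoking transitions under
policy-adjusted rates, then prevalence stock adjustments (one-off level
effects in the year a policy changes; price effects every year from
consecutive real prices).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import HorizonError, ValidationError
from .grid import PopulationGrid
from .markov import (
    adult_prevalence,
    apply_prevalence_adjustment,
    apply_smoking_transitions,
    evolve_population,
)
from .policy import (
    FULL_POWE,
    KOREA_2022,
    PolicyEffectTable,
    PolicyMultipliers,
    PolicyState,
    level_change_multipliers,
    price_multipliers,
)
from .rates import DemographicRates, TransitionRates

START_YEAR = 2022
POLICY_YEAR = 2023
END_YEAR = 2050
TFG_CUTOFF = 2003

SCENARIO_NAMES = (
    "status_quo",
    "powe",
    "powe_r8000",
    "powe_r8000_r10",
    "powe_tfg",
    "powe_tfg_r8000",
    "powe_tfg_r8000_r10",
)

_ALIASES = {
    "statusquo": "status_quo",
    "powe": "powe",
    "power8000": "powe_r8000",
    "power8000r10": "powe_r8000_r10",
    "powetfg": "powe_tfg",
    "powetfgr8000": "powe_tfg_r8000",
    "powetfgr8000r10": "powe_tfg_r8000_r10",
}


@dataclass
class Baseline:
    """Calibrated model inputs: the initial population and all rates."""

    grid: PopulationGrid
    demo: DemographicRates
    rates: TransitionRates


@dataclass
class Scenario:
    """A calendar schedule of policy levels plus a price path and TFG flag."""

    name: str
    policy_schedule: dict[int, PolicyState]
    price_rule: str = "status_quo_nominal"
    tfg_cutoff_birth_year: int | None = None
    start_year: int = START_YEAR
    horizon_end: int = END_YEAR

    def __post_init__(self):
        for y in self.policy_schedule:
            if not self.start_year < y <= self.horizon_end:
                raise ValidationError(
                    f"schedule year {y} outside ({self.start_year}, {self.horizon_end}]"
                )
        if (
            self.tfg_cutoff_birth_year is not None
            and self.tfg_cutoff_birth_year >= self.start_year
        ):
            raise ValidationError("TFG cutoff birth year must precede the start year")

    def state_at(self, year: int) -> PolicyState:
        """Policy state in force at a calendar year."""
        state = KOREA_2022
        for y in sorted(self.policy_schedule):
            if y <= year:
                state = self.policy_schedule[y]
        return state

    def nominal_price(self, year: int) -> float:
        if self.price_rule == "status_quo_nominal":
            return KOREA_2022.price.nominal_price
        if self.price_rule == "jump_8000":
            return 4500.0 if year < POLICY_YEAR else 8000.0
        if self.price_rule == "jump_8000_growth_10":
            if year < POLICY_YEAR:
                return 4500.0
            return 8000.0 * 1.10 ** (year - POLICY_YEAR)
        raise ValidationError(f"unknown price rule {self.price_rule!r}")


def build_scenario(name: str) -> Scenario:
    """Construct one of the seven built-in scenarios by name.

    Accepts canonical names (``powe_tfg_r8000_r10``) and the punctuated
    aliases used in reports (``POWE+TFG+R8000+R10%``).
    """
    key = "".join(ch for ch in name.lower() if ch.isalnum())
    key = key.replace("percent", "")
    if key not in _ALIASES:
        raise ValidationError(f"unknown scenario name {name!r}")
    canonical = _ALIASES[key]
    schedule: dict[int, PolicyState] = {}
    price_rule = "status_quo_nominal"
    tfg = None
    if canonical != "status_quo":
        schedule[POLICY_YEAR] = FULL_POWE
    if "r8000" in canonical:
        price_rule = "jump_8000_growth_10" if canonical.endswith("r10") else "jump_8000"
    if "tfg" in canonical:
        tfg = TFG_CUTOFF
    return Scenario(canonical, schedule, price_rule, tfg)


def scenario_from_yaml(path) -> Scenario:
    """Load a scenario from a YAML file.

    The file either names a built-in scenario (``builtin: powe_tfg``) or
    gives ``name``, an optional ``price_rule`` and ``tfg_cutoff_birth_year``,
    and a ``schedule`` mapping years to policy-level fields, e.g.::

        name: my_scenario
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
    import yaml

    with open(path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise ValidationError("scenario file must contain a mapping")
    if "builtin" in spec:
        return build_scenario(spec["builtin"])
    try:
        name = spec["name"]
    except KeyError:
        raise ValidationError("scenario file needs a 'name' (or 'builtin') key")
    schedule = {}
    for year, fields in (spec.get("schedule") or {}).items():
        schedule[int(year)] = replace(KOREA_2022, **fields)
    return Scenario(
        name,
        schedule,
        spec.get("price_rule", "status_quo_nominal"),
        spec.get("tfg_cutoff_birth_year"),
        int(spec.get("start_year", START_YEAR)),
        int(spec.get("horizon_end", END_YEAR)),
    )


def apply_tfg(
    rates: TransitionRates, grid_year: int, cutoff_birth_year: int | None
) -> TransitionRates:
    """Zero the initiation rate for cohorts born after the cutoff year.

    A person aged ``a`` in ``grid_year`` was born in ``grid_year - a``; the
    ban covers birth years strictly greater than the cutoff.
    """
    if cutoff_birth_year is None:
        return rates
    out = rates.copy()
    ages = np.arange(out.initiation.shape[0])
    banned = (grid_year - ages) > cutoff_birth_year
    out.initiation[banned, :] = 0.0
    return out


@dataclass
class ProjectionSeries:
    """Adult smoking prevalence (%) by year, sex and combined total."""

    scenario: str
    year: np.ndarray
    male: np.ndarray
    female: np.ndarray
    total: np.ndarray
    metadata: dict = field(default_factory=dict)

    def value(self, year: int, sex: str = "total") -> float:
        idx = np.where(self.year == year)[0]
        if idx.size == 0:
            raise HorizonError(f"year {year} not in projection horizon")
        if sex in ("total", "both"):
            return float(self.total[idx[0]])
        if sex == "male":
            return float(self.male[idx[0]])
        if sex == "female":
            return float(self.female[idx[0]])
        raise ValidationError(f"unknown sex selector {sex!r}")

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for sex, arr in (("male", self.male), ("female", self.female),
                         ("total", self.total)):
            frames.append(
                pd.DataFrame(
                    {
                        "scenario": self.scenario,
                        "year": self.year,
                        "sex": sex,
                        "prevalence_pct": arr,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_scenario(
    baseline: Baseline,
    scenario: Scenario,
    table: PolicyEffectTable | None = None,
    min_age: int = 19,
) -> ProjectionSeries:
    """Project adult smoking prevalence under a scenario.

    Deterministic: iterates the Markov engine from the baseline grid year
    to the horizon end, applying policy-level multipliers in the year each
    level change takes effect (stock effect once; initiation/cessation
    multipliers persisting thereafter) and price multipliers every year
    from consecutive real prices.
    """
    if table is None:
        table = PolicyEffectTable.default()
    if baseline.grid.year != scenario.start_year:
        raise HorizonError(
            f"baseline grid year {baseline.grid.year} != scenario start "
            f"{scenario.start_year}"
        )

    grid = baseline.grid.copy()
    inflation = KOREA_2022.price.inflation_rate
    persistent = PolicyMultipliers.identity()

    years = [grid.year]
    male = [adult_prevalence(grid, min_age, "male")]
    female = [adult_prevalence(grid, min_age, "female")]
    total = [adult_prevalence(grid, min_age, "both")]

    prev_state = scenario.state_at(scenario.start_year)
    real_prev = scenario.nominal_price(scenario.start_year)  # CPI base year

    for year in range(scenario.start_year + 1, scenario.horizon_end + 1):
        grid = evolve_population(grid, baseline.demo, max_year=scenario.horizon_end)

        stock_mult = np.ones(grid.counts.shape[0])

        state = scenario.state_at(year)
        if state != prev_state:
            lvl = level_change_multipliers(prev_state, state, table)
            persistent = persistent * lvl
            stock_mult = stock_mult * lvl.prevalence
            prev_state = state

        nominal = scenario.nominal_price(year)
        real_now = deflated = nominal / (1.0 + inflation) ** (year - START_YEAR)
        pm = price_multipliers(real_prev, real_now, table)
        real_prev = deflated

        eff = baseline.rates.copy()
        eff.initiation = np.clip(
            eff.initiation * (persistent.initiation * pm.initiation)[:, None], 0.0, 1.0
        )
        eff.cessation = np.clip(
            eff.cessation * (persistent.cessation * pm.cessation)[:, None], 0.0, 1.0
        )
        eff = apply_tfg(eff, year, scenario.tfg_cutoff_birth_year)
        grid = apply_smoking_transitions(grid, eff)

        stock_mult = stock_mult * pm.prevalence
        grid = apply_prevalence_adjustment(grid, stock_mult)

        years.append(year)
        male.append(adult_prevalence(grid, min_age, "male"))
        female.append(adult_prevalence(grid, min_age, "female"))
        total.append(adult_prevalence(grid, min_age, "both"))

    return ProjectionSeries(
        scenario.name,
        np.array(years),
        np.array(male),
        np.array(female),
        np.array(total),
        metadata={"price_rule": scenario.price_rule,
                  "tfg_cutoff": scenario.tfg_cutoff_birth_year},
    )


def scenario_delta(
    series_a: ProjectionSeries,
    series_b: ProjectionSeries,
    year: int,
    sex: str = "male",
) -> float:
    """Prevalence difference a - b at a year, in percentage points."""
    return series_a.value(year, sex) - series_b.value(year, sex)
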