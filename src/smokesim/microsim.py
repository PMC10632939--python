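"""Individual-based simulator used as an independent cross-check.

Simulates discrete agents with the same per-year death and smoking
transition probabilities as the cohort engine.  In expectation the two
agree exactly; the agent simulator adds only Monte-Carlo noise, which is
reported as a per-year standard error so that equivalence can be asserted
within a stated number of SEs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .grid import CURRENT, FORMER_FIRST, FORMER_WIDTHS, NEVER, N_AGES, N_STATES, PopulationGrid
from .rates import DemographicRates, TransitionRates


@dataclass
class MicrosimResult:
    """Adult prevalence trajectory from the agent simulator.

    ``prevalence`` and ``se`` are in percent; ``n_adults`` is the live
    adult agent count per year for the requested sex selector.
    """

    year: np.ndarray
    prevalence: np.ndarray
    se: np.ndarray
    n_adults: np.ndarray
    sex: str
    seed: int


def _sample_agents(grid: PopulationGrid, n_agents: int, rng: np.random.Generator):
    p = grid.counts.ravel() / grid.total()
    cells = rng.choice(p.size, size=n_agents, p=p)
    age, sex, state = np.unravel_index(cells, grid.counts.shape)
    return age.astype(np.int64), sex.astype(np.int64), state.astype(np.int64)


def microsim_oracle(
    grid: PopulationGrid,
    demo: DemographicRates,
    rates: TransitionRates,
    n_agents: int,
    n_years: int,
    seed: int,
    min_age: int = 19,
    sex: str = "both",
) -> MicrosimResult:
    """Simulate ``n_agents`` individuals for ``n_years`` and return the
    adult smoking-prevalence trajectory with Monte-Carlo standard errors.
    """
    if n_agents < 10_000:
        raise ValidationError("microsim oracle requires n_agents >= 10^4")
    grid.validate()
    demo.validate()
    rates.validate()
    rng = np.random.default_rng(seed)

    age, agent_sex, state = _sample_agents(grid, n_agents, rng)
    # births are simulated per-agent so that denominators track the cohort model
    years, prev, se, n_ad = [], [], [], []

    def record(year: int) -> None:
        if sex == "male":
            mask = agent_sex == 0
        elif sex == "female":
            mask = agent_sex == 1
        elif sex == "both":
            mask = np.ones_like(agent_sex, dtype=bool)
        else:
            raise ValidationError(f"unknown sex selector {sex!r}")
        adult = mask & (age >= min_age)
        n = int(adult.sum())
        if n == 0:
            raise ValidationError("no adult agents alive")
        p = float((state[adult] == CURRENT).mean())
        years.append(year)
        prev.append(100.0 * p)
        se.append(100.0 * np.sqrt(max(p * (1 - p), 1e-12) / n))
        n_ad.append(n)

    record(grid.year)
    year = grid.year
    for _ in range(n_years):
        year += 1
        # deaths
        mult = demo.mortality_multiplier[state]
        q = demo.mortality[age, agent_sex] * mult
        alive = rng.random(q.size) >= q
        age, agent_sex, state = age[alive], agent_sex[alive], state[alive]
        # births from surviving women (fertility of completed age)
        fert = demo.fertility[age] * (agent_sex == 1)
        n_births = int(rng.binomial(1, np.clip(fert, 0, 1)).sum())
        if n_births:
            b_sex = (rng.random(n_births) >= demo.sex_ratio_at_birth).astype(np.int64)
            age = np.concatenate([age + 1, np.zeros(n_births, dtype=np.int64)])
            agent_sex = np.concatenate([agent_sex, b_sex])
            state = np.concatenate([state, np.full(n_births, NEVER, dtype=np.int64)])
        else:
            age = age + 1
        np.minimum(age, 85, out=age)

        # smoking transitions, same simultaneous-flow convention as the cohort engine
        u = rng.random(state.size)
        new_state = state.copy()
        is_never = state == NEVER
        i = rates.initiation[age, agent_sex]
        new_state[is_never & (u < i)] = CURRENT

        is_cur = state == CURRENT
        c = rates.cessation[age, agent_sex]
        new_state[is_cur & (u < c)] = FORMER_FIRST

        is_former = state >= FORMER_FIRST
        dur = np.clip(state - FORMER_FIRST, 0, 4)
        r = rates.relapse[dur, agent_sex]
        relapse_hit = is_former & (u < r)
        new_state[relapse_hit] = CURRENT
        # duration progression for non-relapsing former smokers
        adv_p = np.zeros(5)
        adv_p[:4] = 1.0 / FORMER_WIDTHS[:4]
        u2 = rng.random(state.size)
        advance = is_former & ~relapse_hit & (u2 < adv_p[dur])
        new_state[advance] = np.minimum(state[advance] + 1, N_STATES - 1)
        state = new_state
        record(year)

    return MicrosimResult(
        np.array(years), np.array(prev), np.array(se), np.array(n_ad), sex, seed
    )
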