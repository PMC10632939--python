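"""The discrete-time Markov engine.

One simulated year consists of a demographic step (aging, deaths, births)
followed by a smoking-transition step (initiation, cessation, relapse,
quit-duration progression).  Policy effects enter separately, as rate
multipliers and stock adjustments applied by the scenario engine.
"""
from __future__ import annotations

import numpy as np

from .errors import HorizonError, ValidationError
from .grid import (
    CURRENT,
    FORMER_FIRST,
    FORMER_LAST,
    FORMER_WIDTHS,
    NEVER,
    PopulationGrid,
)
from .rates import DemographicRates, TransitionRates


def evolve_population(
    grid: PopulationGrid,
    demo: DemographicRates,
    max_year: int | None = None,
) -> PopulationGrid:
    """Advance the population one calendar year by aging, death and birth.

    Each age-``a`` cohort moves to age ``a+1`` with survival
    ``1 - mortality(a, sex) * mortality_multiplier(state)``; the 85+ bin
    accumulates survivors from age 84 and from itself.  Births are produced
    by fertility applied to the total female population and enter at age 0
    as never-smokers, split by the sex ratio at birth.  Smoking-state
    proportions within a cohort are untouched by aging.
    """
    grid.validate()
    demo.validate()
    if max_year is not None and grid.year + 1 > max_year:
        raise HorizonError(
            f"cannot evolve past horizon year {max_year} (grid at {grid.year})"
        )

    surv = 1.0 - demo.mortality[:, :, None] * demo.mortality_multiplier[None, None, :]
    if np.any(surv < -1e-12):
        raise ValidationError("mortality * multiplier exceeds 1 for some state")
    surv = np.clip(surv, 0.0, 1.0)

    survivors = grid.counts * surv
    out = PopulationGrid(grid.year + 1)
    out.counts[1:85] = survivors[0:84]
    out.counts[85] = survivors[85] + survivors[84]

    female_pop = grid.counts[:, 1, :].sum(axis=1)
    births = float(np.dot(demo.fertility, female_pop))
    out.counts[0, 0, NEVER] = births * demo.sex_ratio_at_birth
    out.counts[0, 1, NEVER] = births * (1.0 - demo.sex_ratio_at_birth)
    return out


def apply_smoking_transitions(
    grid: PopulationGrid, rates: TransitionRates
) -> PopulationGrid:
    """Redistribute each (age, sex) cohort across smoking states.

    Flows are computed simultaneously from the pre-transition state:
    never -> current by initiation; current -> first former bin by
    cessation; each former bin -> current by its relapse probability.
    Non-relapsing former smokers advance through the quit-duration bins at
    rate ``1 / bin width`` per year (the last bin is absorbing).  Cohort
    totals are conserved exactly.
    """
    grid.validate()
    rates.validate()

    c = grid.counts
    out = PopulationGrid(grid.year, np.zeros_like(c))

    init = rates.initiation  # (86, 2)
    cess = rates.cessation
    rel = rates.relapse  # (5, 2)

    never = c[:, :, NEVER]
    cur = c[:, :, CURRENT]
    former = c[:, :, FORMER_FIRST : FORMER_LAST + 1]  # (86, 2, 5)

    new_smokers = never * init
    quitters = cur * cess
    relapsers = former * rel[None, :, :].transpose(0, 2, 1)  # (86,2,5)
    staying_former = former - relapsers

    advance = np.zeros(5)
    advance[:4] = 1.0 / FORMER_WIDTHS[:4]
    moved_up = staying_former * advance[None, None, :]

    out.counts[:, :, NEVER] = never - new_smokers
    out.counts[:, :, CURRENT] = cur - quitters + new_smokers + relapsers.sum(axis=2)
    new_former = staying_former - moved_up
    new_former[:, :, 1:] += moved_up[:, :, :4]
    new_former[:, :, 0] += quitters
    out.counts[:, :, FORMER_FIRST : FORMER_LAST + 1] = new_former

    if np.any(out.counts < -1e-9):
        raise ValidationError(
            "smoking transitions produced a negative count (rate > 1 or ordering bug)"
        )
    out.counts = np.clip(out.counts, 0.0, None)
    return out


def adult_prevalence(
    grid: PopulationGrid, min_age: int = 19, sex: str = "both"
) -> float:
    """Current-smoker prevalence (%) among persons aged ``min_age`` and over.

    ``sex`` is ``"male"``, ``"female"`` or ``"both"`` (population-weighted).
    """
    if not 0 <= min_age <= 85:
        raise ValidationError(f"min_age {min_age} outside the age range")
    if sex == "male":
        cols = [0]
    elif sex == "female":
        cols = [1]
    elif sex == "both":
        cols = [0, 1]
    else:
        raise ValidationError(f"unknown sex selector {sex!r}")
    sub = grid.counts[min_age:, cols, :]
    denom = sub.sum()
    if denom <= 0:
        raise ValidationError("empty adult population (zero denominator)")
    return 100.0 * float(sub[:, :, CURRENT].sum()) / float(denom)


def apply_prevalence_adjustment(
    grid: PopulationGrid, multiplier: np.ndarray
) -> PopulationGrid:
    """Apply a one-off stock adjustment to current smokers, by age.

    ``multiplier`` has shape (86,) or (86, 2).  Where it is below 1, the
    displaced current smokers represent settled behaviour change: they
    enter the terminal (long-quit) former bin, so a policy-induced
    prevalence reduction is not subsequently undone by early-quit relapse.
    Where it is above 1 (a real price decline), the extra smokers are
    drawn back from the former bins proportionally, capped by
    availability.  Cohort totals are conserved.
    """
    grid.validate()
    m = np.asarray(multiplier, dtype=float)
    if m.ndim == 1:
        m = np.repeat(m[:, None], 2, axis=1)
    if m.shape != (86, 2):
        raise ValidationError("prevalence multiplier must have shape (86,) or (86,2)")
    if np.any(~np.isfinite(m)) or np.any(m <= 0):
        raise ValidationError("prevalence multiplier must be finite and positive")

    out = grid.copy()
    cur = out.counts[:, :, CURRENT]
    former = out.counts[:, :, FORMER_FIRST : FORMER_LAST + 1]

    target = cur * m
    # reductions: move excess into the first former bin
    reduction = np.clip(cur - target, 0.0, None)
    # increases: pull from former bins, proportionally, capped by availability
    former_total = former.sum(axis=2)
    want = np.clip(target - cur, 0.0, None)
    pulled = np.minimum(want, former_total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(former_total > 0, pulled / former_total, 0.0)
    former -= former * frac[:, :, None]
    former[:, :, -1] += reduction
    out.counts[:, :, CURRENT] = cur - reduction + pulled
    out.counts[:, :, FORMER_FIRST : FORMER_LAST + 1] = former
    return out


def project_raw(
    grid: PopulationGrid,
    demo: DemographicRates,
    rates: TransitionRates,
    n_years: int,
    min_age: int = 19,
) -> dict[str, np.ndarray]:
    """Run the bare cohort engine (no policy module) for ``n_years``.

    Returns arrays of adult prevalence (%) by year for each sex and both
    combined, including the starting year.  Used as the deterministic
    counterpart of the individual-based simulator in cross-checks.
    """
    years = [grid.year]
    male = [adult_prevalence(grid, min_age, "male")]
    female = [adult_prevalence(grid, min_age, "female")]
    both = [adult_prevalence(grid, min_age, "both")]
    g = grid
    for _ in range(n_years):
        g = evolve_population(g, demo)
        g = apply_smoking_transitions(g, rates)
        years.append(g.year)
        male.append(adult_prevalence(g, min_age, "male"))
        female.append(adult_prevalence(g, min_age, "female"))
        both.append(adult_prevalence(g, min_age, "both"))
    return {
        "year": np.array(years),
        "male": np.array(male),
        "female": np.array(female),
        "both": np.array(both),
    }
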