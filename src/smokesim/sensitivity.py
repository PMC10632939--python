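"""One-way and probabilistic sensitivity analyses of the policy effects.

One-way analysis scales every effect size of a single MPOWER component
(elasticities for the price component) by ``1 + delta`` and reruns the
combined endgame scenario.  The probabilistic analysis draws a scale
factor per component from a beta distribution rescaled to [0.5, 1.5] with
mean 1, reruns the scenario per draw, and summarizes report-year
prevalences with bias-corrected percentile confidence intervals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .policy import COMPONENTS, PolicyEffectTable
from .scenarios import Baseline, ProjectionSeries, Scenario, run_scenario

REPORT_YEARS = (2030, 2050)
REPORT_SEXES = ("male", "female", "total")

Z_95 = 1.959964  # normal quantile for a 95% interval


def one_way(
    baseline: Baseline,
    scenario: Scenario,
    component: str,
    delta: float,
    table: PolicyEffectTable | None = None,
) -> ProjectionSeries:
    """Rerun a scenario with one component's effect sizes scaled by 1+delta."""
    if component not in COMPONENTS:
        raise ValidationError(f"unknown component {component!r}")
    if not -0.9 <= delta <= 0.9:
        raise ValidationError("delta must lie in [-0.9, 0.9]")
    table = table or PolicyEffectTable.default()
    return run_scenario(baseline, scenario, table.scaled(component, 1.0 + delta))


@dataclass
class OneWayGrid:
    """Report-year prevalences for a grid of components x perturbations."""

    scenario: str
    deltas: tuple[float, ...]
    components: tuple[str, ...]
    # (component, delta, year, sex) -> prevalence %
    values: dict[tuple[str, float, int, str], float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"component": c, "delta": d, "year": y, "sex": s, "prevalence_pct": v}
            for (c, d, y, s), v in self.values.items()
        ]
        return pd.DataFrame(rows)

    def spread(self, component: str, year: int, sex: str) -> float:
        """Max - min prevalence across the perturbation range (%p)."""
        vals = [
            v for (c, d, y, s), v in self.values.items()
            if c == component and y == year and s == sex
        ]
        return max(vals) - min(vals)

    def max_abs_change(self, component: str) -> float:
        """Largest |perturbed - unperturbed| over report years and sexes."""
        out = 0.0
        for (c, d, y, s), v in self.values.items():
            if c == component and d != 0.0:
                out = max(out, abs(v - self.values[(c, 0.0, y, s)]))
        return out


def one_way_grid(
    baseline: Baseline,
    scenario: Scenario,
    components: tuple[str, ...] = COMPONENTS,
    deltas: tuple[float, ...] = (-0.5, -0.25, 0.0, 0.25, 0.5),
    years: tuple[int, ...] = REPORT_YEARS,
    table: PolicyEffectTable | None = None,
) -> OneWayGrid:
    """Full one-way grid over components and perturbations."""
    table = table or PolicyEffectTable.default()
    base_series = run_scenario(baseline, scenario, table)
    values: dict[tuple[str, float, int, str], float] = {}
    for comp in components:
        for d in deltas:
            series = base_series if d == 0.0 else one_way(
                baseline, scenario, comp, d, table
            )
            for y in years:
                for s in REPORT_SEXES:
                    values[(comp, d, y, s)] = series.value(y, s)
    return OneWayGrid(scenario.name, tuple(deltas), tuple(components), values)


# ----------------------------------------------------------------------
def bc_percentile(
    draws: np.ndarray, point: float, level: float = 0.95
) -> tuple[float, float]:
    """Bias-corrected percentile interval.

    The bias correction ``z0`` is the normal quantile of the fraction of
    draws below the point estimate; the interval endpoints are the
    empirical quantiles at ``Phi(2 z0 +/- z_{alpha/2})``.  With exactly
    half the draws below the point this reduces to the plain percentile
    interval.  If every draw lies on one side of the point, ``z0`` is
    infinite and the plain percentile interval is returned with a warning.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 2:
        raise ValidationError("need at least 2 draws for an interval")
    alpha = 1.0 - level
    prop = float(np.mean(draws < point))
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn(
            "all draws on one side of the point estimate; "
            "falling back to the plain percentile interval"
        )
        lo, hi = alpha / 2, 1 - alpha / 2
    else:
        z0 = stats.norm.ppf(prop)
        za = stats.norm.ppf(1 - alpha / 2)
        lo = float(stats.norm.cdf(2 * z0 - za))
        hi = float(stats.norm.cdf(2 * z0 + za))
    return (
        float(np.quantile(draws, lo)),
        float(np.quantile(draws, hi)),
    )


@dataclass
class PsaResult:
    """Probabilistic sensitivity analysis summary."""

    scenario: str
    n_draws: int
    seed: int
    beta_shape: float
    # (year, sex) -> point estimate / draws / CI
    point: dict[tuple[int, str], float]
    draws: dict[tuple[int, str], np.ndarray]
    ci: dict[tuple[int, str], tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, pt in self.point.items():
            lo, hi = self.ci[key]
            rows.append(
                {"year": key[0], "sex": key[1], "point_pct": pt,
                 "ci_lower_pct": lo, "ci_upper_pct": hi}
            )
        return pd.DataFrame(rows)


def sample_component_scales(
    rng: np.random.Generator, shape: float = 7.5
) -> dict[str, float]:
    """One PSA draw: per-component scale from Beta(shape, shape) on [0.5, 1.5].

    Mean is 1 by symmetry; ``shape = 7.5`` gives a standard deviation of
    0.125 on the unit-width support.
    """
    return {c: 0.5 + float(rng.beta(shape, shape)) for c in COMPONENTS}


def psa(
    baseline: Baseline,
    scenario: Scenario,
    n_draws: int = 1000,
    seed: int = 0,
    beta_shape: float = 7.5,
    years: tuple[int, ...] = REPORT_YEARS,
    table: PolicyEffectTable | None = None,
    level: float = 0.95,
) -> PsaResult:
    """Monte-Carlo uncertainty analysis over the policy-effect parameters."""
    if n_draws < 2:
        raise ValidationError("n_draws must be >= 2")
    table = table or PolicyEffectTable.default()
    rng = np.random.default_rng(seed)

    base_series = run_scenario(baseline, scenario, table)
    point = {
        (y, s): base_series.value(y, s) for y in years for s in REPORT_SEXES
    }
    draws: dict[tuple[int, str], list[float]] = {k: [] for k in point}
    for _ in range(n_draws):
        scales = sample_component_scales(rng, beta_shape)
        t = table
        for comp, sc in scales.items():
            t = t.scaled(comp, sc)
        series = run_scenario(baseline, scenario, t)
        for k in draws:
            draws[k].append(series.value(k[0], k[1]))

    arr = {k: np.array(v) for k, v in draws.items()}
    ci = {}
    for k, v in arr.items():
        if np.ptp(v) < 1e-12:
            warnings.warn("degenerate all-equal draws; interval collapses to a point")
            ci[k] = (float(v[0]), float(v[0]))
        else:
            ci[k] = bc_percentile(v, point[k], level)
    return PsaResult(scenario.name, n_draws, seed, beta_shape, point, arr, ci)
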