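"""Tabular output, run configuration and the survey comparator hook."""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import HorizonError, ValidationError
from .scenarios import ProjectionSeries

log = logging.getLogger("smokesim")


def round_half_up(x, decimals: int = 1):
    """Decimal rounding with ties away from zero, as in printed tables."""
    factor = 10.0 ** decimals
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def render_scenario_table(
    results: list[ProjectionSeries],
    years: tuple[int, ...],
    sex: str = "male",
    decimals: int = 1,
) -> pd.DataFrame:
    """Scenario-by-year prevalence table (rows in input order, 1 decimal)."""
    horizons = {tuple(r.year.tolist()) for r in results}
    if len(horizons) > 1:
        raise HorizonError("all series must share the same horizon")
    rows = {}
    for r in results:
        rows[r.scenario] = [round_half_up(r.value(y, sex), decimals) for y in years]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(years))


def format_table(table: pd.DataFrame) -> str:
    """Aligned-text rendering of a scenario table."""
    return table.to_string(float_format=lambda v: f"{v:.1f}")


def compare_to_survey(series: ProjectionSeries, survey: pd.DataFrame) -> pd.DataFrame:
    """Per-year deviation of the projection from a user-supplied survey series.

    ``survey`` must have columns year, sex, prevalence_pct.  Purely
    descriptive: returns model, survey and difference per matched row.
    """
    required = {"year", "sex", "prevalence_pct"}
    if required - set(survey.columns):
        raise ValidationError(
            f"survey frame missing columns: {sorted(required - set(survey.columns))}"
        )
    model = series.to_frame().rename(columns={"prevalence_pct": "model_pct"})
    merged = survey.merge(model, on=["year", "sex"], how="inner")
    if merged.empty:
        raise ValidationError("no overlapping (year, sex) rows between survey and model")
    merged["difference_pp"] = merged["model_pct"] - merged["prevalence_pct"]
    return merged[["year", "sex", "prevalence_pct", "model_pct", "difference_pp"]]


def max_abs_deviation(report: pd.DataFrame) -> float:
    return float(report["difference_pp"].abs().max())


@dataclass
class RunConfig:
    """Configuration of a reproducible scenario run."""

    baseline_dir: str
    scenarios: list[str]
    report_years: tuple[int, ...] = (2022, 2025, 2030, 2035, 2040, 2045, 2050)
    seed: int = 0
    output_dir: str = "results"
    log_level: str = "INFO"
    decimals: int = 1
    extra: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "extra"},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def log_provenance(self) -> None:
        log.info(
            "smokesim %s | config %s | seed %d",
            __version__, self.config_hash(), self.seed,
        )
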