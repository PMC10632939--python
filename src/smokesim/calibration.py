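"""Synthetic Korea-like baseline and its calibration.

The measured inputs behind the original projection (census population,
fertility/mortality life tables, survey-derived initiation/cessation/
relapse schedules) are not published.  This module generates a stylized
stand-in — a smooth below-replacement age pyramid, Gompertz-like
mortality, and parametric smoking schedules — and calibrates a small
number of scale/shape parameters so that the status-quo projection
reproduces the published prevalence trajectory anchors.

The 2022 starting state is built to match the anchor starting prevalences
exactly: each cohort's smoking-state mix is the outcome of running that
cohort through the schedules from birth, with a historical-initiation
elevation factor (older cohorts initiated more) solved so the adult
prevalence hits the target.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import InfeasibleTargetError, ValidationError
from .grid import CURRENT, FORMER_FIRST, FORMER_WIDTHS, NEVER, N_AGES, N_STATES, PopulationGrid
from .rates import DemographicRates, TransitionRates
from .scenarios import Baseline, build_scenario, run_scenario

ANCHOR_YEARS = (2025, 2030, 2035, 2040, 2045, 2050)


@dataclass
class CalibrationAnchors:
    """Published prevalence values the synthetic baseline must reproduce."""

    start_prevalence: tuple[float, float] = (35.3, 3.6)  # (male, female) in 2022
    status_quo_path_male: dict[int, float] = field(
        default_factory=lambda: {2025: 34.0, 2030: 32.2, 2035: 30.7,
                                 2040: 29.4, 2045: 28.3, 2050: 27.6}
    )
    status_quo_path_female: dict[int, float] = field(
        default_factory=lambda: {2025: 3.5, 2030: 3.3, 2035: 3.3,
                                 2040: 3.2, 2045: 3.1, 2050: 3.1}
    )
    adult_age_min: int = 19

    def __post_init__(self):
        for v in (*self.start_prevalence, *self.status_quo_path_male.values(),
                  *self.status_quo_path_female.values()):
            if not 0.0 <= v <= 100.0:
                raise ValidationError("anchor prevalences must lie in [0, 100]")
        male = [self.status_quo_path_male[y] for y in sorted(self.status_quo_path_male)]
        if np.any(np.diff(male) > 1e-9):
            raise ValidationError("male status-quo path must be non-increasing")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationAnchors":
        male = frame[frame.sex == "male"].set_index("year")["prevalence_pct"]
        female = frame[frame.sex == "female"].set_index("year")["prevalence_pct"]
        return cls(
            start_prevalence=(float(male[2022]), float(female[2022])),
            status_quo_path_male={int(y): float(v) for y, v in male.items() if y != 2022},
            status_quo_path_female={int(y): float(v) for y, v in female.items() if y != 2022},
        )

    @classmethod
    def default(cls) -> "CalibrationAnchors":
        import importlib.resources
        import io

        ref = importlib.resources.files("smokesim.data").joinpath("anchors.csv")
        return cls.from_frame(pd.read_csv(io.StringIO(ref.read_text())))

    def items(self):
        for y in sorted(self.status_quo_path_male):
            yield ("male", y, self.status_quo_path_male[y])
        for y in sorted(self.status_quo_path_female):
            yield ("female", y, self.status_quo_path_female[y])


@dataclass
class SyntheticParams:
    """Shape/scale settings of the synthetic baseline generator.

    The free calibration parameters are the initiation and cessation
    scales by sex, the initiation peak age, and the relapse scale; the
    remaining entries fix the stylized demography.
    """

    init_scale_male: float = 0.09     # peak annual initiation probability
    init_scale_female: float = 0.0095
    cess_scale_male: float = 1.0      # multiplier on the age-increasing quit curve
    cess_scale_female: float = 1.0
    init_peak_age: float = 16.4       # mode of the triangular initiation window
    relapse_scale: float = 1.0

    # fixed demography
    cohort_size: float = 1000.0       # newborns per year entering the pyramid
    cohort_shrinkage: float = 0.012   # annual decline of recent birth-cohort sizes
    shrinkage_span: int = 45          # cohorts older than this were of equal size
    tfr: float = 1.05                 # total fertility rate (below replacement)
    sex_ratio_at_birth: float = 0.515
    init_window: tuple[int, int] = (15, 24)
    # current-age span over which historical initiation ramps up to its
    # old-cohort elevation (the epidemic peaked in cohorts now past midlife)
    hist_ramp_ages: tuple[float, float] = (45.0, 68.0)
    # relative all-cause mortality of current smokers vs never smokers;
    # former smokers' excess decays with quit duration toward 1
    smoker_mortality_rr: float = 1.5

    def validate(self):
        if min(self.init_scale_male, self.init_scale_female,
               self.cess_scale_male, self.cess_scale_female,
               self.relapse_scale) < 0:
            raise ValidationError("scales must be >= 0")
        lo, hi = self.init_window
        if not lo < self.init_peak_age < hi + 1:
            raise ValidationError("initiation peak age outside the window")


# ----------------------------------------------------------------------
# stylized demography
def _mortality() -> np.ndarray:
    a = np.arange(N_AGES, dtype=float)
    male = 0.0005 + 2.0e-5 * np.exp(0.095 * a)
    female = 0.0003 + 0.9e-5 * np.exp(0.095 * a)
    return np.clip(np.column_stack([male, female]), 0.0, 0.7)


def _mortality_at(age: np.ndarray, sex: int) -> np.ndarray:
    coef = (0.0005, 2.0e-5) if sex == 0 else (0.0003, 0.9e-5)
    return np.clip(coef[0] + coef[1] * np.exp(0.095 * age), 0.0, 0.7)


def _fertility(tfr: float) -> np.ndarray:
    a = np.arange(N_AGES, dtype=float)
    shape = np.exp(-0.5 * ((a - 32.0) / 4.5) ** 2)
    shape[(a < 18) | (a > 45)] = 0.0
    return shape / shape.sum() * tfr


def _pyramid(params: SyntheticParams) -> np.ndarray:
    """Person counts by (age, sex): shrinking recent cohorts x survivorship."""
    counts = np.zeros((N_AGES, 2))
    for sex in (0, 1):
        frac = params.sex_ratio_at_birth if sex == 0 else 1 - params.sex_ratio_at_birth
        # survivorship to each age, extended beyond 85 for the open bin
        ages_ext = np.arange(111, dtype=float)
        mort = _mortality_at(ages_ext, sex)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - mort[:-1])])
        births = params.cohort_size * frac * (
            1.0 - params.cohort_shrinkage
        ) ** (params.shrinkage_span - np.minimum(np.arange(111), params.shrinkage_span))
        # cohorts born longer ago were larger, up to the shrinkage span
        cohort = births * surv
        counts[:85, sex] = cohort[:85]
        counts[85, sex] = cohort[85:].sum()
    return counts


def _smoking_schedules(params: SyntheticParams) -> TransitionRates:
    lo, hi = params.init_window
    a = np.arange(N_AGES, dtype=float)
    tri = np.zeros(N_AGES)
    peak = params.init_peak_age
    up = (a >= lo) & (a <= peak)
    down = (a > peak) & (a <= hi)
    tri[up] = (a[up] - (lo - 1)) / (peak - (lo - 1))
    tri[down] = ((hi + 1) - a[down]) / ((hi + 1) - peak)
    init = np.column_stack(
        [params.init_scale_male * tri, params.init_scale_female * tri]
    )
    # quitting is rare in young adulthood and accelerates from midlife
    # (health-driven quitting), which produces the hump-shaped
    # prevalence-by-age cross-section seen in survey data
    cess_curve = 0.012 + 0.0010 * np.clip(a - 40.0, 0.0, None)
    cess = np.column_stack(
        [params.cess_scale_male * cess_curve, params.cess_scale_female * cess_curve]
    )
    cess[: lo, :] = 0.0
    base_rel = np.array([0.12, 0.06, 0.03, 0.015, 0.005]) * params.relapse_scale
    relapse = np.column_stack([base_rel, base_rel])
    return TransitionRates(
        np.clip(init, 0.0, 0.95),
        np.clip(cess, 0.0, 0.95),
        np.clip(relapse, 0.0, 0.95),
        params.init_window,
    )


def _cohort_profiles(
    rates: TransitionRates,
    sex: int,
    hist: np.ndarray,
    mortality: np.ndarray | None = None,
    mortality_multiplier: np.ndarray | None = None,
) -> np.ndarray:
    """Smoking-state fractions by current age, shape (86, 7).

    Cohort currently aged ``A`` is simulated from birth through the
    schedules, with its initiation scaled by ``hist[A]`` (a cohort-specific
    historical elevation).  When smoking-state mortality multipliers are
    supplied, states are down-weighted by their relative survival and each
    cohort is renormalized, so the cross-section reflects the selective
    loss of smokers at older ages.
    """
    S = np.zeros((N_AGES, N_STATES))
    S[:, NEVER] = 1.0
    adv = np.zeros(5)
    adv[:4] = 1.0 / FORMER_WIDTHS[:4]
    rel = rates.relapse[:, sex]
    differential = (
        mortality is not None
        and mortality_multiplier is not None
        and np.ptp(mortality_multiplier) > 0
    )
    for a in range(85):
        rows = slice(a + 1, N_AGES)  # cohorts that have lived through age a
        i = np.clip(rates.initiation[a, sex] * hist[rows], 0.0, 0.95)
        c = rates.cessation[a, sex]
        never = S[rows, NEVER]
        cur = S[rows, CURRENT]
        former = S[rows, FORMER_FIRST:]
        new_smokers = never * i
        quitters = cur * c
        relapsers = former * rel[None, :]
        staying = former - relapsers
        moved = staying * adv[None, :]
        S[rows, NEVER] = never - new_smokers
        S[rows, CURRENT] = cur - quitters + new_smokers + relapsers.sum(axis=1)
        nf = staying - moved
        nf[:, 1:] += moved[:, :4]
        nf[:, 0] += quitters
        S[rows, FORMER_FIRST:] = nf
        if differential:
            surv = np.clip(
                1.0 - mortality[a, sex] * mortality_multiplier[None, :], 0.0, 1.0
            )
            S[rows] = S[rows] * surv
    totals = S.sum(axis=1, keepdims=True)
    return S / np.where(totals > 0, totals, 1.0)


def _history_ramp(kappa: float, start: float, end: float) -> np.ndarray:
    """Cohort initiation elevation: 1 for recent cohorts, ``kappa`` for old.

    Ramps linearly over current ages ``start``..``end``, reflecting the
    historical decline in smoking uptake across successive birth cohorts.
    """
    a = np.arange(N_AGES, dtype=float)
    ramp = np.clip((a - start) / (end - start), 0.0, 1.0)
    return 1.0 + (kappa - 1.0) * ramp


def make_synthetic_baseline(
    params: SyntheticParams | None = None,
    anchors: CalibrationAnchors | None = None,
    seed: int = 0,
) -> Baseline:
    """Build the stylized 2022 baseline (population, rates, start state).

    The adult prevalence of the generated grid matches the anchors' 2022
    values exactly, by solving the historical-initiation elevation for each
    sex.  ``seed`` is accepted for interface uniformity; the generator is
    deterministic.
    """
    params = params or SyntheticParams()
    anchors = anchors or CalibrationAnchors.default()
    params.validate()

    excess = params.smoker_mortality_rr - 1.0
    if excess < 0:
        raise ValidationError("smoker_mortality_rr must be >= 1")
    # never, current, former by quit duration (excess fading toward never)
    mort_mult = 1.0 + excess * np.array([0.0, 1.0, 0.8, 0.6, 0.4, 0.2, 0.0])
    demo = DemographicRates(
        _fertility(params.tfr),
        _mortality(),
        mortality_multiplier=mort_mult,
        sex_ratio_at_birth=params.sex_ratio_at_birth,
    )
    rates = _smoking_schedules(params)
    pyramid = _pyramid(params)
    min_age = anchors.adult_age_min

    grid = PopulationGrid(2022)
    for sex in (0, 1):
        target = anchors.start_prevalence[sex]
        weights = pyramid[min_age:, sex]

        ramp_lo, ramp_hi = params.hist_ramp_ages

        def prev_of(kappa: float) -> float:
            S = _cohort_profiles(
                rates, sex, _history_ramp(kappa, ramp_lo, ramp_hi),
                demo.mortality, mort_mult,
            )
            return 100.0 * float(
                np.dot(weights, S[min_age:, CURRENT]) / weights.sum()
            )

        if target <= 0.0:
            S = np.zeros((N_AGES, N_STATES))
            S[:, NEVER] = 1.0
        else:
            init_peak = rates.initiation[:, sex].max()
            if init_peak <= 0.0:
                raise InfeasibleTargetError(
                    f"cannot reach {target}% prevalence with zero initiation"
                )
            k_hi = 0.9 / init_peak
            lo, hi = prev_of(0.0), prev_of(k_hi)
            if not lo <= target <= hi:
                raise InfeasibleTargetError(
                    f"target {target}% outside attainable range "
                    f"[{lo:.2f}, {hi:.2f}] for sex index {sex}"
                )
            kappa = optimize.brentq(
                lambda k: prev_of(k) - target, 0.0, k_hi, xtol=1e-6
            )
            S = _cohort_profiles(
                rates, sex, _history_ramp(kappa, ramp_lo, ramp_hi),
                demo.mortality, mort_mult,
            )
        grid.counts[:, sex, :] = pyramid[:, sex, None] * S
    grid.validate(min_initiation_age=params.init_window[0])
    return Baseline(grid, demo, rates)


# ----------------------------------------------------------------------
@dataclass
class CalibrationResult:
    """Outcome of fitting the synthetic baseline to the anchors."""

    params: SyntheticParams
    baseline: Baseline
    loss: float                     # sum of squared %p deviations at anchors
    converged: bool
    residuals: dict[str, float]     # "sex:year" -> fit - anchor (%p)
    n_eval: int
    settings: dict
    underdetermined: bool = False   # fewer anchors than free parameters

    def max_abs_residual(self) -> float:
        if not self.residuals:
            return 0.0
        return max(abs(v) for v in self.residuals.values())


_FREE = (
    "init_scale_male", "init_scale_female",
    "cess_scale_male", "cess_scale_female",
    "init_peak_age", "relapse_scale",
)
_LOG = {"init_scale_male", "init_scale_female", "cess_scale_male",
        "cess_scale_female", "relapse_scale"}


def _pack(params: SyntheticParams) -> np.ndarray:
    vals = []
    for name in _FREE:
        v = getattr(params, name)
        vals.append(np.log(v) if name in _LOG else v)
    return np.array(vals)


def _unpack(x: np.ndarray, template: SyntheticParams) -> SyntheticParams:
    kw = {}
    for name, v in zip(_FREE, x):
        kw[name] = float(np.exp(v)) if name in _LOG else float(v)
    return replace(template, **kw)


def status_quo_projection(baseline: Baseline, table=None):
    return run_scenario(baseline, build_scenario("status_quo"), table)


def calibration_loss(
    params: SyntheticParams, anchors: CalibrationAnchors
) -> tuple[float, dict[str, float]]:
    """Sum of squared %p deviations between the status-quo projection and
    the anchors (the 2022 values match exactly by construction)."""
    try:
        baseline = make_synthetic_baseline(params, anchors)
        series = status_quo_projection(baseline)
    except (InfeasibleTargetError, ValidationError):
        return 1e6, {}
    residuals = {}
    loss = 0.0
    for sex, year, target in anchors.items():
        dev = series.value(year, sex) - target
        residuals[f"{sex}:{year}"] = dev
        loss += dev * dev
    return loss, residuals


def calibrate(
    anchors: CalibrationAnchors | None = None,
    params0: SyntheticParams | None = None,
    settings: dict | None = None,
) -> CalibrationResult:
    """Fit the free generator parameters to the anchors.

    Derivative-free Nelder-Mead in transformed (log-scale) coordinates,
    with one restart from the incumbent; deterministic.  Non-convergence
    (final loss above ``loss_target``) is flagged, not raised.
    """
    anchors = anchors or CalibrationAnchors.default()
    params0 = params0 or SyntheticParams()
    cfg = {"budget": 1200, "restarts": 1, "loss_target": 0.5,
           "xatol": 1e-3, "fatol": 1e-5}
    cfg.update(settings or {})

    lo_peak, hi_peak = params0.init_window
    n_eval = 0

    def objective(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        p = _unpack(x, params0)
        if not lo_peak + 0.5 <= p.init_peak_age <= hi_peak + 0.5:
            return 1e6
        if not (1e-5 <= p.init_scale_male <= 0.9 and 1e-6 <= p.init_scale_female <= 0.9
                and 0.02 <= p.cess_scale_male <= 50 and 0.02 <= p.cess_scale_female <= 50
                and 0.01 <= p.relapse_scale <= 20):
            return 1e6
        return calibration_loss(p, anchors)[0]

    x = _pack(params0)
    best_x, best_f = x, objective(x)
    rounds = 1 + int(cfg["restarts"])
    per_round = max(50, int(cfg["budget"]) // rounds)
    for _ in range(rounds):
        res = optimize.minimize(
            objective, best_x, method="Nelder-Mead",
            options={"maxfev": per_round, "xatol": cfg["xatol"],
                     "fatol": cfg["fatol"], "adaptive": True},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, float(res.fun)

    if best_f >= 1e6:
        raise InfeasibleTargetError(
            "no feasible generator parameters found for these anchors"
        )
    params = _unpack(best_x, params0)
    loss, residuals = calibration_loss(params, anchors)
    baseline = make_synthetic_baseline(params, anchors)
    n_anchors = len(list(anchors.items()))
    return CalibrationResult(
        params=params,
        baseline=baseline,
        loss=loss,
        converged=loss <= cfg["loss_target"],
        underdetermined=n_anchors < len(_FREE),
        residuals=residuals,
        n_eval=n_eval,
        settings={"optimizer": "nelder-mead", **cfg},
    )


# ----------------------------------------------------------------------
def save_baseline(result: CalibrationResult, directory) -> None:
    """Write a calibrated baseline as a directory of CSV/JSON files."""
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    b = result.baseline
    b.grid.to_csv(d / "grid_2022.csv")
    b.demo.to_frame().to_csv(d / "demographic_rates.csv", index=False)
    b.rates.to_frame().to_csv(d / "transition_rates.csv", index=False)
    b.rates.relapse_frame().to_csv(d / "relapse_rates.csv", index=False)
    meta = {
        "params": asdict(result.params),
        "loss": result.loss,
        "converged": result.converged,
        "residuals": result.residuals,
        "n_eval": result.n_eval,
        "settings": result.settings,
        "sex_ratio_at_birth": b.demo.sex_ratio_at_birth,
        "mortality_multiplier": b.demo.mortality_multiplier.tolist(),
        "initiation_window": list(b.rates.initiation_window),
    }
    (d / "calibration.json").write_text(json.dumps(meta, indent=2))


def load_baseline(directory) -> Baseline:
    import pathlib

    d = pathlib.Path(directory)
    meta = json.loads((d / "calibration.json").read_text())
    grid = PopulationGrid.from_csv(d / "grid_2022.csv")
    demo = DemographicRates.from_frame(
        pd.read_csv(d / "demographic_rates.csv"),
        sex_ratio_at_birth=meta["sex_ratio_at_birth"],
        mortality_multiplier=np.asarray(meta["mortality_multiplier"]),
    )
    rates = TransitionRates.from_frames(
        pd.read_csv(d / "transition_rates.csv"),
        pd.read_csv(d / "relapse_rates.csv"),
        tuple(meta["initiation_window"]),
    )
    return Baseline(grid, demo, rates)
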