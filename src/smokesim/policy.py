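"""Policy states and their conversion into rate multipliers.

The policy module translates a change in tobacco-control policy levels
(smoke-free air, cessation support, health warnings, advertising bans) and
changes in the real cigarette price into multiplicative adjustments of
smoking prevalence, initiation and cessation.

Conventions:

* Each component's achieved effect at a level is a fraction ``PE``; moving
  from an old to a new level multiplies prevalence (and initiation) by
  ``(1 - PE_new) / (1 - PE_old)`` and cessation by
  ``(1 + CE_new) / (1 + CE_old)``.  Components combine multiplicatively,
  which keeps combined effects below 1 and makes level changes
  path-independent.
* Price effects use age-banded elasticities applied to the proportional
  change in the *real* (inflation-deflated) price between consecutive
  years; cessation moves inversely to prevalence.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import ValidationError
from .grid import N_AGES

CLEAN_AIR_LEVELS = ("none", "partial", "complete")
CESSATION_LEVELS = ("none", "partial", "full")
WARNING_LEVELS = ("low", "high")
AD_BAN_LEVELS = ("none", "partial", "complete", "comprehensive")

COMPONENTS = ("P", "O", "W", "E", "R")

_ELASTICITY_BANDS = (
    ("age_15_17", 15, 17),
    ("age_18_24", 18, 24),
    ("age_25_34", 25, 34),
    ("age_35_plus", 35, 85),
)


@dataclass(frozen=True)
class PriceState:
    """Nominal cigarette price and the deflation assumptions around it."""

    nominal_price: float  # KRW per pack
    tax_share: float = 0.739
    inflation_rate: float = 0.03
    base_year: int = 2022  # CPI deflator base (index 1.0)

    def __post_init__(self):
        if not self.nominal_price > 0:
            raise ValidationError("price must be > 0")
        if not 0.0 < self.tax_share < 1.0:
            raise ValidationError("tax_share must be in (0, 1)")
        if self.inflation_rate < 0:
            raise ValidationError("inflation rate must be >= 0")

    def real_price(self, year: int) -> float:
        return deflate(self.nominal_price, self.base_year, year, self.inflation_rate)


@dataclass(frozen=True)
class PolicyState:
    """Implementation level of each non-price component, plus the price."""

    clean_air: str = "none"
    cessation_support: str = "none"
    warnings: str = "low"
    warnings_enforced: bool = False
    ad_ban: str = "none"
    ad_ban_enforced: bool = False
    price: PriceState = field(default_factory=lambda: PriceState(4500.0))

    def __post_init__(self):
        if self.clean_air not in CLEAN_AIR_LEVELS:
            raise ValidationError(f"unknown clean-air level {self.clean_air!r}")
        if self.cessation_support not in CESSATION_LEVELS:
            raise ValidationError(
                f"unknown cessation-support level {self.cessation_support!r}"
            )
        if self.warnings not in WARNING_LEVELS:
            raise ValidationError(f"unknown warning level {self.warnings!r}")
        if self.ad_ban not in AD_BAN_LEVELS:
            raise ValidationError(f"unknown ad-ban level {self.ad_ban!r}")


@dataclass
class PolicyMultipliers:
    """Multiplicative adjustment per age: prevalence, initiation, cessation."""

    prevalence: np.ndarray
    initiation: np.ndarray
    cessation: np.ndarray

    @classmethod
    def identity(cls) -> "PolicyMultipliers":
        return cls(np.ones(N_AGES), np.ones(N_AGES), np.ones(N_AGES))

    @classmethod
    def uniform(cls, prevalence: float, initiation: float, cessation: float):
        return cls(
            np.full(N_AGES, prevalence),
            np.full(N_AGES, initiation),
            np.full(N_AGES, cessation),
        )

    def __mul__(self, other: "PolicyMultipliers") -> "PolicyMultipliers":
        return PolicyMultipliers(
            self.prevalence * other.prevalence,
            self.initiation * other.initiation,
            self.cessation * other.cessation,
        )

    def validate(self) -> None:
        for name in ("prevalence", "initiation", "cessation"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValidationError(f"{name} multipliers must be finite and > 0")


class PolicyEffectTable:
    """All policy effect sizes and price elasticities, loadable from YAML."""

    def __init__(self, data: dict):
        self.data = data
        self._validate()

    @classmethod
    def default(cls) -> "PolicyEffectTable":
        ref = importlib.resources.files("smokesim.data").joinpath("effects.yaml")
        return cls(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_yaml(cls, path) -> "PolicyEffectTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def _validate(self) -> None:
        for section in ("clean_air", "cessation_treatment", "warnings", "ad_ban",
                        "price_elasticity"):
            if section not in self.data:
                raise ValidationError(f"effect table missing section {section!r}")
        for name, _, _ in _ELASTICITY_BANDS:
            e = self.data["price_elasticity"][name]
            if e > 0:
                raise ValidationError("elasticities must be <= 0")
        mags = [abs(self.data["price_elasticity"][n]) for n, _, _ in _ELASTICITY_BANDS]
        if np.any(np.diff(mags) > 1e-12):
            raise ValidationError("elasticity magnitude must be non-increasing with age")
        for frac in self._iter_fractions():
            if not 0.0 <= frac < 1.0:
                raise ValidationError("effect fractions must lie in [0, 1)")

    def _iter_fractions(self):
        d = self.data
        for venue in ("workplace", "restaurant", "bars_other"):
            yield from d["clean_air"][venue].values()
        yield d["cessation_treatment"]["prevalence_reduction"]
        for lvl in ("high", "low"):
            yield from d["warnings"][lvl].values()
        yield d["warnings"]["enforcement_publicity"]
        for lvl in ("comprehensive", "complete", "partial"):
            yield from d["ad_ban"][lvl].values()
        yield d["ad_ban"]["enforcement_publicity"]

    # ------------------------------------------------------------------
    def elasticity_by_age(self) -> np.ndarray:
        eps = np.zeros(N_AGES)
        for name, lo, hi in _ELASTICITY_BANDS:
            eps[lo : hi + 1] = self.data["price_elasticity"][name]
        return eps

    @property
    def multiplier_floor(self) -> float:
        return float(self.data.get("multiplier_floor", 0.2))

    def scaled(self, component: str, factor: float) -> "PolicyEffectTable":
        """A copy with every effect size of one MPOWER component scaled.

        Effect fractions are clipped to [0, 0.95]; elasticities (component
        ``R``) are scaled without sign change.  Used by sensitivity
        analyses.
        """
        if component not in COMPONENTS:
            raise ValidationError(f"unknown component {component!r}")
        import copy

        d = copy.deepcopy(self.data)

        def scale_frac(x: float) -> float:
            return float(np.clip(x * factor, 0.0, 0.95))

        if component == "P":
            for venue in ("workplace", "restaurant", "bars_other"):
                d["clean_air"][venue] = {
                    k: scale_frac(v) for k, v in d["clean_air"][venue].items()
                }
        elif component == "O":
            d["cessation_treatment"]["prevalence_reduction"] = scale_frac(
                d["cessation_treatment"]["prevalence_reduction"]
            )
            d["cessation_treatment"]["cessation_rate_increase"] = max(
                0.0, d["cessation_treatment"]["cessation_rate_increase"] * factor
            )
        elif component == "W":
            for lvl in ("high", "low"):
                d["warnings"][lvl] = {
                    k: scale_frac(v) for k, v in d["warnings"][lvl].items()
                }
            d["warnings"]["enforcement_publicity"] = scale_frac(
                d["warnings"]["enforcement_publicity"]
            )
        elif component == "E":
            for lvl in ("comprehensive", "complete", "partial"):
                d["ad_ban"][lvl] = {
                    k: scale_frac(v) for k, v in d["ad_ban"][lvl].items()
                }
            d["ad_ban"]["enforcement_publicity"] = scale_frac(
                d["ad_ban"]["enforcement_publicity"]
            )
        elif component == "R":
            d["price_elasticity"] = {
                k: v * factor for k, v in d["price_elasticity"].items()
            }
        return PolicyEffectTable(d)


# ----------------------------------------------------------------------
def _component_effects(state: PolicyState, table: PolicyEffectTable):
    """Achieved (prevalence, initiation, cessation) effect fractions per
    component at the given policy state.  Prevalence/initiation entries are
    reductions ``PE``; cessation entries are rate increases ``CE``.
    """
    d = table.data
    eff = {}

    # P — clean air: venue effects combine multiplicatively; applied equally
    # to prevalence, initiation and cessation
    if state.clean_air == "none":
        pe_p = 0.0
    else:
        keep = 1.0
        for venue in ("workplace", "restaurant", "bars_other"):
            keep *= 1.0 - d["clean_air"][venue][state.clean_air]
        pe_p = 1.0 - keep
    eff["P"] = (pe_p, pe_p, pe_p)

    # O — cessation treatment: prevalence reduction + cessation-rate increase;
    # no initiation effect
    frac = {"none": 0.0, "partial": d["cessation_treatment"]["partial_fraction"],
            "full": 1.0}[state.cessation_support]
    eff["O"] = (
        frac * d["cessation_treatment"]["prevalence_reduction"],
        0.0,
        frac * d["cessation_treatment"]["cessation_rate_increase"],
    )

    # W — health warnings
    w = d["warnings"][state.warnings]
    bump = d["warnings"]["enforcement_publicity"] if state.warnings_enforced else 0.0
    eff["W"] = (w["prevalence"] + bump, w["initiation"] + bump, w["cessation"] + bump)

    # E — advertising ban
    if state.ad_ban == "none":
        e = {"prevalence": 0.0, "initiation": 0.0, "cessation": 0.0}
    else:
        e = d["ad_ban"][state.ad_ban]
    bump = d["ad_ban"]["enforcement_publicity"] if state.ad_ban_enforced else 0.0
    eff["E"] = (e["prevalence"] + bump, e["initiation"] + bump, e["cessation"] + bump)
    return eff


def level_change_multipliers(
    old: PolicyState, new: PolicyState, table: PolicyEffectTable
) -> PolicyMultipliers:
    """Multipliers implied by moving from one non-price policy state to
    another.  Identical states give the identity."""
    eff_old = _component_effects(old, table)
    eff_new = _component_effects(new, table)
    prev = init = 1.0
    cess = 1.0
    for comp in ("P", "O", "W", "E"):
        pe_o, ie_o, ce_o = eff_old[comp]
        pe_n, ie_n, ce_n = eff_new[comp]
        if pe_n >= 1.0 or pe_o >= 1.0 or ie_n >= 1.0 or ie_o >= 1.0:
            raise ValidationError("achieved effect fraction >= 1")
        prev *= (1.0 - pe_n) / (1.0 - pe_o)
        init *= (1.0 - ie_n) / (1.0 - ie_o)
        cess *= (1.0 + ce_n) / (1.0 + ce_o)
    out = PolicyMultipliers.uniform(prev, init, cess)
    out.validate()
    return out


def price_multipliers(
    price_old_real: float, price_new_real: float, table: PolicyEffectTable
) -> PolicyMultipliers:
    """Multipliers implied by a real price change between consecutive years.

    Prevalence and initiation move by ``1 + elasticity * dP/P`` (floored);
    cessation moves inversely, bounded by the reciprocal floor.
    """
    if price_old_real <= 0 or price_new_real <= 0:
        raise ValidationError("real prices must be > 0")
    rel = (price_new_real - price_old_real) / price_old_real
    eps = table.elasticity_by_age()
    floor = table.multiplier_floor
    pm = np.clip(1.0 + eps * rel, floor, 1.0 / floor)
    out = PolicyMultipliers(pm.copy(), pm.copy(), 1.0 / pm)
    out.validate()
    return out


def deflate(nominal: float, base_year: int, target_year: int, inflation_rate: float) -> float:
    """Real value of ``nominal`` in base-year units after cumulative inflation."""
    return nominal / (1.0 + inflation_rate) ** (target_year - base_year)


# Korea's assessed policy state in 2022: partially implemented smoke-free
# laws, partial cessation support, strong warnings without extra
# enforcement/publicity, a partial advertising ban, and a KRW 4500 pack price.
KOREA_2022 = PolicyState(
    clean_air="partial",
    cessation_support="partial",
    warnings="high",
    warnings_enforced=False,
    ad_ban="partial",
    ad_ban_enforced=False,
    price=PriceState(4500.0),
)

# Full-strength non-price policies: complete smoke-free laws, full cessation
# support including brief interventions, strong warnings with enforcement and
# publicity, and a comprehensive advertising ban with enforcement.
FULL_POWE = replace(
    KOREA_2022,
    clean_air="complete",
    cessation_support="full",
    warnings="high",
    warnings_enforced=True,
    ad_ban="comprehensive",
    ad_ban_enforced=True,
)
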