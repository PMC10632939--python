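"""Demographic and smoking-transition rate tables.

All rates are annual probabilities.  Demographic rates (fertility,
mortality) drive the population projection; transition rates (initiation,
cessation, relapse) drive the smoking-state distribution within each
age-sex cohort.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import N_AGES, N_FORMER, N_STATES, SEXES

DEFAULT_INITIATION_WINDOW = (15, 24)


def _check_prob(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class DemographicRates:
    """Fertility, mortality and the male fraction of births.

    ``fertility`` — births per woman per year by maternal age, shape (86,).
    ``mortality`` — annual death probability by (age, sex), shape (86, 2).
    ``mortality_multiplier`` — relative mortality by smoking state, shape
    (7,); defaults to 1 everywhere (no differential smoker mortality).
    ``sex_ratio_at_birth`` — fraction of births that are male.
    """

    fertility: np.ndarray
    mortality: np.ndarray
    mortality_multiplier: np.ndarray = field(
        default_factory=lambda: np.ones(N_STATES)
    )
    sex_ratio_at_birth: float = 0.515

    def __post_init__(self) -> None:
        self.fertility = np.asarray(self.fertility, dtype=float)
        self.mortality = np.asarray(self.mortality, dtype=float)
        self.mortality_multiplier = np.asarray(self.mortality_multiplier, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.fertility.shape != (N_AGES,):
            raise ValidationError(f"fertility must have shape ({N_AGES},)")
        if self.mortality.shape != (N_AGES, 2):
            raise ValidationError(f"mortality must have shape ({N_AGES}, 2)")
        if self.mortality_multiplier.shape != (N_STATES,):
            raise ValidationError(
                f"mortality_multiplier must have shape ({N_STATES},)"
            )
        if not np.all(np.isfinite(self.fertility)) or np.any(self.fertility < 0):
            raise ValidationError("fertility must be finite and >= 0")
        _check_prob("mortality", self.mortality)
        if not np.all(self.mortality_multiplier > 0):
            raise ValidationError("mortality multipliers must be > 0")
        if not 0.0 < self.sex_ratio_at_birth < 1.0:
            raise ValidationError("sex_ratio_at_birth must be in (0, 1)")

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in range(N_AGES):
            rows.append(
                {
                    "age": a,
                    "fertility": self.fertility[a],
                    "mortality_male": self.mortality[a, 0],
                    "mortality_female": self.mortality[a, 1],
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        sex_ratio_at_birth: float = 0.515,
        mortality_multiplier: np.ndarray | None = None,
    ) -> "DemographicRates":
        required = {"age", "fertility", "mortality_male", "mortality_female"}
        if required - set(frame.columns):
            raise ValidationError(
                f"demographic frame missing columns: {sorted(required - set(frame.columns))}"
            )
        frame = frame.sort_values("age")
        fert = np.zeros(N_AGES)
        mort = np.zeros((N_AGES, 2))
        fert[frame["age"].to_numpy()] = frame["fertility"].to_numpy()
        mort[frame["age"].to_numpy(), 0] = frame["mortality_male"].to_numpy()
        mort[frame["age"].to_numpy(), 1] = frame["mortality_female"].to_numpy()
        kwargs = {}
        if mortality_multiplier is not None:
            kwargs["mortality_multiplier"] = mortality_multiplier
        return cls(fert, mort, sex_ratio_at_birth=sex_ratio_at_birth, **kwargs)


@dataclass
class TransitionRates:
    """Annual smoking-state transition probabilities.

    ``initiation`` — P(never -> current) by (age, sex); nonzero only inside
    the initiation window.
    ``cessation`` — P(current -> former, first duration bin) by (age, sex).
    ``relapse`` — P(former -> current) by (quit-duration category, sex),
    non-increasing in duration.
    """

    initiation: np.ndarray
    cessation: np.ndarray
    relapse: np.ndarray
    initiation_window: tuple[int, int] = DEFAULT_INITIATION_WINDOW

    def __post_init__(self) -> None:
        self.initiation = np.asarray(self.initiation, dtype=float)
        self.cessation = np.asarray(self.cessation, dtype=float)
        self.relapse = np.asarray(self.relapse, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.initiation.shape != (N_AGES, 2):
            raise ValidationError(f"initiation must have shape ({N_AGES}, 2)")
        if self.cessation.shape != (N_AGES, 2):
            raise ValidationError(f"cessation must have shape ({N_AGES}, 2)")
        if self.relapse.shape != (N_FORMER, 2):
            raise ValidationError(f"relapse must have shape ({N_FORMER}, 2)")
        _check_prob("initiation", self.initiation)
        _check_prob("cessation", self.cessation)
        _check_prob("relapse", self.relapse)
        lo, hi = self.initiation_window
        outside = np.ones(N_AGES, dtype=bool)
        outside[lo : hi + 1] = False
        if np.any(self.initiation[outside] > 0):
            raise ValidationError(
                f"initiation must be zero outside ages [{lo}, {hi}]"
            )
        if np.any(np.diff(self.relapse, axis=0) > 1e-12):
            raise ValidationError("relapse must be non-increasing in quit duration")

    def copy(self) -> "TransitionRates":
        return TransitionRates(
            self.initiation.copy(),
            self.cessation.copy(),
            self.relapse.copy(),
            self.initiation_window,
        )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in range(N_AGES):
            rows.append(
                {
                    "age": a,
                    "initiation_male": self.initiation[a, 0],
                    "initiation_female": self.initiation[a, 1],
                    "cessation_male": self.cessation[a, 0],
                    "cessation_female": self.cessation[a, 1],
                }
            )
        return pd.DataFrame(rows)

    def relapse_frame(self) -> pd.DataFrame:
        cats = ["1-2", "3-5", "6-10", "11-15", "16+"]
        return pd.DataFrame(
            {
                "quit_duration": cats,
                "relapse_male": self.relapse[:, 0],
                "relapse_female": self.relapse[:, 1],
            }
        )

    @classmethod
    def from_frames(
        cls,
        rate_frame: pd.DataFrame,
        relapse_frame: pd.DataFrame,
        initiation_window: tuple[int, int] = DEFAULT_INITIATION_WINDOW,
    ) -> "TransitionRates":
        init = np.zeros((N_AGES, 2))
        cess = np.zeros((N_AGES, 2))
        ages = rate_frame["age"].to_numpy()
        init[ages, 0] = rate_frame["initiation_male"].to_numpy()
        init[ages, 1] = rate_frame["initiation_female"].to_numpy()
        cess[ages, 0] = rate_frame["cessation_male"].to_numpy()
        cess[ages, 1] = rate_frame["cessation_female"].to_numpy()
        rel = np.column_stack(
            [
                relapse_frame["relapse_male"].to_numpy(),
                relapse_frame["relapse_female"].to_numpy(),
            ]
        )
        return cls(init, cess, rel, initiation_window)

    def to_json(self) -> str:
        return json.dumps(
            {
                "initiation": self.initiation.tolist(),
                "cessation": self.cessation.tolist(),
                "relapse": self.relapse.tolist(),
                "initiation_window": list(self.initiation_window),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TransitionRates":
        obj = json.loads(text)
        return cls(
            np.asarray(obj["initiation"]),
            np.asarray(obj["cessation"]),
            np.asarray(obj["relapse"]),
            tuple(obj["initiation_window"]),
        )
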