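"""Population state container.

The model state at one calendar year is a dense array of person counts
indexed by single year of age (0..84 plus an open-ended 85+ bin), sex, and
smoking state.  Former smokers are split by time since quitting, because
relapse risk falls steeply with quit duration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

N_AGES = 86  # ages 0..84 in single years; index 85 is the open-ended 85+ bin
AGE_CAP = 85

SEXES = ("male", "female")
MALE, FEMALE = 0, 1

STATES = (
    "never",
    "current",
    "former_1_2",
    "former_3_5",
    "former_6_10",
    "former_11_15",
    "former_16p",
)
NEVER, CURRENT = 0, 1
FORMER_FIRST, FORMER_LAST = 2, 6
N_STATES = len(STATES)
N_FORMER = FORMER_LAST - FORMER_FIRST + 1

# nominal widths (years) of the quit-duration categories; the last is absorbing
FORMER_WIDTHS = np.array([2.0, 3.0, 5.0, 5.0, np.inf])


@dataclass
class PopulationGrid:
    """Person counts by (age, sex, smoking state) at one calendar year.

    ``counts`` has shape ``(86, 2, 7)`` — age x sex x state — and holds
    non-negative (fractional) person counts.
    """

    year: int
    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_AGES, 2, N_STATES))
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_AGES, 2, N_STATES):
            raise ValidationError(
                f"counts must have shape {(N_AGES, 2, N_STATES)}, "
                f"got {self.counts.shape}"
            )

    # ------------------------------------------------------------------
    def validate(self, min_initiation_age: int | None = None) -> None:
        """Raise :class:`ValidationError` on negative/non-finite counts.

        If ``min_initiation_age`` is given, additionally require that no one
        below that age has ever smoked.
        """
        if not np.all(np.isfinite(self.counts)):
            raise ValidationError("grid contains non-finite counts")
        if np.any(self.counts < -1e-9):
            raise ValidationError("grid contains negative counts")
        if min_initiation_age is not None:
            juvenile = self.counts[:min_initiation_age, :, 1:]
            if np.any(juvenile > 1e-9):
                raise ValidationError(
                    f"non-zero smoking counts below age {min_initiation_age}"
                )

    # ------------------------------------------------------------------
    def copy(self) -> "PopulationGrid":
        return PopulationGrid(self.year, self.counts.copy())

    def population(self) -> np.ndarray:
        """Total persons by (age, sex), summed over smoking states."""
        return self.counts.sum(axis=2)

    def total(self) -> float:
        return float(self.counts.sum())

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format view: year, age, sex, state, count."""
        ages, sexes, states = np.meshgrid(
            np.arange(N_AGES), np.arange(2), np.arange(N_STATES), indexing="ij"
        )
        return pd.DataFrame(
            {
                "year": self.year,
                "age": ages.ravel(),
                "sex": np.asarray(SEXES)[sexes.ravel()],
                "state": np.asarray(STATES)[states.ravel()],
                "count": self.counts.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationGrid":
        required = {"year", "age", "sex", "state", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"grid frame missing columns: {sorted(missing)}")
        years = frame["year"].unique()
        if len(years) != 1:
            raise ValidationError("grid frame must contain exactly one year")
        grid = cls(int(years[0]))
        sex_idx = frame["sex"].map({s: i for i, s in enumerate(SEXES)})
        state_idx = frame["state"].map({s: i for i, s in enumerate(STATES)})
        if sex_idx.isna().any() or state_idx.isna().any():
            raise ValidationError("unknown sex or state label in grid frame")
        grid.counts[frame["age"].to_numpy(), sex_idx.to_numpy(), state_idx.to_numpy()] = (
            frame["count"].to_numpy()
        )
        return grid

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PopulationGrid":
        return cls.from_frame(pd.read_csv(path))
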