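"""Age-indexed mortality inputs.

The cohort model needs an annual all-cause death probability ``q_all`` for
every age from the cohort start age to a terminal age, plus (optionally) an
annual probability that an incident cardiovascular event is fatal
(``cvd_fatality``).  Published period life tables supply the former; the
package also ships a synthetic Gompertz generator so every stage is runnable
without external downloads.

CSV format: header columns ``age,q_all[,cvd_fatality]``, one row per year of
age, ages contiguous, probabilities in [0, 1], final row ``q_all = 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "load_life_table",
    "save_life_table",
    "make_gompertz_life_table",
]


@dataclass(frozen=True)
class LifeTable:
    ages: np.ndarray
    q_all: np.ndarray
    cvd_fatality: np.ndarray | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_all, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_all", q)
        if ages.size == 0:
            raise ValueError("life table is empty")
        if ages.size != q.size:
            raise ValueError("age and q_all columns differ in length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous and strictly increasing")
        if np.any((q < 0.0) | (q > 1.0)):
            bad = q[(q < 0.0) | (q > 1.0)][0]
            raise ValueError(f"q_all contains probability outside [0, 1]: {bad}")
        if self.cvd_fatality is not None:
            cf = np.asarray(self.cvd_fatality, dtype=float)
            object.__setattr__(self, "cvd_fatality", cf)
            if cf.size != ages.size:
                raise ValueError("cvd_fatality column length mismatch")
            if np.any((cf < 0.0) | (cf > 1.0)):
                raise ValueError("cvd_fatality contains probability outside [0, 1]")
        adult = ages >= 30
        if adult.sum() > 1 and np.any(np.diff(q[adult]) < 0):
            warnings.warn(
                "q_all decreases with age above 30; check the table",
                stacklevel=2,
            )

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def mortality_at(self, age: int) -> float:
        """Annual all-cause death probability at ``age`` (1.0 past terminal)."""
        if age < self.min_age:
            raise ValueError(f"age {age} below life-table coverage ({self.min_age}+)")
        if age > self.max_age:
            return 1.0
        return float(self.q_all[int(age) - self.min_age])

    def case_fatality_at(self, age: int, default: float = 0.10) -> float:
        """CVD case-fatality probability at ``age`` (column value or default)."""
        if self.cvd_fatality is None or age > self.max_age:
            return default
        if age < self.min_age:
            raise ValueError(f"age {age} below life-table coverage ({self.min_age}+)")
        return float(self.cvd_fatality[int(age) - self.min_age])

    def survival_from(self, age: int) -> np.ndarray:
        """S(t): probability of surviving t further years from ``age``.

        ``S(0) = 1``; the curve is non-increasing and reaches 0 by the cycle
        after the terminal age.
        """
        idx = int(age) - self.min_age
        if idx < 0:
            raise ValueError(f"age {age} below life-table coverage ({self.min_age}+)")
        q = self.q_all[idx:]
        return np.concatenate([[1.0], np.cumprod(1.0 - q)])

    def life_expectancy(self, age: int) -> float:
        """Remaining life expectancy at ``age`` (trapezoid over survival)."""
        s = self.survival_from(age)
        return float(np.trapezoid(s, dx=1.0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"age": self.ages, "q_all": self.q_all})
        if self.cvd_fatality is not None:
            df["cvd_fatality"] = self.cvd_fatality
        return df


def load_life_table(path) -> LifeTable:
    """Read and validate a life table from CSV.

    The final row is coerced to ``q_all = 1`` (with a warning) so the cohort
    always terminates.
    """
    # round_trip parsing keeps write->read cycles bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"age", "q_all"} - set(df.columns)
    if missing:
        raise ValueError(f"life table {path}: missing columns {sorted(missing)}")
    q = df["q_all"].to_numpy(dtype=float)
    if q[-1] != 1.0:
        warnings.warn(
            f"life table {path}: terminal q_all={q[-1]} coerced to 1.0",
            stacklevel=2,
        )
        q = q.copy()
        q[-1] = 1.0
    cf = df["cvd_fatality"].to_numpy(dtype=float) if "cvd_fatality" in df else None
    return LifeTable(df["age"].to_numpy(), q, cf)


def save_life_table(table: LifeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def make_gompertz_life_table(
    a: float,
    b: float,
    max_age: int = 110,
    min_age: int = 0,
    cvd_fatality: float | None = 0.10,
) -> LifeTable:
    """Synthetic life table with Gompertz mortality.

    The annual hazard at age x is ``a * exp(b * x)``, so the annual death
    probability is ``q(x) = 1 - exp(-a * exp(b * x))``; the terminal row is
    forced to ``q = 1``.  With b > 0, q is strictly increasing in age; in the
    b -> 0 limit it is the constant ``1 - exp(-a)``.
    """
    if a <= 0.0 or b <= 0.0:
        raise ValueError(f"Gompertz parameters must be > 0; got a={a}, b={b}")
    ages = np.arange(min_age, max_age + 1)
    q = 1.0 - np.exp(-a * np.exp(b * ages))
    q[-1] = 1.0
    cf = None if cvd_fatality is None else np.full(ages.size, cvd_fatality)
    return LifeTable(ages, q, cf)
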