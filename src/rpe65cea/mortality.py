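"""Background mortality from period life tables.

The two-state (alive/dead) Markov transition uses general-population
age- and sex-specific annual death probabilities q(x).  Any national
period life table can be supplied as a CSV (``age,qx_female,qx_male``,
consecutive integer ages from 0).  The package also ships a deterministic
Gompertz-Makeham generator that approximates modern German mortality, so
the pipeline builds without downloads; a real table is a drop-in via the
CSV interface.

No excess mortality from visual impairment is applied in either arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .population import SEX_FEMALE, SEX_MALE


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard mu(age) = A + B * exp(C * age).

    A is the age-independent (background) hazard per year, B the baseline
    senescent hazard, C the senescence rate.  Defaults give a female life
    expectancy at birth of about 84 years.
    """

    A: float = 2.2e-4
    B: float = 2.7e-5
    C: float = 0.098

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ConfigError(f"Gompertz-Makeham A must be >= 0, got {self.A}")
        if self.B <= 0:
            raise ConfigError(f"Gompertz-Makeham B must be > 0, got {self.B}")
        if self.C <= 0:
            raise ConfigError(f"Gompertz-Makeham C must be > 0, got {self.C}")


class LifeTable:
    """Age x sex annual death probabilities, integer ages 0..max_age.

    The terminal age is absorbing: q(max_age) is forced to 1 so every
    trajectory ends by max_age + 1.
    """

    def __init__(self, qx_female, qx_male, max_age: int | None = None) -> None:
        qf = np.asarray(qx_female, dtype=float).copy()
        qm = np.asarray(qx_male, dtype=float).copy()
        if qf.ndim != 1 or qm.ndim != 1 or len(qf) != len(qm) or len(qf) < 2:
            raise ConfigError("life table needs two equal-length 1-D qx arrays")
        if max_age is None:
            max_age = len(qf) - 1
        if max_age != len(qf) - 1:
            raise ConfigError(
                f"max_age {max_age} inconsistent with array length {len(qf)}"
            )
        for name, q in (("qx_female", qf), ("qx_male", qm)):
            if np.any((q < 0) | (q > 1)):
                bad = int(np.argmax((q < 0) | (q > 1)))
                raise ConfigError(
                    f"{name}[{bad}] = {q[bad]} outside [0, 1]"
                )
        qf[-1] = 1.0
        qm[-1] = 1.0
        self.max_age = int(max_age)
        self.qx_female = qf
        self.qx_male = qm

    def qx(self, sex: str) -> np.ndarray:
        if sex == SEX_FEMALE:
            return self.qx_female
        if sex == SEX_MALE:
            return self.qx_male
        raise ConfigError(f"unknown sex {sex!r}")

    def survival_curve(self, sex: str) -> np.ndarray:
        """S(a) = P(alive at exact age a | alive at 0), a = 0..max_age+1."""
        q = self.qx(sex)
        s = np.empty(self.max_age + 2)
        s[0] = 1.0
        s[1:] = np.cumprod(1.0 - q)
        return s

    def life_expectancy(self, sex: str, age: int = 0) -> float:
        """Curtate-plus-half life expectancy at an exact integer age."""
        s = self.survival_curve(sex)
        if not 0 <= age <= self.max_age:
            raise ConfigError(f"age {age} outside table range")
        if s[age] == 0.0:
            return 0.0
        return float(s[age + 1:].sum() / s[age]) + 0.5


def annual_death_prob(table: LifeTable, age: float, sex: str) -> float:
    """q(floor(age)) for the given sex; ages above max_age return 1."""
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    iage = int(age)
    if iage > table.max_age:
        return 1.0
    return float(table.qx(sex)[iage])


def generate_life_table(
    params: GompertzMakehamParams = GompertzMakehamParams(),
    sex_ratio_adjust: float = 1.6,
    max_age: int = 100,
) -> LifeTable:
    """Deterministic synthetic life table from a Gompertz-Makeham hazard.

    q(age) = 1 - exp(-(A + B*exp(C*age))) for females; the male table uses
    the female hazard scaled by ``sex_ratio_adjust`` (> 1 means excess male
    mortality, the empirical norm).
    """
    if sex_ratio_adjust <= 0:
        raise ConfigError("sex_ratio_adjust must be > 0")
    ages = np.arange(max_age + 1, dtype=float)
    hazard = params.A + params.B * np.exp(params.C * ages)
    qf = np.minimum(1.0, 1.0 - np.exp(-hazard))
    qm = np.minimum(1.0, 1.0 - np.exp(-sex_ratio_adjust * hazard))
    return LifeTable(qf, qm, max_age=max_age)


def write_life_table(table: LifeTable, path) -> None:
    """CSV with header ``age,qx_female,qx_male``; full float precision."""
    df = pd.DataFrame(
        {
            "age": np.arange(table.max_age + 1),
            "qx_female": table.qx_female,
            "qx_male": table.qx_male,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_life_table(path) -> LifeTable:
    """Read and validate a life-table CSV (see :func:`write_life_table`)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["age", "qx_female", "qx_male"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"life table CSV missing columns: {missing}")
    ages = df["age"].to_numpy()
    for i, a in enumerate(ages):
        if int(a) != i:
            raise FormatError(
                f"life table CSV row {i}: expected consecutive age {i}, got {a}"
            )
    for col in ("qx_female", "qx_male"):
        q = df[col].to_numpy(dtype=float)
        bad = np.flatnonzero((q < 0) | (q > 1) | ~np.isfinite(q))
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"life table CSV row {i}: {col} = {q[i]} outside [0, 1]"
            )
    return LifeTable(df["qx_female"].to_numpy(dtype=float),
                     df["qx_male"].to_numpy(dtype=float))
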