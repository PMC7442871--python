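"""Cohort sampling.

Simulated patients mirror the phase-III trial population for biallelic
RPE65-mediated inherited retinal degeneration: young (mean 15.1 y, range
4-44), majority female (58%), with severely reduced best-corrected visual
acuity (BCVA, logMAR; higher is worse) and a constricted kinetic visual
field (VF, Goldmann III4e sum total degrees; higher is better).  Baseline
BCVA/VF distributions differ by treatment arm because the trial arms did.

Ages are drawn from a normal distribution truncated (by rejection) to the
trial's age range; BCVA and VF are normal draws clamped to their
physiological bounds.  Each patient carries an individual onset age,
uniform on a configurable window, before which BCVA is naturally stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

ARM_VN = "VN"
ARM_SOC = "SoC"
SEX_FEMALE = "female"
SEX_MALE = "male"

_ARMS = (ARM_VN, ARM_SOC)
_SEXES = (SEX_FEMALE, SEX_MALE)


@dataclass(frozen=True)
class ArmBaseline:
    """Baseline BCVA/VF distribution for one treatment arm."""

    bcva_mean: float
    bcva_sd: float
    vf_mean: float
    vf_sd: float

    def __post_init__(self) -> None:
        if self.bcva_sd < 0 or self.vf_sd < 0:
            raise ConfigError("baseline SDs must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to sample one trial-like cohort.

    Defaults are the trial baselines; ``n_patients`` must be even because
    the cohort is split equally between the VN and SoC arms.
    """

    n_patients: int = 70
    fraction_female: float = 0.58
    age_mean: float = 15.1
    age_sd: float = 10.9
    age_range: tuple[float, float] = (4.0, 44.0)
    onset_window: tuple[float, float] = (15.0, 20.0)
    baseline_vn: ArmBaseline = field(
        default_factory=lambda: ArmBaseline(1.137, 0.369, 332.9, 413.3)
    )
    baseline_soc: ArmBaseline = field(
        default_factory=lambda: ArmBaseline(0.987, 0.306, 427.1, 372.0)
    )
    # Clamp bounds for sampled states; keep consistent with ProgressionParams.
    bcva_bounds: tuple[float, float] = (-0.3, 2.3)
    vf_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_patients % 2 != 0:
            raise ConfigError(
                f"n_patients must be a positive even count, got {self.n_patients}"
            )
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ConfigError(
                f"fraction_female must be in [0, 1], got {self.fraction_female}"
            )
        if self.age_sd < 0:
            raise ConfigError("age_sd must be >= 0")
        lo, hi = self.age_range
        if lo > hi:
            raise ConfigError(f"age_range min > max: {self.age_range}")
        if lo < 0:
            raise ConfigError("age_range must be non-negative")
        olo, ohi = self.onset_window
        if olo > ohi:
            raise ConfigError(f"onset_window min > max: {self.onset_window}")
        blo, bhi = self.bcva_bounds
        if blo > bhi:
            raise ConfigError(f"bcva_bounds min > max: {self.bcva_bounds}")


@dataclass(slots=True)
class Patient:
    """One simulated individual at baseline."""

    id: int
    age: float
    sex: str
    bcva: float
    vf: float
    onset_age: float
    arm: str

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ConfigError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.arm not in _ARMS:
            raise ConfigError(f"arm must be one of {_ARMS}, got {self.arm!r}")
        if self.vf < 0:
            raise ConfigError(f"vf must be >= 0, got {self.vf}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sample N(mean, sd) restricted to [lo, hi]."""
    if sd == 0.0:
        if lo <= mean <= hi:
            return mean
        raise ConfigError(
            f"degenerate truncated normal: mean {mean} outside [{lo}, {hi}]"
        )
    for _ in range(1_000_000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise ConfigError(
        f"truncated normal rejection failed: N({mean}, {sd}) on [{lo}, {hi}]"
    )


def sample_cohort(spec: CohortSpec, rng: np.random.Generator) -> list[Patient]:
    """Sample ``spec.n_patients`` patients, exactly half per arm.

    Draw order (fixed for reproducibility): ages, sexes, onset ages, arm
    permutation, then per-patient arm-specific BCVA/VF.  Arm assignment is
    a random permutation with the first half treated (VN), which realises
    "chosen by random draws" while guaranteeing the even split.
    """
    n = spec.n_patients
    ages = [
        _truncated_normal(rng, spec.age_mean, spec.age_sd, *spec.age_range)
        for _ in range(n)
    ]
    sexes = [SEX_FEMALE if rng.random() < spec.fraction_female else SEX_MALE
             for _ in range(n)]
    olo, ohi = spec.onset_window
    onsets = [float(rng.uniform(olo, ohi)) for _ in range(n)]
    order = rng.permutation(n)
    arms = [ARM_SOC] * n
    for idx in order[: n // 2]:
        arms[idx] = ARM_VN

    blo, bhi = spec.bcva_bounds
    patients: list[Patient] = []
    for i in range(n):
        base = spec.baseline_vn if arms[i] == ARM_VN else spec.baseline_soc
        bcva = min(max(rng.normal(base.bcva_mean, base.bcva_sd), blo), bhi)
        vf = max(rng.normal(base.vf_mean, base.vf_sd), spec.vf_floor)
        patients.append(
            Patient(id=i, age=ages[i], sex=sexes[i], bcva=float(bcva),
                    vf=float(vf), onset_age=onsets[i], arm=arms[i])
        )
    return patients


_COHORT_COLUMNS = ["id", "age", "sex", "bcva", "vf", "onset_age", "arm"]


def cohort_to_csv(patients: Sequence[Patient], path) -> None:
    """Write a cohort as CSV (one row per patient)."""
    df = pd.DataFrame(
        [[p.id, p.age, p.sex, p.bcva, p.vf, p.onset_age, p.arm] for p in patients],
        columns=_COHORT_COLUMNS,
    )
    df.to_csv(path, index=False)


def cohort_from_csv(path) -> list[Patient]:
    """Read a cohort written by :func:`cohort_to_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cohort CSV missing columns: {missing}")
    return [
        Patient(id=int(r.id), age=float(r.age), sex=str(r.sex),
                bcva=float(r.bcva), vf=float(r.vf),
                onset_age=float(r.onset_age), arm=str(r.arm))
        for r in df.itertuples(index=False)
    ]


def with_n_patients(spec: CohortSpec, n: int) -> CohortSpec:
    """Convenience copy of a spec with a different cohort size."""
    return replace(spec, n_patients=n)
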