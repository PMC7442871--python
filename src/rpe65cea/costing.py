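"""Direct and indirect costs per annual cycle, with discounting.

Direct costs (German payer prices, EUR): the one-time bilateral VN
treatment bundle in year 1 (drug + pharmacy surcharge + DRG G18Z
reimbursement, each per eye and doubled, plus four quarterly outpatient
fees), then one reimbursed annual check thereafter.  The SoC arm accrues
the annual check in every year.

Indirect costs (societal perspective) depend on the visual-impairment
band of the patient's decimal acuity (10^-logMAR): band A < 0.02,
band B [0.02, 0.05), band C [0.05, 0.3); decimal acuity >= 0.3 accrues
nothing.  Band values are per 6 months, so annual cost is twice the band
sum of medical + non-medical + general components.  The default mode uses
band means deterministically; a sampled mode draws each component from a
zero-clipped normal (the published SDs are enormous relative to the
means, so sampling inflates the expectation and is off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .population import ARM_VN

BAND_A = "A"
BAND_B = "B"
BAND_C = "C"
BAND_NONE = "none"


@dataclass(frozen=True)
class DirectCostSchedule:
    """Per-item direct costs in EUR (per eye where noted)."""

    drug_per_eye: float = 410_550.0
    pharmacy_per_eye: float = 2_000.0
    drg_per_eye: float = 2_840.0
    outpatient_per_quarter: float = 220.0
    vn_year1_quarters: int = 4
    followup_visits_per_year: int = 1

    def __post_init__(self) -> None:
        for name in ("drug_per_eye", "pharmacy_per_eye", "drg_per_eye",
                     "outpatient_per_quarter"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.vn_year1_quarters < 0 or self.followup_visits_per_year < 0:
            raise ConfigError("visit counts must be >= 0")

    def scaled(self, factor: float) -> "DirectCostSchedule":
        """All monetary components multiplied by ``factor`` (sensitivity)."""
        return DirectCostSchedule(
            drug_per_eye=self.drug_per_eye * factor,
            pharmacy_per_eye=self.pharmacy_per_eye * factor,
            drg_per_eye=self.drg_per_eye * factor,
            outpatient_per_quarter=self.outpatient_per_quarter * factor,
            vn_year1_quarters=self.vn_year1_quarters,
            followup_visits_per_year=self.followup_visits_per_year,
        )


@dataclass(frozen=True)
class BandCosts:
    """Indirect cost components for one impairment band, EUR per 6 months."""

    medical: float
    medical_sd: float
    nonmedical: float
    nonmedical_sd: float
    general: float
    general_sd: float

    def __post_init__(self) -> None:
        for name in ("medical", "medical_sd", "nonmedical", "nonmedical_sd",
                     "general", "general_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"indirect cost {name} must be >= 0")


@dataclass(frozen=True)
class IndirectCostTable:
    """Published indirect costs by decimal-acuity band (per 6 months)."""

    band_a: BandCosts = field(
        default_factory=lambda: BandCosts(5116, 9938, 10_868, 115_022, 3948, 7437)
    )
    band_b: BandCosts = field(
        default_factory=lambda: BandCosts(3342, 4854, 3940, 21_011, 3934, 7892)
    )
    band_c: BandCosts = field(
        default_factory=lambda: BandCosts(2400, 5483, 1207, 6442, 3061, 6891)
    )

    def for_band(self, band: str) -> BandCosts:
        if band == BAND_A:
            return self.band_a
        if band == BAND_B:
            return self.band_b
        if band == BAND_C:
            return self.band_c
        raise ConfigError(f"no indirect costs for band {band!r}")


@dataclass(frozen=True)
class DiscountParams:
    """Annual discount rates for costs and QALYs (base case 3% each)."""

    rate_costs: float = 0.03
    rate_qalys: float = 0.03

    def __post_init__(self) -> None:
        if self.rate_costs < 0 or self.rate_qalys < 0:
            raise ConfigError("discount rates must be >= 0")


def direct_cost(arm: str, year_index: int, s: DirectCostSchedule) -> float:
    """Direct cost in EUR for one arm-year (1-based year index).

    VN year 1 carries the bilateral treatment bundle; every other
    arm-year is the annual outpatient check.
    """
    if year_index < 1:
        raise ConfigError(f"year_index must be >= 1, got {year_index}")
    if arm == ARM_VN and year_index == 1:
        bundle = 2.0 * (s.drug_per_eye + s.pharmacy_per_eye + s.drg_per_eye)
        return bundle + s.vn_year1_quarters * s.outpatient_per_quarter
    return s.followup_visits_per_year * s.outpatient_per_quarter


def bcva_band(bcva: float) -> str:
    """Impairment band of a logMAR acuity via decimal acuity 10^(-bcva)."""
    decimal = 10.0 ** (-bcva)
    if decimal < 0.02:
        return BAND_A
    if decimal < 0.05:
        return BAND_B
    if decimal < 0.3:
        return BAND_C
    return BAND_NONE


def indirect_annual_cost(band: str, table: IndirectCostTable,
                         mode: str = "mean",
                         rng: np.random.Generator | None = None) -> float:
    """Annual indirect cost (EUR) for one impairment band.

    Mean mode doubles the band's 6-month component means.  Sampled mode
    doubles the sum of three zero-clipped normal draws instead.
    """
    if band == BAND_NONE:
        return 0.0
    b = table.for_band(band)
    if mode == "mean":
        return 2.0 * (b.medical + b.nonmedical + b.general)
    if mode == "sampled":
        if rng is None:
            raise ConfigError("sampled indirect-cost mode needs an rng")
        total = 0.0
        for mean, sd in ((b.medical, b.medical_sd),
                         (b.nonmedical, b.nonmedical_sd),
                         (b.general, b.general_sd)):
            total += max(0.0, float(rng.normal(mean, sd)))
        return 2.0 * total
    raise ConfigError(f"unknown indirect-cost mode {mode!r}")


def discount_factor(year_index: int, rate: float) -> float:
    """(1 + rate)^-(year_index - 1); the first model year is undiscounted."""
    if year_index < 1:
        raise ConfigError(f"year_index must be >= 1, got {year_index}")
    if rate < 0:
        raise ConfigError(f"rate must be >= 0, got {rate}")
    return (1.0 + rate) ** (-(year_index - 1))
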