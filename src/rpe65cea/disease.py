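"""Natural history, treatment effect, and the utility mapping.

Visual function is tracked as two patient-level scalars: BCVA in logMAR
(higher = worse acuity) and VF as Goldmann III4e sum total degrees
(higher = larger field).  Natural history is piecewise linear: BCVA is
stable until an individual onset age (window 15-20 y) and then worsens at
0.0436 logMAR/year up to a cap; VF declines at 25 deg/year to zero.

The one-time gene therapy is modelled as an arm-specific first-cycle
shift in both endpoints, drawn per patient from the trial's change
distributions.  Under the base case the treated state is then maintained
for life; under the waning scenario it is held for a plateau (10 y) and
then relaxed exponentially over a further 10 years onto the patient's own
counterfactual standard-of-care ("shadow") trajectory.

Health states map to a utility in [u_min, u_max] through a linear
function of two normalised scores (acuity and field).  The literature
supplies no coefficients for this mapping, so the weights are exposed in
configuration and can be calibrated (see :mod:`rpe65cea.calibrate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError
from .population import ARM_VN, Patient

SCENARIO_LIFETIME = "lifetime"
SCENARIO_WANING = "waning"


@dataclass(frozen=True)
class ProgressionParams:
    """Natural-history slopes and state bounds."""

    bcva_age_coeff: float = 0.0436   # logMAR worsening per year after onset
    vf_slope: float = -25.0          # sum total degrees per year (negative)
    bcva_cap: float = 2.3            # worst trackable acuity, logMAR
    bcva_floor: float = -0.3         # best trackable acuity, logMAR
    vf_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.bcva_age_coeff < 0:
            raise ConfigError("bcva_age_coeff must be >= 0")
        if self.vf_slope > 0:
            raise ConfigError("vf_slope must be <= 0")
        if self.bcva_floor > self.bcva_cap:
            raise ConfigError("bcva_floor must be <= bcva_cap")


@dataclass(frozen=True)
class TrialEffect:
    """First-cycle change distribution for one arm (logMAR, degrees)."""

    bcva_change_mean: float
    bcva_change_sd: float
    vf_change_mean: float
    vf_change_sd: float

    def __post_init__(self) -> None:
        if self.bcva_change_sd < 0 or self.vf_change_sd < 0:
            raise ConfigError("effect SDs must be >= 0")


@dataclass(frozen=True)
class TrialEffects:
    """Per-arm first-cycle effects (trial change-from-baseline results)."""

    vn: TrialEffect = field(
        default_factory=lambda: TrialEffect(-0.163, 0.336, 302.1, 289.6)
    )
    soc: TrialEffect = field(
        default_factory=lambda: TrialEffect(-0.312, 0.097, -76.7, 258.7)
    )


@dataclass(frozen=True)
class EffectScenario:
    """How long the treated state persists.

    ``lifetime``: effect maintained for life.  ``waning``: full effect for
    ``plateau_years`` after treatment, then exponential decay of the
    residual effect over ``waning_years`` down to ``residual_floor``,
    after which the patient sits exactly on the shadow SoC trajectory.
    """

    kind: str = SCENARIO_LIFETIME
    plateau_years: float = 10.0
    waning_years: float = 10.0
    residual_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in (SCENARIO_LIFETIME, SCENARIO_WANING):
            raise ConfigError(
                f"scenario kind must be 'lifetime' or 'waning', got {self.kind!r}"
            )
        if self.plateau_years <= 0 or self.waning_years <= 0:
            raise ConfigError("plateau_years and waning_years must be > 0")
        if not 0 <= self.residual_floor < 1:
            raise ConfigError("residual_floor must be in [0, 1)")


@dataclass(frozen=True)
class UtilityParams:
    """Linear utility over normalised acuity/field scores.

    u = u_min + (u_max - u_min) * (w_va * s_va + (1 - w_va) * s_vf) with
    s_va = clamp((bcva_cap_anchor - bcva) / bcva_ref, 0, 1) and
    s_vf = clamp(vf / vf_ref, 0, 1).  u_max anchors the best state
    (normal acuity, full field), u_min the worst (blind).
    """

    u_max: float = 0.85
    u_min: float = 0.40
    w_va: float = 0.5
    bcva_ref: float = 2.3
    vf_ref: float = 1000.0
    bcva_cap_anchor: float = 2.3

    def __post_init__(self) -> None:
        if not (0 <= self.u_min < self.u_max <= 1):
            raise ConfigError(
                f"need 0 <= u_min < u_max <= 1, got ({self.u_min}, {self.u_max})"
            )
        if not 0 <= self.w_va <= 1:
            raise ConfigError(f"w_va must be in [0, 1], got {self.w_va}")
        if self.bcva_ref <= 0 or self.vf_ref <= 0:
            raise ConfigError("bcva_ref and vf_ref must be > 0")

    @property
    def w_vf(self) -> float:
        return 1.0 - self.w_va


def natural_bcva_step(bcva: float, age: float, onset_age: float,
                      p: ProgressionParams) -> float:
    """One year of natural acuity decline (none before the onset age)."""
    if age < onset_age:
        return bcva
    return min(bcva + p.bcva_age_coeff, p.bcva_cap)


def natural_vf_step(vf: float, p: ProgressionParams) -> float:
    """One year of natural field loss, floored at zero."""
    return max(vf + p.vf_slope, p.vf_floor)


def draw_effect_deltas(eff: TrialEffect, rng: np.random.Generator
                       ) -> tuple[float, float]:
    """Per-patient (BCVA delta, VF delta) from the arm's distributions."""
    d_bcva = float(rng.normal(eff.bcva_change_mean, eff.bcva_change_sd))
    d_vf = float(rng.normal(eff.vf_change_mean, eff.vf_change_sd))
    return d_bcva, d_vf


def apply_first_cycle_effect(patient: Patient, effects: TrialEffects,
                             rng: np.random.Generator,
                             p: ProgressionParams = ProgressionParams()
                             ) -> Patient:
    """Return a copy of the patient with its arm's first-cycle deltas applied.

    Both arms receive their arm-specific change-from-baseline draws; the
    result is clamped to [bcva_floor, bcva_cap] and [vf_floor, inf).
    """
    eff = effects.vn if patient.arm == ARM_VN else effects.soc
    d_bcva, d_vf = draw_effect_deltas(eff, rng)
    bcva = min(max(patient.bcva + d_bcva, p.bcva_floor), p.bcva_cap)
    vf = max(patient.vf + d_vf, p.vf_floor)
    return replace(patient, bcva=bcva, vf=vf)


def residual_effect_fraction(scenario: EffectScenario,
                             years_since_treatment: float) -> float:
    """Fraction of the treatment effect remaining t years after dosing.

    Lifetime: always 1.  Waning: 1 through the plateau, then
    exp(-k * (t - plateau)) with k = -ln(residual_floor) / waning_years,
    snapped to 0 once the waning window has elapsed.
    """
    if scenario.kind == SCENARIO_LIFETIME:
        return 1.0
    t = years_since_treatment
    if t <= scenario.plateau_years:
        return 1.0
    if t > scenario.plateau_years + scenario.waning_years:
        return 0.0
    k = -math.log(scenario.residual_floor) / scenario.waning_years
    return math.exp(-k * (t - scenario.plateau_years))


def treated_state(frozen_state: tuple[float, float],
                  shadow_soc_state: tuple[float, float],
                  residual: float,
                  p: ProgressionParams = ProgressionParams()
                  ) -> tuple[float, float]:
    """Blend the maintained post-treatment state with the shadow SoC state.

    state = shadow + residual * (frozen - shadow), componentwise for
    (bcva, vf), clamped to the progression bounds.
    """
    if not 0.0 <= residual <= 1.0:
        raise ConfigError(f"residual must be in [0, 1], got {residual}")
    fb, fv = frozen_state
    sb, sv = shadow_soc_state
    bcva = sb + residual * (fb - sb)
    vf = sv + residual * (fv - sv)
    bcva = min(max(bcva, p.bcva_floor), p.bcva_cap)
    vf = max(vf, p.vf_floor)
    return bcva, vf


def utility(bcva: float, vf: float, u: UtilityParams) -> float:
    """Map a (BCVA, VF) state to a utility in [u_min, u_max]."""
    s_va = (u.bcva_cap_anchor - bcva) / u.bcva_ref
    s_va = min(max(s_va, 0.0), 1.0)
    s_vf = min(max(vf / u.vf_ref, 0.0), 1.0)
    return u.u_min + (u.u_max - u.u_min) * (u.w_va * s_va + u.w_vf * s_vf)
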