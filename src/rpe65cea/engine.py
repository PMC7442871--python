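"""Lifetime annual-cycle microsimulation and the Monte Carlo ensemble.

Each patient is tracked individually through annual cycles until death or
the life table's terminal age.  Per cycle: (1) the alive->dead transition
is drawn from the age/sex death probability; (2) if alive, the visual
state is updated (first cycle: trial effect; later cycles: arm/scenario
rules); (3) discounted utility and discounted direct+indirect costs are
accrued; (4) age advances one year.  A patient who dies in a cycle
accrues nothing in that cycle.

One replicate samples a fresh trial-sized cohort and returns arm means;
the Monte Carlo ensemble repeats this with independent per-replicate seed
streams spawned from a master seed.  Within a replicate four substreams
(cohort, effects, mortality, indirect-cost sampling) are kept separate so
toggling one randomness source leaves the others unchanged — the
common-random-numbers backbone used by calibration and the sensitivity
suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import costing, disease
from .config import ScenarioConfig, config_fingerprint
from .costing import BAND_A, BAND_B, BAND_C, BAND_NONE
from .disease import SCENARIO_LIFETIME
from .errors import ConfigError
from .mortality import LifeTable, generate_life_table, read_life_table
from .population import ARM_VN, SEX_FEMALE, Patient, sample_cohort


@dataclass(slots=True)
class CycleRecord:
    """State and accruals for one patient-year."""

    cycle: int
    age: float
    bcva: float
    vf: float
    alive: bool
    utility: float
    cost_direct: float
    cost_indirect: float
    discounted_qaly: float
    discounted_cost: float


@dataclass(frozen=True)
class SimResult:
    """Arm means and deltas for one Monte Carlo replicate.

    ``icur`` is NaN (with ``icur_defined`` False) when delta_qaly is 0.
    The ``dl``/``sva``/``svf`` fields decompose each arm's discounted
    QALYs into the utility-parameter-independent functionals
    (discounted alive-time, discounted acuity score, discounted field
    score); they let utility parameters be re-evaluated without re-running
    trajectories.
    """

    sim_id: int
    qaly_vn: float
    qaly_soc: float
    cost_vn: float
    cost_soc: float
    delta_qaly: float
    delta_cost: float
    icur: float
    icur_defined: bool
    dl_vn: float = 0.0
    sva_vn: float = 0.0
    svf_vn: float = 0.0
    dl_soc: float = 0.0
    sva_soc: float = 0.0
    svf_soc: float = 0.0


@dataclass(frozen=True)
class Ensemble:
    """All replicates of one scenario run."""

    results: list[SimResult]
    config_fingerprint: str
    master_seed: int

    def __len__(self) -> int:
        return len(self.results)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sim_id": [r.sim_id for r in self.results],
                "qaly_vn": [r.qaly_vn for r in self.results],
                "qaly_soc": [r.qaly_soc for r in self.results],
                "cost_vn": [r.cost_vn for r in self.results],
                "cost_soc": [r.cost_soc for r in self.results],
                "delta_qaly": [r.delta_qaly for r in self.results],
                "delta_cost": [r.delta_cost for r in self.results],
                "icur": [r.icur for r in self.results],
            }
        )


# Band thresholds on the logMAR scale: decimal = 10^-bcva, so
# decimal < d  <=>  bcva > -log10(d).  Bands are lower-closed on the
# decimal scale, hence upper-closed on logMAR.
_BCVA_BAND_A = -math.log10(0.02)   # 1.69897...
_BCVA_BAND_B = -math.log10(0.05)   # 1.30103...
_BCVA_BAND_C = -math.log10(0.3)    # 0.52288...


class _RunContext:
    """Precomputed per-run constants for the hot per-cycle loop."""

    def __init__(self, config: ScenarioConfig, life_table: LifeTable) -> None:
        self.config = config
        self.table = life_table
        self.max_age = life_table.max_age
        self.progression = config.progression
        self.effects = config.effects
        self.scenario = config.scenario
        self.utility = config.utility
        n = self.max_age + 3
        dc = config.costs.discount
        self.df_costs = [costing.discount_factor(t, dc.rate_costs)
                         for t in range(1, n + 1)]
        self.df_qalys = [costing.discount_factor(t, dc.rate_qalys)
                         for t in range(1, n + 1)]
        self.qx_f = life_table.qx_female.tolist()
        self.qx_m = life_table.qx_male.tolist()
        s = config.costs.direct
        self.direct_vn_y1 = costing.direct_cost(ARM_VN, 1, s)
        self.direct_yn = s.followup_visits_per_year * s.outpatient_per_quarter
        tab = config.costs.indirect
        if config.costs.include_indirect:
            self.indirect_mean = {
                BAND_A: costing.indirect_annual_cost(BAND_A, tab),
                BAND_B: costing.indirect_annual_cost(BAND_B, tab),
                BAND_C: costing.indirect_annual_cost(BAND_C, tab),
                BAND_NONE: 0.0,
            }
        else:
            self.indirect_mean = {BAND_A: 0.0, BAND_B: 0.0, BAND_C: 0.0,
                                  BAND_NONE: 0.0}
        self.sampled_indirect = (config.costs.include_indirect
                                 and config.costs.indirect_mode == "sampled")


def _band_from_bcva(bcva: float) -> str:
    if bcva > _BCVA_BAND_A:
        return BAND_A
    if bcva > _BCVA_BAND_B:
        return BAND_B
    if bcva > _BCVA_BAND_C:
        return BAND_C
    return BAND_NONE


def _simulate(patient: Patient, ctx: _RunContext,
              eff_rng: np.random.Generator, mort_rng: np.random.Generator,
              cost_rng: np.random.Generator | None = None,
              max_cycles: int | None = None,
              collect_records: bool = False):
    """Shared cycle loop.

    Returns ``(totals, records)`` where totals is the tuple
    (disc_qaly, disc_cost, disc_alive, disc_sva, disc_svf, life_years)
    and records is a list of CycleRecord (empty unless requested).
    """
    p = ctx.progression
    u = ctx.utility
    scen = ctx.scenario
    lifetime = scen.kind == SCENARIO_LIFETIME
    is_vn = patient.arm == ARM_VN
    qx = ctx.qx_f if patient.sex == SEX_FEMALE else ctx.qx_m
    max_age = ctx.max_age

    # All effect draws happen up-front so the effect stream advances by a
    # fixed amount per patient regardless of scenario or lifespan.  VN
    # patients also draw their counterfactual SoC ("shadow") deltas.
    d_bcva, d_vf = disease.draw_effect_deltas(
        ctx.effects.vn if is_vn else ctx.effects.soc, eff_rng)
    if is_vn:
        sh_d_bcva, sh_d_vf = disease.draw_effect_deltas(ctx.effects.soc, eff_rng)

    bcva = patient.bcva
    vf = patient.vf
    age = patient.age
    onset = patient.onset_age
    bcva_floor = p.bcva_floor
    bcva_cap = p.bcva_cap
    vf_floor = p.vf_floor
    coeff = p.bcva_age_coeff
    slope = p.vf_slope
    spread = u.u_max - u.u_min
    w_va = u.w_va
    w_vf = 1.0 - w_va
    inv_bref = 1.0 / u.bcva_ref
    inv_vref = 1.0 / u.vf_ref
    cap_anchor = u.bcva_cap_anchor
    df_c = ctx.df_costs
    df_q = ctx.df_qalys
    ind_mean = ctx.indirect_mean
    indirect_tab = ctx.config.costs.indirect
    sampled = ctx.sampled_indirect

    shadow_bcva = shadow_vf = frozen_bcva = frozen_vf = 0.0
    dq = dc = dl = sva = svf = ly = 0.0
    records: list[CycleRecord] = []
    t = 1
    while int(age) <= max_age and (max_cycles is None or t <= max_cycles):
        q = qx[int(age)]
        if mort_rng.random() < q:
            if collect_records:
                records.append(CycleRecord(t, age, bcva, vf, False,
                                           0.0, 0.0, 0.0, 0.0, 0.0))
            break
        # --- state update ---
        if t == 1:
            bcva = min(max(bcva + d_bcva, bcva_floor), bcva_cap)
            vf = max(vf + d_vf, vf_floor)
            if is_vn:
                frozen_bcva, frozen_vf = bcva, vf
                shadow_bcva = min(max(patient.bcva + sh_d_bcva, bcva_floor),
                                  bcva_cap)
                shadow_vf = max(patient.vf + sh_d_vf, vf_floor)
        elif is_vn:
            if not lifetime:
                if age >= onset:
                    shadow_bcva = min(shadow_bcva + coeff, bcva_cap)
                shadow_vf = max(shadow_vf + slope, vf_floor)
                r = disease.residual_effect_fraction(scen, t - 1)
                if r >= 1.0:
                    bcva, vf = frozen_bcva, frozen_vf
                elif r <= 0.0:
                    bcva, vf = shadow_bcva, shadow_vf
                else:
                    bcva = shadow_bcva + r * (frozen_bcva - shadow_bcva)
                    vf = shadow_vf + r * (frozen_vf - shadow_vf)
                    bcva = min(max(bcva, bcva_floor), bcva_cap)
                    vf = max(vf, vf_floor)
        else:
            if age >= onset:
                bcva = min(bcva + coeff, bcva_cap)
            vf = max(vf + slope, vf_floor)
        # --- utility ---
        s_va = (cap_anchor - bcva) * inv_bref
        if s_va < 0.0:
            s_va = 0.0
        elif s_va > 1.0:
            s_va = 1.0
        s_vf = vf * inv_vref
        if s_vf < 0.0:
            s_vf = 0.0
        elif s_vf > 1.0:
            s_vf = 1.0
        util = u.u_min + spread * (w_va * s_va + w_vf * s_vf)
        # --- costs ---
        direct = ctx.direct_vn_y1 if (is_vn and t == 1) else ctx.direct_yn
        band = _band_from_bcva(bcva)
        if sampled:
            indirect = costing.indirect_annual_cost(
                band, indirect_tab, mode="sampled", rng=cost_rng)
        else:
            indirect = ind_mean[band]
        # --- accrual ---
        dfq = df_q[t - 1]
        dfc = df_c[t - 1]
        dq += dfq * util
        dc += dfc * (direct + indirect)
        dl += dfq
        sva += dfq * s_va
        svf += dfq * s_vf
        ly += 1.0
        if collect_records:
            records.append(CycleRecord(t, age, bcva, vf, True, util,
                                       direct, indirect,
                                       dfq * util, dfc * (direct + indirect)))
        age += 1.0
        t += 1
    return (dq, dc, dl, sva, svf, ly), records


def resolve_life_table(config: ScenarioConfig) -> LifeTable:
    """Life table from the configured CSV path or the synthetic generator."""
    m = config.mortality
    if m.life_table_path is not None:
        return read_life_table(m.life_table_path)
    return generate_life_table(m.gompertz_makeham, m.sex_ratio_adjust,
                               max_age=config.max_age)


def simulate_patient(patient: Patient, config: ScenarioConfig,
                     rng: np.random.Generator,
                     life_table: LifeTable | None = None,
                     max_cycles: int | None = None) -> list[CycleRecord]:
    """Full per-cycle trajectory of one patient.

    The single ``rng`` serves both the first-cycle effect draws (consumed
    up-front) and the per-cycle mortality draws, in that order.
    """
    if life_table is None:
        life_table = resolve_life_table(config)
    ctx = _RunContext(config, life_table)
    _, records = _simulate(patient, ctx, rng, rng, cost_rng=rng,
                           max_cycles=max_cycles, collect_records=True)
    return records


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def run_simulation(config: ScenarioConfig, sim_seed,
                   life_table: LifeTable | None = None,
                   sim_id: int = 0) -> SimResult:
    """One Monte Carlo replicate: fresh cohort, per-patient simulation,
    arm means of discounted QALYs/costs, deltas (VN - SoC) and ICUR."""
    if life_table is None:
        life_table = resolve_life_table(config)
    ctx = _RunContext(config, life_table)
    ss = _as_seedseq(sim_seed)
    cohort_ss, eff_ss, mort_ss, cost_ss = ss.spawn(4)
    cohort_rng = np.random.default_rng(cohort_ss)
    eff_rng = np.random.default_rng(eff_ss)
    mort_rng = np.random.default_rng(mort_ss)
    cost_rng = np.random.default_rng(cost_ss)

    patients = sample_cohort(config.cohort, cohort_rng)
    sums = {True: [0.0] * 6, False: [0.0] * 6}
    counts = {True: 0, False: 0}
    for patient in patients:
        totals, _ = _simulate(patient, ctx, eff_rng, mort_rng, cost_rng)
        acc = sums[patient.arm == ARM_VN]
        for i, v in enumerate(totals):
            acc[i] += v
        counts[patient.arm == ARM_VN] += 1
    n_vn, n_soc = counts[True], counts[False]
    vn = [v / n_vn for v in sums[True]]
    soc = [v / n_soc for v in sums[False]]
    delta_qaly = vn[0] - soc[0]
    delta_cost = vn[1] - soc[1]
    defined = delta_qaly != 0.0
    icur = delta_cost / delta_qaly if defined else math.nan
    return SimResult(
        sim_id=sim_id,
        qaly_vn=vn[0], qaly_soc=soc[0], cost_vn=vn[1], cost_soc=soc[1],
        delta_qaly=delta_qaly, delta_cost=delta_cost,
        icur=icur, icur_defined=defined,
        dl_vn=vn[2], sva_vn=vn[3], svf_vn=vn[4],
        dl_soc=soc[2], sva_soc=soc[3], svf_soc=soc[4],
    )


def run_monte_carlo(config: ScenarioConfig, n_sims: int | None = None,
                    master_seed: int | None = None,
                    progress: bool = False) -> Ensemble:
    """Run the full Monte Carlo ensemble (default 1000 replicates)."""
    if n_sims is None:
        n_sims = config.n_sims
    if master_seed is None:
        master_seed = config.master_seed
    if n_sims < 1:
        raise ConfigError(f"n_sims must be >= 1, got {n_sims}")
    life_table = resolve_life_table(config)
    children = np.random.SeedSequence(master_seed).spawn(n_sims)
    iterator = range(n_sims)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="replicates", unit="rep")
    results = [
        run_simulation(config, children[i], life_table=life_table, sim_id=i)
        for i in iterator
    ]
    return Ensemble(results=results,
                    config_fingerprint=config_fingerprint(config),
                    master_seed=master_seed)
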