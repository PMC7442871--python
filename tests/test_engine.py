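"""Microsimulation engine: cycle mechanics, determinism, aggregation."""

from dataclasses import replace

import numpy as np
import pytest

from rpe65cea import (CohortSpec, DiscountParams, LifeTable, Patient,
                      UtilityParams, run_monte_carlo, run_simulation,
                      simulate_patient)
from rpe65cea.engine import _RunContext, _simulate, resolve_life_table

from _reference import reference_patient_totals


def _zero_sd_config(base_config, zero_sd_effects):
    return replace(base_config, effects=zero_sd_effects)


class TestThreeCycleOracle:
    """Hand-computed 3-cycle spreadsheet check: SoC patient, no mortality,
    all SDs zero, 3% discounting."""

    def _expected(self):
        # cycle 1: trial SoC deltas; cycles 2-3: natural steps; band C costs
        rows = []
        bcva, vf = 0.987 - 0.312, 427.1 - 76.7
        for t in (1, 2, 3):
            if t > 1:
                bcva = bcva + 0.0436       # age 31, 32 >= onset 17
                vf = vf - 25.0
            s_va = (2.3 - bcva) / 2.3
            s_vf = vf / 1000.0
            u = 0.40 + 0.45 * (0.5 * s_va + 0.5 * s_vf)
            cost = 220.0 + 13_336.0        # annual check + band C indirect
            df = 1.03 ** (-(t - 1))
            rows.append((u * df, cost * df))
        return (sum(r[0] for r in rows), sum(r[1] for r in rows))

    def test_totals_match_hand_computation(self, base_config, zero_sd_effects,
                                           immortal_table):
        cfg = _zero_sd_config(base_config, zero_sd_effects)
        patient = Patient(0, 30.0, "female", 0.987, 427.1, 17.0, "SoC")
        records = simulate_patient(patient, cfg, np.random.default_rng(0),
                                   life_table=immortal_table, max_cycles=3)
        assert len(records) == 3
        exp_qaly, exp_cost = self._expected()
        assert sum(r.discounted_qaly for r in records) == \
            pytest.approx(exp_qaly, abs=1e-9)
        assert sum(r.discounted_cost for r in records) == \
            pytest.approx(exp_cost, abs=1e-9)
        assert all(r.alive for r in records)
        assert records[0].bcva == pytest.approx(0.675)
        assert records[2].vf == pytest.approx(300.4)


def test_degenerate_accumulation_is_u_times_T(base_config, zero_sd_effects,
                                              immortal_table):
    """Zero discounting + pinned utility: total QALYs = u * cycles."""
    cfg = replace(
        _zero_sd_config(base_config, zero_sd_effects),
        costs=replace(base_config.costs, discount=DiscountParams(0.0, 0.0)),
        # pinning u_min = u_max - eps makes utility essentially constant
        utility=UtilityParams(u_max=0.7000000001, u_min=0.7),
    )
    patient = Patient(0, 30.0, "female", 0.987, 427.1, 17.0, "SoC")
    records = simulate_patient(patient, cfg, np.random.default_rng(0),
                               life_table=immortal_table, max_cycles=25)
    total = sum(r.discounted_qaly for r in records)
    assert total == pytest.approx(0.7 * 25, rel=1e-8)


def test_patient_starting_at_terminal_age(base_config, immortal_table):
    """qx is 1 at the terminal age, so the trajectory is a single dead
    cycle with zero accruals."""
    patient = Patient(0, 100.0, "female", 1.0, 300.0, 17.0, "VN")
    records = simulate_patient(patient, base_config,
                               np.random.default_rng(0),
                               life_table=immortal_table)
    assert len(records) == 1
    assert not records[0].alive
    assert records[0].discounted_qaly == 0.0
    assert records[0].discounted_cost == 0.0


def test_death_is_absorbing_with_zero_accruals(base_config):
    """Trajectories end at the death cycle; the death cycle accrues nothing."""
    table = resolve_life_table(base_config)
    rng = np.random.default_rng(42)
    for i in range(30):
        patient = Patient(i, 40.0, "male", 1.0, 300.0, 17.0, "SoC")
        records = simulate_patient(patient, base_config, rng,
                                   life_table=table)
        dead = [r for r in records if not r.alive]
        assert len(dead) <= 1
        if dead:
            assert records[-1] is dead[0]
            assert dead[0].discounted_qaly == 0.0
            assert dead[0].discounted_cost == 0.0


def test_record_path_equals_fast_path(base_config):
    """The totals-only accumulation path and the CycleRecord path are the
    same arithmetic."""
    table = resolve_life_table(base_config)
    ctx = _RunContext(base_config, table)
    for seed in range(10):
        patient = Patient(0, 12.0, "female", 1.1, 400.0, 16.0,
                          "VN" if seed % 2 else "SoC")
        totals, _ = _simulate(patient, ctx, np.random.default_rng(seed),
                              np.random.default_rng(seed + 1000))
        _, records = _simulate(patient, ctx, np.random.default_rng(seed),
                               np.random.default_rng(seed + 1000),
                               collect_records=True)
        assert sum(r.discounted_qaly for r in records) == \
            pytest.approx(totals[0], abs=1e-12)
        assert sum(r.discounted_cost for r in records) == \
            pytest.approx(totals[1], abs=1e-12)


@pytest.mark.parametrize("scenario_kind", ["lifetime", "waning"])
def test_engine_matches_straight_line_reference(base_config, scenario_kind):
    """Independent plainly-written reference reproduces per-patient totals
    to 1e-9 on 20 random patients, in both effect-duration scenarios."""
    from rpe65cea import sample_cohort

    cfg = replace(base_config,
                  scenario=replace(base_config.scenario, kind=scenario_kind))
    table = resolve_life_table(cfg)
    ctx = _RunContext(cfg, table)
    cohort = sample_cohort(CohortSpec(n_patients=20),
                           np.random.default_rng(99))
    for i, patient in enumerate(cohort):
        totals, _ = _simulate(patient, ctx, np.random.default_rng(i),
                              np.random.default_rng(i + 500))
        ref_q, ref_c = reference_patient_totals(
            patient, cfg, table, np.random.default_rng(i),
            np.random.default_rng(i + 500))
        assert totals[0] == pytest.approx(ref_q, abs=1e-9)
        assert totals[1] == pytest.approx(ref_c, abs=1e-9)


def test_same_sim_seed_is_bit_identical(small_config):
    r1 = run_simulation(small_config, 777)
    r2 = run_simulation(small_config, 777)
    assert r1 == r2


def test_icur_identity_per_replicate(small_config):
    for seed in range(5):
        r = run_simulation(small_config, seed)
        assert r.icur == r.delta_cost / r.delta_qaly


def test_null_effect_control(base_config, zero_sd_effects):
    """Identical baselines and identical (SoC) effects in both arms, with
    progression switched off so the maintained treated state and the
    untreated trajectory coincide: delta-QALY ~ 0 and delta-cost ~ the
    VN treatment bundle (year 1, undiscounted)."""
    from rpe65cea import ProgressionParams

    soc = zero_sd_effects.soc
    cfg = replace(
        base_config,
        effects=replace(zero_sd_effects, vn=soc),
        cohort=replace(base_config.cohort,
                       baseline_vn=base_config.cohort.baseline_soc),
        progression=ProgressionParams(bcva_age_coeff=0.0, vf_slope=0.0),
        costs=replace(base_config.costs, include_indirect=False),
    )
    ens = run_monte_carlo(cfg, n_sims=100, master_seed=5)
    dq = np.mean([r.delta_qaly for r in ens.results])
    dc = np.mean([r.delta_cost for r in ens.results])
    bundle = 831_660 - 220  # VN year-1 bundle minus the SoC-arm check
    assert abs(dq) < 0.3
    assert dc == pytest.approx(bundle, rel=0.02)


def test_monte_carlo_reproducible_and_sized(small_config):
    e1 = run_monte_carlo(small_config, n_sims=15, master_seed=3)
    e2 = run_monte_carlo(small_config, n_sims=15, master_seed=3)
    assert len(e1) == 15
    assert e1.results == e2.results


def test_ensemble_standard_error_scaling(base_config):
    """SE of the ensemble-mean delta-QALY shrinks ~ 1/sqrt(n_sims)."""
    cfg = replace(base_config,
                  cohort=replace(base_config.cohort, n_patients=10))
    sizes = (100, 400, 1600)
    ses = []
    for n in sizes:
        ens = run_monte_carlo(cfg, n_sims=n, master_seed=11)
        dq = np.array([r.delta_qaly for r in ens.results])
        ses.append(dq.std(ddof=1) / np.sqrt(n))
    assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.35)
    assert ses[1] / ses[2] == pytest.approx(2.0, rel=0.35)


def test_discounted_qalys_bounded_by_life_years(base_config):
    table = resolve_life_table(base_config)
    ctx = _RunContext(base_config, table)
    for seed in range(10):
        patient = Patient(0, 20.0, "female", 1.0, 300.0, 16.0, "SoC")
        totals, _ = _simulate(patient, ctx, np.random.default_rng(seed),
                              np.random.default_rng(seed * 7 + 1))
        disc_qaly, life_years = totals[0], totals[5]
        assert disc_qaly <= life_years + 1e-12
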