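"""Independent straight-line reference for the per-patient simulation.

Written directly from the documented model contracts, deliberately
plainly and without sharing code with the engine: explicit decimal-acuity
band lookups, fresh discount-factor computation per cycle, no
precomputation.  Used only to cross-check ``simulate_patient``.
"""

import math


def reference_patient_totals(patient, config, life_table, eff_rng, mort_rng,
                             max_cycles=None):
    """(discounted QALYs, discounted costs) for one patient."""
    prog = config.progression
    u = config.utility
    scen = config.scenario
    d = config.costs.discount
    sched = config.costs.direct
    tab = config.costs.indirect

    def clamp_bcva(x):
        return min(max(x, prog.bcva_floor), prog.bcva_cap)

    def clamp_vf(x):
        return max(x, prog.vf_floor)

    def util_of(bcva, vf):
        s_va = min(max((u.bcva_cap_anchor - bcva) / u.bcva_ref, 0.0), 1.0)
        s_vf = min(max(vf / u.vf_ref, 0.0), 1.0)
        return u.u_min + (u.u_max - u.u_min) * (u.w_va * s_va
                                                + (1 - u.w_va) * s_vf)

    def indirect_of(bcva):
        if not config.costs.include_indirect:
            return 0.0
        decimal = 10.0 ** (-bcva)
        if decimal < 0.02:
            b = tab.band_a
        elif decimal < 0.05:
            b = tab.band_b
        elif decimal < 0.3:
            b = tab.band_c
        else:
            return 0.0
        return 2.0 * (b.medical + b.nonmedical + b.general)

    is_vn = patient.arm == "VN"
    eff = config.effects.vn if is_vn else config.effects.soc
    d_bcva = eff_rng.normal(eff.bcva_change_mean, eff.bcva_change_sd)
    d_vf = eff_rng.normal(eff.vf_change_mean, eff.vf_change_sd)
    if is_vn:
        soc_eff = config.effects.soc
        sh_d_bcva = eff_rng.normal(soc_eff.bcva_change_mean,
                                   soc_eff.bcva_change_sd)
        sh_d_vf = eff_rng.normal(soc_eff.vf_change_mean, soc_eff.vf_change_sd)

    qx = (life_table.qx_female if patient.sex == "female"
          else life_table.qx_male)
    bcva, vf = patient.bcva, patient.vf
    age = patient.age
    total_qaly = 0.0
    total_cost = 0.0
    frozen = shadow = None
    t = 0
    while True:
        t += 1
        if max_cycles is not None and t > max_cycles:
            break
        if int(age) > life_table.max_age:
            break
        if mort_rng.random() < qx[int(age)]:
            break
        if t == 1:
            bcva = clamp_bcva(bcva + d_bcva)
            vf = clamp_vf(vf + d_vf)
            if is_vn:
                frozen = (bcva, vf)
                shadow = (clamp_bcva(patient.bcva + sh_d_bcva),
                          clamp_vf(patient.vf + sh_d_vf))
        elif is_vn:
            if scen.kind == "waning":
                sb, sv = shadow
                if age >= patient.onset_age:
                    sb = clamp_bcva(sb + prog.bcva_age_coeff)
                sv = clamp_vf(sv + prog.vf_slope)
                shadow = (sb, sv)
                years = t - 1
                if years <= scen.plateau_years:
                    r = 1.0
                elif years > scen.plateau_years + scen.waning_years:
                    r = 0.0
                else:
                    k = -math.log(scen.residual_floor) / scen.waning_years
                    r = math.exp(-k * (years - scen.plateau_years))
                bcva = clamp_bcva(sb + r * (frozen[0] - sb))
                vf = clamp_vf(sv + r * (frozen[1] - sv))
        else:
            if age >= patient.onset_age:
                bcva = clamp_bcva(bcva + prog.bcva_age_coeff)
            vf = clamp_vf(vf + prog.vf_slope)
        if is_vn and t == 1:
            direct = (2 * (sched.drug_per_eye + sched.pharmacy_per_eye
                           + sched.drg_per_eye)
                      + sched.vn_year1_quarters * sched.outpatient_per_quarter)
        else:
            direct = sched.followup_visits_per_year * sched.outpatient_per_quarter
        total_qaly += util_of(bcva, vf) * (1 + d.rate_qalys) ** (-(t - 1))
        total_cost += (direct + indirect_of(bcva)) * (1 + d.rate_costs) ** (-(t - 1))
        age += 1
    return total_qaly, total_cost
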