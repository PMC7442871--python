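"""Utility-function calibration.

The published model states only that utility is a linear function of the
tracked visual endpoints; its coefficients are not available.  This
module anchors the utility parameterisation to a known base-case
incremental-QALY value: it tunes one scalar — by default the visual-field
weight w_vf, falling back to the utility spread (u_max - u_min) — by
bisection until the base-case ensemble-mean delta-QALY hits the target.

Utility parameters influence no random draw and no state transition, so
for a fixed master seed the map from utility parameters to delta-QALY is
deterministic and can be evaluated exactly from one base-case run: each
replicate's discounted QALYs decompose as

    QALY = u_min * DL + (u_max - u_min) * (w_va * SVA + w_vf * SVF)

where DL, SVA, SVF (discounted alive-time and discounted normalised
acuity/field scores) are stored on every :class:`SimResult`.  Bisection
on the cached decomposition is therefore identical to re-running the
Monte Carlo with common random numbers at every candidate — just without
the redundant trajectory recomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .config import ScenarioConfig
from .disease import UtilityParams
from .engine import Ensemble, run_monte_carlo
from .errors import CalibrationError

_BISECT_TOL = 1e-12
_MAX_ITER = 200


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of a utility calibration."""

    params: UtilityParams
    achieved_delta_qaly: float
    target_delta_qaly: float
    tuned_parameter: str
    n_iterations: int


def delta_qaly_for_utility(ensemble: Ensemble, u: UtilityParams) -> float:
    """Ensemble-mean delta-QALY under alternative utility parameters.

    Exact re-evaluation from the stored per-replicate decomposition; see
    module docstring.
    """
    spread = u.u_max - u.u_min
    total = 0.0
    for r in ensemble.results:
        q_vn = u.u_min * r.dl_vn + spread * (u.w_va * r.sva_vn
                                             + u.w_vf * r.svf_vn)
        q_soc = u.u_min * r.dl_soc + spread * (u.w_va * r.sva_soc
                                               + u.w_vf * r.svf_soc)
        total += q_vn - q_soc
    return total / len(ensemble.results)


def _bisect(f, lo: float, hi: float, target: float, rel_tol: float
            ) -> tuple[float, float, int]:
    """Bisection for f(x) = target on [lo, hi]; f need not be increasing."""
    flo, fhi = f(lo), f(hi)
    if not (min(flo, fhi) <= target <= max(flo, fhi)):
        raise CalibrationError(
            f"target {target} not bracketed: f({lo})={flo:.4f}, "
            f"f({hi})={fhi:.4f}"
        )
    increasing = fhi >= flo
    it = 0
    while it < _MAX_ITER:
        mid = 0.5 * (lo + hi)
        fmid = f(mid)
        it += 1
        if abs(fmid - target) <= rel_tol * abs(target) or hi - lo < _BISECT_TOL:
            return mid, fmid, it
        if (fmid < target) == increasing:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection did not converge")


def calibrate_utility(config: ScenarioConfig,
                      target_delta_qaly: float = 4.82,
                      seed: int | None = None,
                      rel_tol: float = 0.01,
                      n_sims: int | None = None) -> CalibrationResult:
    """Tune utility parameters so the base case yields the target delta-QALY.

    Tries the field weight ``w_vf`` on [0, 1] first; if the target is not
    bracketed there, fixes ``w_vf`` at its better endpoint and tunes the
    spread by raising ``u_max`` toward 1.  Raises
    :class:`~rpe65cea.errors.CalibrationError` with the achievable range
    when no in-bounds parameterisation reaches the target.
    """
    if target_delta_qaly <= 0:
        raise CalibrationError("target_delta_qaly must be > 0")
    master_seed = config.master_seed if seed is None else seed
    ensemble = run_monte_carlo(config, n_sims=n_sims, master_seed=master_seed)
    base_u = config.utility

    def eval_wvf(w_vf: float) -> float:
        return delta_qaly_for_utility(ensemble, replace(base_u, w_va=1.0 - w_vf))

    try:
        w_vf, achieved, it = _bisect(eval_wvf, 0.0, 1.0,
                                     target_delta_qaly, rel_tol)
        return CalibrationResult(
            params=replace(base_u, w_va=1.0 - w_vf),
            achieved_delta_qaly=achieved,
            target_delta_qaly=target_delta_qaly,
            tuned_parameter="w_vf",
            n_iterations=it,
        )
    except CalibrationError:
        pass

    # Fallback: widen the spread via u_max at the better w_vf endpoint.
    w_vf_star = 0.0 if eval_wvf(0.0) >= eval_wvf(1.0) else 1.0
    u_at = replace(base_u, w_va=1.0 - w_vf_star)

    def eval_umax(u_max: float) -> float:
        return delta_qaly_for_utility(ensemble, replace(u_at, u_max=u_max))

    lo = base_u.u_min + 1e-6
    try:
        u_max, achieved, it = _bisect(eval_umax, lo, 1.0,
                                      target_delta_qaly, rel_tol)
    except CalibrationError as exc:
        raise CalibrationError(
            f"no utility parameterisation in bounds reaches a delta-QALY of "
            f"{target_delta_qaly}: w_vf sweep gives "
            f"[{min(eval_wvf(0.0), eval_wvf(1.0)):.4f}, "
            f"{max(eval_wvf(0.0), eval_wvf(1.0)):.4f}], spread sweep at "
            f"w_vf={w_vf_star} gives [{eval_umax(lo):.4f}, "
            f"{eval_umax(1.0):.4f}]"
        ) from exc
    return CalibrationResult(
        params=replace(u_at, u_max=u_max),
        achieved_delta_qaly=achieved,
        target_delta_qaly=target_delta_qaly,
        tuned_parameter="u_max",
        n_iterations=it,
    )
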