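"""Headline economics, CE plane, CEAC, and the sensitivity suite.

The headline incremental cost-utility ratio (ICUR) is the ratio of
ensemble means (mean delta-cost over mean delta-QALY), the standard
aggregation in cost-effectiveness analysis; the mean of per-replicate
ratios is also reported for transparency, because the two differ on
skewed ensembles.

The cost-effectiveness acceptability curve (CEAC) is computed from net
monetary benefit (NMB = lambda * dQALY - dCost >= 0), which handles the
dominant/dominated quadrants correctly and is monotone in the
willingness-to-pay threshold; the literal "ICUR below threshold" rule is
available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .costing import DiscountParams
from .disease import SCENARIO_WANING
from .engine import Ensemble, run_monte_carlo
from .errors import ConfigError


@dataclass(frozen=True)
class CEACPoint:
    """One point of the acceptability curve."""

    threshold: float
    fraction_cost_effective: float


@dataclass(frozen=True)
class ScenarioResult:
    """Summary economics of one scenario ensemble."""

    name: str
    delta_qaly: float
    delta_cost: float
    icur: float
    icur_defined: bool
    icur_mean_of_ratios: float
    n_sims: int


def summarize(ensemble: Ensemble, name: str = "base") -> ScenarioResult:
    """Ensemble means and the ratio-of-means ICUR."""
    if len(ensemble) == 0:
        raise ConfigError("cannot summarize an empty ensemble")
    dq = float(np.mean([r.delta_qaly for r in ensemble.results]))
    dc = float(np.mean([r.delta_cost for r in ensemble.results]))
    defined = dq != 0.0
    icur = dc / dq if defined else math.nan
    ratios = [r.icur for r in ensemble.results if r.icur_defined]
    mean_of_ratios = float(np.mean(ratios)) if ratios else math.nan
    return ScenarioResult(name=name, delta_qaly=dq, delta_cost=dc,
                          icur=icur, icur_defined=defined,
                          icur_mean_of_ratios=mean_of_ratios,
                          n_sims=len(ensemble))


def ceac(ensemble: Ensemble, thresholds, method: str = "nmb"
         ) -> list[CEACPoint]:
    """Fraction of replicates cost-effective at each threshold.

    ``nmb``: lambda * dQALY - dCost >= 0 (default; monotone, quadrant-safe).
    ``icur``: the literal rule — per-replicate ICUR strictly below the
    threshold, with dominant replicates (dQALY > 0, dCost <= 0) always
    cost-effective.
    """
    dq = np.array([r.delta_qaly for r in ensemble.results])
    dc = np.array([r.delta_cost for r in ensemble.results])
    points = []
    for lam in thresholds:
        if lam < 0:
            raise ConfigError(f"threshold must be >= 0, got {lam}")
        if method == "nmb":
            ok = lam * dq - dc >= 0
        elif method == "icur":
            dominant = (dq > 0) & (dc <= 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dq != 0, dc / dq, np.inf)
            ok = dominant | ((dq > 0) & (ratio < lam))
        else:
            raise ConfigError(f"unknown CEAC method {method!r}")
        points.append(CEACPoint(float(lam), float(np.mean(ok))))
    return points


def ceac_to_dataframe(points: list[CEACPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {"threshold": [p.threshold for p in points],
         "fraction_cost_effective": [p.fraction_cost_effective for p in points]}
    )


def ce_plane(ensemble: Ensemble) -> pd.DataFrame:
    """(delta_qaly, delta_cost) scatter, one row per replicate."""
    if len(ensemble) == 0:
        raise ConfigError("cannot build a CE plane from an empty ensemble")
    return pd.DataFrame(
        {
            "sim_id": [r.sim_id for r in ensemble.results],
            "delta_qaly": [r.delta_qaly for r in ensemble.results],
            "delta_cost": [r.delta_cost for r in ensemble.results],
        }
    )


# --- sensitivity suite -----------------------------------------------------

SCENARIO_BASE = "base"
SCENARIO_WANING_NAME = "effect_10y_waning"
SCENARIO_DISCOUNT0 = "discount_0pct"
SCENARIO_DIRECT_UP = "direct_costs_+10pct"
SCENARIO_DIRECT_DOWN = "direct_costs_-10pct"
SCENARIO_VF_SLOPE = "vf_slope_-24.3"


def scenario_variants(base: ScenarioConfig) -> dict[str, ScenarioConfig]:
    """The published sensitivity scenarios derived from a base config."""
    return {
        SCENARIO_BASE: base,
        SCENARIO_WANING_NAME: replace(
            base, scenario=replace(base.scenario, kind=SCENARIO_WANING)),
        SCENARIO_DISCOUNT0: replace(
            base, costs=replace(base.costs,
                                discount=DiscountParams(0.0, 0.0))),
        SCENARIO_DIRECT_UP: replace(
            base, costs=replace(base.costs, direct=base.costs.direct.scaled(1.1))),
        SCENARIO_DIRECT_DOWN: replace(
            base, costs=replace(base.costs, direct=base.costs.direct.scaled(0.9))),
        SCENARIO_VF_SLOPE: replace(
            base, progression=replace(base.progression, vf_slope=-24.3)),
    }


def run_sensitivity_suite(base_config: ScenarioConfig,
                          master_seed: int | None = None,
                          n_sims: int | None = None,
                          progress: bool = False
                          ) -> tuple[list[ScenarioResult], dict[str, Ensemble]]:
    """Run base case plus the five published sensitivity scenarios.

    All scenarios reuse the base run's master seed (common random
    numbers), so differences between scenario results isolate the
    parameter changes.  Returns the labelled summaries and the underlying
    ensembles keyed by scenario name.
    """
    if master_seed is None:
        master_seed = base_config.master_seed
    ensembles: dict[str, Ensemble] = {}
    results: list[ScenarioResult] = []
    for name, cfg in scenario_variants(base_config).items():
        ens = run_monte_carlo(cfg, n_sims=n_sims, master_seed=master_seed,
                              progress=progress)
        ensembles[name] = ens
        results.append(summarize(ens, name=name))
    return results, ensembles


def sensitivity_to_dataframe(results: list[ScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scenario": [r.name for r in results],
            "delta_qaly": [r.delta_qaly for r in results],
            "delta_cost": [r.delta_cost for r in results],
            "icur": [r.icur for r in results],
        }
    )


# --- plotting helpers ------------------------------------------------------

def plot_ce_plane(ensemble: Ensemble, path) -> None:
    """Scatter of incremental costs vs incremental QALYs per replicate."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = ce_plane(ensemble)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(df["delta_qaly"], df["delta_cost"], s=6, alpha=0.5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs (VN - SoC)")
    ax.set_ylabel("Incremental cost, EUR (VN - SoC)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(points: list[CEACPoint], path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = ceac_to_dataframe(points)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["threshold"], df["fraction_cost_effective"])
    ax.set_xlabel("Willingness-to-pay threshold, EUR/QALY")
    ax.set_ylabel("Fraction cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_sensitivity(results: list[ScenarioResult], path) -> None:
    """Horizontal bars of scenario ICURs centred on the base-case ICUR."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = next((r for r in results if r.name == SCENARIO_BASE), results[0])
    others = [r for r in results if r.name != base.name]
    fig, ax = plt.subplots(figsize=(7, 0.6 * max(len(others), 2) + 1.5))
    names = [r.name for r in others]
    vals = [r.icur - base.icur for r in others]
    ax.barh(names, vals, left=base.icur, color="steelblue")
    ax.axvline(base.icur, color="black", lw=1)
    ax.set_xlabel("ICUR, EUR/QALY")
    ax.set_title(f"Sensitivity analysis (base ICUR = {base.icur:,.0f})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
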