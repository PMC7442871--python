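"""Shared fixtures: small configs, degenerate tables, deterministic RNGs."""

from dataclasses import replace

import numpy as np
import pytest

from rpe65cea import (ArmBaseline, CohortSpec, LifeTable, ScenarioConfig,
                      TrialEffect, TrialEffects, default_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def base_config() -> ScenarioConfig:
    return default_config()


@pytest.fixture
def small_config(base_config) -> ScenarioConfig:
    """Default science, small Monte Carlo (fast unit-level runs)."""
    return replace(base_config, n_sims=20)


@pytest.fixture
def zero_sd_effects() -> TrialEffects:
    """Deterministic first-cycle effects (trial means, SDs zero)."""
    return TrialEffects(
        vn=TrialEffect(-0.163, 0.0, 302.1, 0.0),
        soc=TrialEffect(-0.312, 0.0, -76.7, 0.0),
    )


@pytest.fixture
def deterministic_cohort_spec() -> CohortSpec:
    """A cohort with no sampling spread (all SDs zero)."""
    return CohortSpec(
        n_patients=2,
        age_mean=30.0, age_sd=0.0, age_range=(4.0, 44.0),
        onset_window=(17.0, 17.0),
        baseline_vn=ArmBaseline(1.137, 0.0, 332.9, 0.0),
        baseline_soc=ArmBaseline(0.987, 0.0, 427.1, 0.0),
    )


@pytest.fixture
def immortal_table() -> LifeTable:
    """No mortality below the (absorbing) terminal age 100."""
    q = np.zeros(101)
    return LifeTable(q, q.copy())
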