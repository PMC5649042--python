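"""Shared fixtures: small synthetic cohorts generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from actiwell import (
    CohortConfig,
    GenerativeCoefficients,
    build_analysis_table,
    generate_profiles,
    generate_timelines,
    generate_wellbeing,
    perfect_state_calls,
)

warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_participants=6, n_days=28, seed=42, missingness_prob=0.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Cohort with default coefficients, perfect state flags, no dropout."""
    cfg = small_config
    coeffs = (GenerativeCoefficients.mood_defaults(), GenerativeCoefficients.energy_defaults())
    profiles = generate_profiles(cfg, coeffs)
    timelines = generate_timelines(cfg, profiles)
    ema, latent = generate_wellbeing(timelines, profiles, coeffs, cfg)
    states = pd.concat([perfect_state_calls(t, cfg) for t in timelines], ignore_index=True)
    return dict(
        config=cfg,
        coeffs=coeffs,
        profiles=profiles,
        timelines=timelines,
        ema=ema,
        latent=latent,
        states=states,
    )


@pytest.fixture(scope="session")
def analysis_table(small_cohort):
    cfg = small_cohort["config"]
    table, report = build_analysis_table(
        small_cohort["states"],
        small_cohort["ema"],
        start_date=cfg.start_date,
        n_days=cfg.n_days,
    )
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
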