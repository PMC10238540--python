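"""Shared fixtures: synthetic sessions and their leave-one-out results.

The heavy sessions are generated once per test run (session scope) into a
temporary directory; every module reuses them instead of regenerating.
"""

import warnings

import numpy as np
import pytest

from exodecode import (
    PipelineConfig,
    SyntheticConfig,
    generate_session,
    generate_trial,
    loo_experience,
    null_config,
)
from exodecode.errors import ExodecodeWarning
from exodecode.synthetic import EXPERIENCE_TRIAL_PLAN


@pytest.fixture(scope="session")
def default_experience_session(tmp_path_factory):
    """Full 16-trial flat-ground session with the default effect sizes."""
    out = tmp_path_factory.mktemp("exp_default")
    return generate_session(SyntheticConfig(seed=42), out)


@pytest.fixture(scope="session")
def null_experience_session(tmp_path_factory):
    """Full 16-trial session with both effect factors at 1 (no contrast)."""
    out = tmp_path_factory.mktemp("exp_null")
    return generate_session(null_config(SyntheticConfig(seed=42)), out)


@pytest.fixture(scope="session")
def slopes_session(tmp_path_factory):
    """Full 16-trial ramp session with the default effect sizes."""
    out = tmp_path_factory.mktemp("slopes_default")
    return generate_session(SyntheticConfig(seed=42, scenario="slopes"), out)


@pytest.fixture(scope="session")
def small_experience_session(tmp_path_factory):
    """4-trial session with short baselines, for cheap structural tests."""
    out = tmp_path_factory.mktemp("exp_small")
    cfg = SyntheticConfig(seed=5, n_trials=4, baseline_duration=30.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExodecodeWarning)
        return generate_session(cfg, out)


@pytest.fixture(scope="session")
def default_mi_result(default_experience_session):
    return loo_experience(default_experience_session, "mi", PipelineConfig())


@pytest.fixture(scope="session")
def default_att_result(default_experience_session):
    return loo_experience(default_experience_session, "att", PipelineConfig())


@pytest.fixture()
def experience_trial():
    """One in-memory flat-ground trial (recording + sidecar metadata)."""
    cfg = SyntheticConfig(seed=3)
    rng = np.random.default_rng(3)
    return generate_trial(cfg, EXPERIENCE_TRIAL_PLAN, rng)
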