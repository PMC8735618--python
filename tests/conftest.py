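import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from seropls import SimulationConfig, simulate_cohort
from seropls.synthetic import GROUPS, GroupCovariates

#: identical age/sex structure in every group — used wherever a test needs a
#: cohort with no class signal beyond the injected effects
NULL_COVARIATES = {g: GroupCovariates(60.0, 11.0, 0.45) for g in GROUPS}


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A cohort config with no group differences at all."""
    base = SimulationConfig(seed=seed, effect_map={}, covariate_model=NULL_COVARIATES)
    return replace(base, **overrides)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Down-scaled cohort (coarser axis, fewer subjects) for fast tests."""
    base = SimulationConfig(
        n_recent=30, n_lifetime=10, n_none=30, ppm_step=0.002, seed=seed
    )
    return replace(base, **overrides)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
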