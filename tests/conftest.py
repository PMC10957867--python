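import dataclasses

import numpy as np
import pytest

from ivsem import (ModelSpec, SimulationConfig, build_analysis_frame,
                   gibbs_fit, simulate_survey)

#: Planted structural truths used throughout: the maternal-grandmother
#: point estimates (investment, adversity, interaction effects in SDQ units).
TRUTH = {"sdq_total~gi_c": 2.476,
         "sdq_total~aele_c": 3.196,
         "sdq_total~gi_x_aele": -0.839}


def make_frame(n=1000, seed=0, **overrides):
    """Complete-data analysis frame from the default confounded generator."""
    cfg = SimulationConfig(n_children=n, seed=seed, missing_rate=0.0,
                           **overrides)
    return build_analysis_frame(simulate_survey(cfg))


@pytest.fixture(scope="session")
def fast_spec():
    """Reduced sampler settings for replicate studies: 2 chains x 800
    iterations, 300 burn-in (1000 retained draws)."""
    return ModelSpec(iterations=800, burn_in=300, seed=0)


@pytest.fixture(scope="session")
def frame_2000():
    return make_frame(n=2000, seed=42)


@pytest.fixture(scope="session")
def gibbs_2000(frame_2000):
    """One moderately long covariance-mode fit shared across tests."""
    return gibbs_fit(frame_2000, ModelSpec(iterations=3000, burn_in=1000,
                                           seed=7))


@pytest.fixture(scope="session")
def direct_fit_small(fast_spec):
    frame = make_frame(n=800, seed=11)
    return gibbs_fit(frame, dataclasses.replace(fast_spec, mode="direct",
                                                seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
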