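import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from thermoresp import GeneratorConfig, ScholanderTruth, generate_steady_state

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def truth() -> ScholanderTruth:
    return ScholanderTruth()


@pytest.fixture(scope="session")
def steady_default(truth) -> pd.DataFrame:
    """Default synthetic steady-state dataset: 36 birds, seed 42."""
    return generate_steady_state(truth, GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def steady_noiseless(truth) -> pd.DataFrame:
    cfg = GeneratorConfig(
        seed=0,
        noise_sd_mr=0.0,
        noise_sd_tb=0.0,
        noise_sd_ehl=0.0,
        among_sd_mr=0.0,
        among_sd_tb=0.0,
        among_sd_ehl=0.0,
        scheme="full_grid",
    )
    return generate_steady_state(truth, cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
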