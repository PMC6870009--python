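import numpy as np
import pytest

from gatenet.pipeline import run_pipeline
from gatenet.synthgen import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """Small but structurally complete cohort (80 regions, light subjects)."""
    cfg = SynthConfig(
        n_per_group={"FESZ": 4, "UHR": 4, "HC": 4},
        n_trials=16,
        n_sensors=24,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default-condition cohort (25/23/19 subjects, 80 trials)."""
    return generate_cohort(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_cohort):
    """Pipeline products for the default cohort (shared across tests)."""
    return run_pipeline(default_cohort)


@pytest.fixture(scope="session")
def conn_only_cohort():
    """Cohort whose only group differences are the planted couplings."""
    from gatenet.synthgen import connectivity_only_config, generate_cohort

    return generate_cohort(connectivity_only_config(seed=2))


@pytest.fixture(scope="session")
def conn_only_result(conn_only_cohort):
    return run_pipeline(conn_only_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
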