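import dataclasses

import pytest

from emdsim.config import ExperimentConfig, NumericsConfig, baseline_config


@pytest.fixture(scope="session")
def baseline() -> ExperimentConfig:
    return baseline_config()


@pytest.fixture(scope="session")
def coarse_config() -> ExperimentConfig:
    """Baseline experiment on a deliberately coarse grid for behavior tests."""
    base = baseline_config()
    return dataclasses.replace(
        base,
        numerics=NumericsConfig(dx=0.02, dt_ep=0.02, dt_mech=0.2, t_end=80.0,
                                n_elements=8),
        label="coarse",
    )


@pytest.fixture(scope="session")
def study_results():
    """The complete characterization study (shared by the acceptance tests)."""
    from emdsim.study import run_study

    return run_study(seed=1)
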