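import numpy as np
import pytest

from pssubgroup import Scenario, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def sc1() -> Scenario:
    return Scenario.sc1()


@pytest.fixture(scope="session")
def small_cohort(sc1):
    """One n=3000 cohort under Scenario 1, reused across read-only tests."""
    return generate_cohort(SimulationConfig(n=3000), sc1, rng_state=2023)


@pytest.fixture(scope="session")
def null_effect_config() -> SimulationConfig:
    """DGM with no covariate effects anywhere and equal subset intercepts:
    treatment is a fair coin and the hazard is flat at lambda0."""
    zero_t = {(f"X{j}", s): 0.0 for j in range(1, 11) for s in (1, 2)}
    zero_o = {f"X{j}": 0.0 for j in range(1, 11)}
    return SimulationConfig(beta0_s1=0.0, beta0_s2=0.0, beta_treat=zero_t,
                            alpha_out=zero_o, alpha_s=0.0)
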