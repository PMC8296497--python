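import numpy as np
import pytest

from mesoproject.synthetic import (APCScenario, ExposureScenario,
                                   per_capita_series, simulate_apc_counts,
                                   simulate_exposure_counts)


@pytest.fixture(scope="session")
def apc_world():
    """One seeded registry world drawn from the default APC scenario."""
    scenario = APCScenario(seed=11)
    incidence, population, truth = simulate_apc_counts(scenario)
    return scenario, incidence, population, truth


@pytest.fixture(scope="session")
def exposure_world():
    """One seeded world drawn from the default exposure-Poisson scenario."""
    scenario = ExposureScenario(seed=13)
    incidence, truth = simulate_exposure_counts(scenario)
    return scenario, incidence, truth


@pytest.fixture(scope="session")
def consumption_series():
    """Deterministic per-capita consumption series (rise-peak-ban world)."""
    return per_capita_series(ExposureScenario(seed=0))
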