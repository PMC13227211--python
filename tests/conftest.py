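import numpy as np
import pandas as pd
import pytest

from locusprox import (
    AbundanceMatrix,
    RunConfig,
    SimScenario,
    default_design,
    simulate_abundance,
)


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture()
def config():
    return RunConfig(seed=1)


def noise_free_scenario(**overrides) -> SimScenario:
    """All noise off, missingness off; effects default to 1."""
    params = dict(
        n_proteins=50,
        effect_on_target=1.0,
        effect_background=1.0,
        effect_contaminant=1.0,
        channel_bias_sd=0.0,
        replicate_noise_sd=0.0,
        missing_midpoint=0.0,
        seed=11,
    )
    params.update(overrides)
    return SimScenario(**params)


@pytest.fixture()
def small_matrix(design):
    """A modest noisy simulated matrix shared by filter/summary tests."""
    scenario = SimScenario(n_proteins=300, seed=5)
    matrix, truth = simulate_abundance(scenario, design)
    return matrix, truth


def as_matrix(frame: pd.DataFrame) -> AbundanceMatrix:
    """Wrap a plain DataFrame (proteins x channels) for quant functions."""
    frame = frame.copy()
    frame.index.name = "protein"
    return AbundanceMatrix(frame, pd.Series(True, index=frame.index))
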