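import numpy as np
import pandas as pd
import pytest

from riskscreen.model import MultiStateModel


@pytest.fixture
def single_edge_model():
    """One transition R1R1 -> SP at 0.01/month."""
    return MultiStateModel(
        transitions=(("R1R1", "SP"),), log_baseline=[np.log(0.01)]
    )


@pytest.fixture
def small_model():
    """Three-transition model with regression and absorption."""
    return MultiStateModel(
        transitions=(("R0R0", "R1R0"), ("R1R0", "R0R0"), ("R1R0", "SP")),
        log_baseline=np.log([0.05, 0.03, 0.02]),
    )


@pytest.fixture
def covariate_model():
    """Two-transition model with a single covariate effect."""
    return MultiStateModel(
        transitions=(("R1R0", "R1R1"), ("R1R1", "SP")),
        log_baseline=np.log([0.02, 0.03]),
        covariates=("hba1c",),
        betas=np.array([[0.02], [0.01]]),
        centering=np.array([51.0]),
    )


@pytest.fixture
def tiny_cohort():
    rng = np.random.default_rng(11)
    n = 40
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "state0": rng.choice(["R0R0", "R1R0", "R1R1"], n, p=[0.6, 0.25, 0.15]),
        }
    )
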