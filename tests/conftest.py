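import numpy as np
import pytest

import psmcea as P


@pytest.fixture(scope="session")
def cfg():
    return P.default_config()


@pytest.fixture(scope="session")
def base_results(cfg):
    """Base-case run of both arms (CPS>=5, Table-1 inputs)."""
    arm_i, arm_c, settings = P.build_arms(cfg)
    _, res_i = P.run_model(arm_i, settings)
    _, res_c = P.run_model(arm_c, settings)
    return res_i, res_c, settings


@pytest.fixture(scope="session")
def loglogistic_sample():
    """Right-censored draws from a known log-logistic PFS model."""
    model = P.ParametricSurvival("loglogistic", (2.212, 9.015))
    recipe = P.SimulationRecipe(
        model=model, n=2000, cutoff_months=30.0, dropout_fraction=0.2,
        arm="sim", seed=20240915,
    )
    return model, P.simulate_ipd(recipe)


def km_value(km: np.ndarray, t: float) -> float:
    """Step-function lookup in an ordered (time, survival) array."""
    idx = np.searchsorted(km[:, 0], t, side="right") - 1
    return float(km[max(idx, 0), 1])
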