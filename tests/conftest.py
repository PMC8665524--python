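import numpy as np
import pandas as pd
import pytest

from phenotrack.movement_hmm import HmmParams


@pytest.fixture
def two_state_params():
    """Small hand-set 2-state model used by brute-force oracle tests."""
    beta = np.zeros((2, 2, 3))
    beta[0, 1, 0] = -1.0
    beta[1, 0, 0] = -0.5
    beta[0, 1, 1] = 0.3  # cosinor terms exercise the time dependence
    beta[1, 0, 2] = -0.2
    return HmmParams(
        step_mean=np.array([0.5, 3.0]),
        step_sd=np.array([0.3, 1.0]),
        step_zero_mass=np.array([0.2, 0.0]),
        angle_shape=np.array([1.2, 0.7]),
        angle_scale=np.array([1.5, 0.4]),
        beta=beta,
        delta=np.array([0.6, 0.4]),
    )


@pytest.fixture
def four_state_params():
    from phenotrack.synthetic_data import _default_hmm_params

    return _default_hmm_params()


def make_obs(sqrt_step, turn_angle=None, solar_hour=None):
    n = len(sqrt_step)
    return pd.DataFrame(
        {
            "sqrt_step": np.asarray(sqrt_step, dtype=float),
            "turn_angle": np.full(n, np.nan)
            if turn_angle is None
            else np.asarray(turn_angle, dtype=float),
            "solar_hour": np.zeros(n)
            if solar_hour is None
            else np.asarray(solar_hour, dtype=float),
        }
    )


@pytest.fixture
def obs_factory():
    return make_obs
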