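import warnings

import numpy as np
import pytest

import speechpop as sp


@pytest.fixture(scope="session")
def two_condition_sim():
    """One spoken + silent condition, many trials, rotation at 3 Hz.

    Shared by the frequency-recovery and rate-convergence tests.
    """
    cfg = sp.SimConfig(
        n_electrodes=24, conditions=("ga", "silent"),
        trials_per_condition=200, rot_freq=3.0, trial_length=5.5,
        cis_gain=20.0, rot_gain=25.0, tuning_gain=10.0, prompt_gain=5.0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dataset, truth = sp.simulate_speech_task(cfg, seed=7)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def small_sim():
    """Small but complete 4-spoken + silent session with all latents on."""
    cfg = sp.SimConfig(
        n_electrodes=20, conditions=("a", "b", "c", "d", "silent"),
        trials_per_condition=8,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dataset, truth = sp.simulate_speech_task(cfg, seed=11)
    return cfg, dataset, truth


def make_rate_tensor(rates, dt=0.01, normalized=True, centered=False):
    """Wrap a raw (units, conditions, time) array as a RateTensor."""
    n_u, n_c, n_t = rates.shape
    return sp.RateTensor(
        rates=np.asarray(rates, dtype=float),
        time=np.arange(n_t) * dt,
        conditions=tuple(f"c{i}" for i in range(n_c)),
        alignment="AO", bin=dt, kernel_sd=0.03,
        normalization={"offset": 10.0, "ranges": np.ones(n_u)}
        if normalized else None,
        centered=centered,
    )
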