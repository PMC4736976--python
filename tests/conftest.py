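import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from p300shape import (
    CalibrationParams,
    Curve,
    EpochSet,
    NONP300,
    P300,
    SimulationConfig,
    calibrate,
    make_fixture_chains,
    simulate_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_chains():
    """The four published 16-symbol example chains."""
    return make_fixture_chains()


#: Electrodes carrying the full-amplitude P300 in the recovery subject.
INJECTED_ELECTRODES = ("Fz", "C4", "Cz")


@pytest.fixture(scope="session")
def full_scale_recovery():
    """Reference-regime recovery subject: 3 signal electrodes, 7 silent.

    Simulates the full acquisition regime (480/2,400 training and 150/750
    validation trials, 10 electrodes, 256 Hz, 800 ms) and runs the complete
    calibration wrapper (A=180, K=15, O=10). Session-scoped: the wrapper
    run is the costliest computation in the suite.
    """
    cfg = SimulationConfig(seed=0, amplitude_profile=(1, 1, 1, 0, 0, 0, 0, 0, 0, 0))
    train, valid, _ = simulate_dataset(cfg)
    profile = calibrate(train, CalibrationParams(master_seed=0))
    return train, valid, profile


def build_epochs(
    n_p300=4,
    n_nonp300=4,
    n_electrodes=2,
    n_samples=8,
    seed=0,
    sampling_rate_hz=256.0,
    epoch_duration_ms=800.0,
    electrode_names=None,
):
    """Small random EpochSet for structural tests."""
    rng = np.random.default_rng(seed)
    n = n_p300 + n_nonp300
    names = electrode_names or tuple(f"E{i + 1}" for i in range(n_electrodes))
    return EpochSet(
        rng.normal(size=(n, n_electrodes, n_samples)),
        np.array([P300] * n_p300 + [NONP300] * n_nonp300, dtype=object),
        names,
        sampling_rate_hz,
        epoch_duration_ms,
    )


@pytest.fixture
def small_epochs():
    return build_epochs()


def random_curve(n_samples=204, seed=0):
    rng = np.random.default_rng(seed)
    return Curve(np.arange(1, n_samples + 1), rng.normal(size=n_samples))
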