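import numpy as np
import pytest

from cardioresp.synthetic import SignalScenario, generate_signals


@pytest.fixture(scope="session")
def degenerate_recording():
    """No variability at all: 60 bpm, 15 breaths/min, clean channels."""
    scenario = SignalScenario(
        duration_s=60.0, mean_hr=60.0, resp_rate=15.0, rmssd_target=0.0,
        rsa_gain=0.0, cv_breath_duration=0.0, cv_breath_amplitude=0.0,
        cardiac_artifact_gain=0.0, noise_sd=0.0, seed=0,
    )
    return generate_signals(scenario)


@pytest.fixture(scope="session")
def typical_recording():
    """A realistic resting recording with all couplings active."""
    scenario = SignalScenario(
        duration_s=180.0, mean_hr=65.0, rmssd_target=45.0, resp_rate=14.0,
        seed=3,
    )
    return generate_signals(scenario)


@pytest.fixture(scope="session")
def sine_ip_record():
    """Pure 0.25 Hz sinusoidal IP channel, 60 s at 250 Hz."""
    from cardioresp.types import SignalRecord

    t = np.arange(60 * 250) / 250.0
    return SignalRecord(ecg=np.zeros_like(t), ip=np.sin(2 * np.pi * 0.25 * t), fs=250.0)
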