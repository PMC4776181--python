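import numpy as np
import pytest

from dopaphys import (
    CurrentTrace,
    DetectionConfig,
    SpikeTrain,
    TraceSimConfig,
    simulate_mipsc_trace,
)


@pytest.fixture(scope="session")
def mipsc_trace_and_truth():
    """One standard 120-s synthetic mIPSC trace (2 Hz, 30 +/- 5 pA,
    tau_rise 1.5 ms / tau_decay 7 ms, noise 2 pA), shared across tests."""
    return simulate_mipsc_trace(TraceSimConfig(seed=42))


@pytest.fixture(scope="session")
def detection_config():
    return DetectionConfig()


@pytest.fixture()
def six_spike_train():
    """ISIs 50, 50, 200, 200, 50 ms: two bursts ({0,1,2} and {4,5})."""
    return SpikeTrain("hand", [0.0, 0.05, 0.10, 0.30, 0.50, 0.55], 2.0)


def make_train(isis_ms, unit_id="u", epoch=None, **kw):
    """Spike train from a list of ISIs in ms (first spike at t=0.1 s)."""
    times = 0.1 + np.concatenate([[0.0], np.cumsum(np.asarray(isis_ms) / 1e3)])
    epoch = epoch or times[-1] + 1.0
    return SpikeTrain(unit_id, times, epoch, **kw)


def make_noise_trace(seed=0, duration=120.0, noise_sd=2.0, fs=5000.0):
    rng = np.random.default_rng(seed)
    return CurrentTrace(
        "noise", fs, rng.normal(0.0, noise_sd, int(duration * fs)), -60.0,
        protocol="mipsc",
    )
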