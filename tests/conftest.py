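import numpy as np
import pytest

from crossfreq import SimulationSpec, TrialSeries, simulate_pac_trials

FS = 1000.0


@pytest.fixture(scope="session")
def coupled_trials():
    """Default coupled simulation (64 trials x 1.2 s, fp=10, 50-70 Hz)."""
    return simulate_pac_trials(SimulationSpec(seed=42))


@pytest.fixture(scope="session")
def uncoupled_trials():
    """Same generator with coupling switched off."""
    return simulate_pac_trials(SimulationSpec(seed=42, coupling=0.0))


@pytest.fixture()
def sinusoid_trials():
    """Eight clean 10 Hz sinusoid trials of 2 s with independent phases."""
    rng = np.random.default_rng(0)
    t = np.arange(int(2.0 * FS)) / FS
    data = np.cos(2 * np.pi * 10.0 * t[None, :] + rng.uniform(0, 2 * np.pi, (8, 1)))
    return TrialSeries(data=data, fs=FS)


def dense_phase_amp(n=20000):
    """Dense uniform phases with a cosine-modulated amplitude; the standard
    smooth coupled toy input for histogram/KL oracles."""
    phase = np.linspace(-np.pi, np.pi, n, endpoint=False)
    amp = 1.0 + np.cos(phase)
    return phase, amp
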