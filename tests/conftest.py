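"""Shared fixtures: small, fast simulation configurations.

All simulated fixtures run at reduced size (8-16 channels, 128 Hz, short
trials) so the full suite stays quick; the structure (3 x 2 within-subject
design, planted band-limited phase coupling, pink background) is identical
to the full-scale generator defaults.
"""

import numpy as np
import pytest

from wplinet import EpochSet, SimulationConfig, epoch_and_baseline
from wplinet.simulate import make_subject_recording

NULL_COUPLING = {b: {"nostalgic": 0.0, "non-nostalgic": 0.0}
                 for b in ("delta", "theta", "alpha", "beta", "gamma")}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """8 channels, one trial per cell, noise only unless coupling is set."""
    return SimulationConfig(
        n_subjects=4, n_channels=8, fs=128.0, trial_sec=6.0,
        n_trials_per_cell=1, n_coupled=4, gap_sec=3.0,
        band_coupling={k: dict(v) for k, v in NULL_COUPLING.items()}, seed=7)


@pytest.fixture
def coupled_config():
    """16 channels with the default condition-dependent alpha/gamma coupling."""
    return SimulationConfig(
        n_subjects=4, n_channels=16, fs=128.0, trial_sec=8.0,
        n_trials_per_cell=2, n_coupled=8, gap_sec=3.0, seed=11)


def epochs_of(config: SimulationConfig, subject: int = 0,
              baseline=(-2.0, 0.0)) -> EpochSet:
    rec, events = make_subject_recording(config, subject)
    return epoch_and_baseline(rec, events, 0.0, config.trial_sec, baseline)


def tone_epochs(fs: float = 256.0, dur: float = 30.0, freqs=(10.0,),
                amps=(1.0,), n_channels: int = 1, n_trials: int = 1,
                labels=None) -> EpochSet:
    """Epochs holding a deterministic sum of sinusoids on every channel."""
    t = np.arange(int(dur * fs)) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    data = np.tile(x, (n_trials, n_channels, 1))
    cond = [("visual", "nostalgic")] * n_trials
    chs = labels or [f"ch{i}" for i in range(n_channels)]
    return EpochSet(data, fs, cond, chs)
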