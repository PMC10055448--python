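"""Shared fixtures: small synthetic recordings and sessions."""

import logging

import numpy as np
import pandas as pd
import pytest

from flickerlfp import synth
from flickerlfp.io import Recording

logging.getLogger("flickerlfp").setLevel(logging.ERROR)

FS = 500.0


def make_probe_recording(samples: np.ndarray, fs: float = FS, excluded=None) -> Recording:
    """Single-probe recording from a (channels, time) array."""
    n = samples.shape[0]
    return Recording(
        samples=samples,
        fs=fs,
        channels=pd.DataFrame(dict(
            contact_id=[f"c{i}" for i in range(n)],
            probe_id=["p0"] * n,
            probe_index=list(range(n)),
            excluded=excluded if excluded is not None else [False] * n,
        )),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def driven_session():
    """One strongly driven + one null contact, 40 Hz flicker, 15 trials."""
    gt = synth.GroundTruth(channels=[
        synth.ChannelGroundTruth(steady_fold=2.0, jitter_sd=0.2, peaks=((10.0, 0.9, 4.0),)),
        synth.ChannelGroundTruth(),
    ])
    trials = synth.make_trial_table([("visual", 40.0)], n_trials_per_condition=15, seed=21)
    rec, truth = synth.make_lfp_session(gt, trials, fs=FS, seed=21)
    return rec, trials, truth


@pytest.fixture(scope="session")
def pulse_pair():
    """Stimulated and occluded pulse recordings sharing one ground truth."""
    gt = synth.GroundTruth(channels=[
        synth.ChannelGroundTruth(response_mode="linear_superposition", kernel_amp=30.0,
                                 kernel_freq=8.0, kernel_tau=0.05),
        synth.ChannelGroundTruth(),
    ])
    rec, onsets = synth.make_pulse_recording(gt, n_pulses=120, fs=FS, seed=31)
    occ, occ_onsets = synth.make_pulse_recording(gt, n_pulses=120, fs=FS, seed=32, occluded=True)
    return gt, rec, onsets, occ, occ_onsets
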