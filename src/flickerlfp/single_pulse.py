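"""Single-pulse evoked potentials and the linear-superposition simulation.

A single-pulse EP is the time-locked average response to isolated 12.5 ms
sensory pulses.  Significance is assessed against a relative occluded
control (stimulus delivered but blocked from the senses) by permuting trial
labels of the RMS-of-mean statistic.  The linear-superposition counterfactual
builds simulated 40 Hz flicker trials by summing randomly drawn single-pulse
EPs every stimulus period; comparing its steady-state amplitude with the
measured one tests whether flicker responses are mere sums of pulse EPs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import signal

from .io import Recording
from .stats import permutation_diff_of_means

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PulseEPResult:
    """Per-contact single-pulse evoked response.

    times run from -0.25 s to +1.25 s around pulse onset; trials is the
    (n_trials, n_channels, n_times) stack of baseline-corrected segments.
    """

    times: np.ndarray
    trials: np.ndarray
    mean: np.ndarray     # (n_channels, n_times)
    sem: np.ndarray
    fs: float

    def post_onset(self, t_stop: float = 1.0) -> np.ndarray:
        """Trial stack restricted to [0, t_stop) after pulse onset."""
        i0 = int(np.searchsorted(self.times, -1e-9))
        i1 = i0 + int(round(t_stop * self.fs))
        return self.trials[:, :, i0:i1]


def pulse_ep(
    rec: Recording,
    pulse_onsets: np.ndarray,
    pre: float = 0.25,
    post: float = 1.25,
    min_ipi: float = 0.9,
    channel_rows: np.ndarray | None = None,
) -> PulseEPResult:
    """Trial-averaged single-pulse evoked potential.

    The recording is zero-phase high-pass filtered at 0.1 Hz (Butterworth,
    order 4), segmented into [-0.25, +1.25) s around each pulse, and each
    segment baseline-corrected by the mean of its 0.25 s pre-onset window.
    Pulses whose response windows overlap (interval < ``min_ipi``) raise.
    """
    pulse_onsets = np.sort(np.asarray(pulse_onsets, float))
    if len(pulse_onsets) < 2:
        raise ValueError("need at least 2 pulse trials")
    if np.any(np.diff(pulse_onsets) < min_ipi):
        raise ValueError("pulse segments overlap: inter-pulse interval below minimum")
    if channel_rows is None:
        channel_rows = rec.good_channel_indices()
    channel_rows = np.asarray(channel_rows)

    sos = signal.butter(4, 0.1, btype="highpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples[channel_rows], axis=1)

    n_pre = int(round(pre * rec.fs))
    n_len = int(round((pre + post) * rec.fs))
    segs = []
    for o in pulse_onsets:
        start = int(round(o * rec.fs)) - n_pre
        if start < 0 or start + n_len > filtered.shape[1]:
            raise ValueError(f"pulse at {o:.3f}s exceeds recording bounds")
        segs.append(filtered[:, start:start + n_len])
    trials = np.stack(segs)  # (n_trials, n_ch, n_len)
    trials = trials - trials[:, :, :n_pre].mean(axis=2, keepdims=True)
    mean = trials.mean(axis=0)
    sem = trials.std(axis=0, ddof=1) / np.sqrt(trials.shape[0])
    times = (np.arange(n_len) - n_pre) / rec.fs
    return PulseEPResult(times=times, trials=trials, mean=mean, sem=sem, fs=rec.fs)


def _rms_of_mean(mean_trace: np.ndarray) -> np.ndarray:
    """RMS over time of a trial-averaged trace (vectorized over permutations)."""
    return np.sqrt((mean_trace ** 2).mean(axis=-1))


def pulse_significance(
    stim_trials: np.ndarray,
    occluded_trials: np.ndarray,
    n_perm: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation test of the single-pulse EP against the occluded control.

    Both inputs are (n_trials, n_times) stacks of one contact's 0-1 s
    post-onset traces.  The statistic is RMS(mean stim trace) -
    RMS(mean occluded trace); labels are permuted over trials (one-sided,
    add-one smoothed p).
    """
    return permutation_diff_of_means(
        np.asarray(stim_trials, float), np.asarray(occluded_trials, float),
        n_perm=n_perm, seed=seed, statistic=_rms_of_mean,
    )


def peak_amplitude(ep_mean: np.ndarray, times: np.ndarray, window: tuple[float, float] = (0.0, 1.0)) -> float:
    """Absolute maximum of the mean trace from stimulus onset to +1 s."""
    sel = (times >= window[0]) & (times < window[1])
    return float(np.max(np.abs(np.asarray(ep_mean)[..., sel])))


def normalize_amplitudes(
    values: np.ndarray, groups: np.ndarray | None = None
) -> np.ndarray:
    """Min-max normalize amplitudes to [0.001, 1] within groups, then log10.

    Groups are (subject, modality) cells in the study; the group minimum maps
    to 0.001 (log10 = -3) and the maximum to 1 (log10 = 0).  Singleton or
    constant groups map to the maximum with a warning.
    """
    values = np.asarray(values, float)
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    groups = np.asarray(groups)
    out = np.empty_like(values)
    for g in pd.unique(groups):
        sel = groups == g
        v = values[sel]
        lo, hi = v.min(), v.max()
        if len(v) < 2 or hi == lo:
            logger.warning("normalization group %r is constant; mapping to maximum", g)
            out[sel] = 0.0
            continue
        scaled = 0.001 + (v - lo) / (hi - lo) * (1.0 - 0.001)
        out[sel] = np.log10(scaled)
    return out


def simulate_superposition(
    pulse_trials: np.ndarray,
    fs: float,
    f_stim: float = 40.0,
    n_sim_trials: int = 15,
    trial_len: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulated flicker trials from linearly summed single-pulse EPs.

    For each simulated trial, one randomly drawn (with replacement)
    single-pulse trial trace is added at every stimulus period (25 ms at
    40 Hz) from trial onset; tails beyond the trial edge are truncated.
    ``pulse_trials`` is the (n_trials, n_times) 1 s post-onset stack of one
    contact.  Returns (n_sim_trials, trial_len * fs).
    """
    pulse_trials = np.asarray(pulse_trials, float)
    if pulse_trials.ndim != 2 or pulse_trials.shape[0] < 1:
        raise ValueError("pulse_trials must be a (n_trials, n_times) stack")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_out = int(round(trial_len * fs))
    n_pulses = int(np.floor(trial_len * f_stim + 1e-9))
    ep_len = pulse_trials.shape[1]
    out = np.zeros((n_sim_trials, n_out))
    for s in range(n_sim_trials):
        picks = rng.integers(0, pulse_trials.shape[0], size=n_pulses)
        for k in range(n_pulses):
            start = int(round(k / f_stim * fs))
            stop = min(start + ep_len, n_out)
            out[s, start:stop] += pulse_trials[picks[k], : stop - start]
    return out


def classify_response(pulse_p: float, flicker_p: float, alpha: float = 0.05) -> str:
    """Cross the single-pulse and steady-state significances for one contact."""
    p = pulse_p < alpha
    f = flicker_p < alpha
    if p and f:
        return "both"
    if p:
        return "pulse_only"
    if f:
        return "flicker_only"
    return "none"
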