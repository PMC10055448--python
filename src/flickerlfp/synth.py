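"""Ground-truth-known synthetic sessions: LFP, trials, spikes, and IEDs.

The generator emulates the statistical structure the analyses assume:

* baseline LFP = Gaussian noise spectrally shaped to an aperiodic 1/f^chi
  component plus Gaussian log-power bumps (endogenous oscillations realized
  as narrowband noise, i.e. a sinusoid with slowly drifting phase and
  amplitude);
* condition-locked steady-state sinusoids whose amplitude is set from a
  target power fold-change, with per-trial stimulus-phase jitter;
* pulse-evoked responses built from a damped-oscillation (or low-pass
  alpha-function) kernel driven by the stimulus pulse train, either linearly
  (superposition), through a second-order resonator (frequency preference),
  or with per-pulse adaptation g_k = g_inf + (1 - g_inf) exp(-k / tau_a);
* von Mises phase-modulated inhomogeneous-Poisson spike trains;
* piecewise-constant-rate Poisson interictal-discharge (IED) streams.

Trial structure defaults follow the study design: 10 s stimulation trials
each followed by a 10 s baseline trial; 15 trials per condition in the
three-frequency paradigm, 10 per condition in the 26-frequency paradigm.
"""

from __future__ import annotations

import dataclasses
import functools
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sp_signal
from scipy.special import i0

from .io import Recording, condition_key, parse_frequency, validate_trial_table
from .steady_state import multitaper_psd

FLICKER_26_FREQS = (
    5.5, 8.0, 11.0, 14.0, 17.0, 20.0, 23.0, 26.0, 29.0, 32.0, 35.0, 38.0, 40.0,
    42.0, 45.0, 48.0, 51.0, 54.0, 57.0, 63.0, 66.0, 69.0, 72.0, 75.0, 78.0, 80.0,
)

PULSE_WIDTH_S = 0.0125  # 12.5 ms pulses, as in 40 Hz flicker


# ---------------------------------------------------------------------------
# stimulus waveforms

@dataclasses.dataclass
class Stimulus:
    """On/off envelope plus pulse onsets for one trial of stimulation."""

    envelope: np.ndarray     # 0/1 (or carrier-modulated for auditory)
    onsets: np.ndarray       # pulse onset times, seconds from trial start
    frequency: float | str
    fs: float
    duration: float


def make_stimulus(
    modality: str,
    frequency_or_tag,
    duration: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    carrier: bool = False,
) -> Stimulus:
    """Stimulus waveform for one trial.

    Periodic conditions are 50% duty-cycle square waves (40 Hz = 12.5 ms on /
    12.5 ms off).  The 'random' tag produces 12.5 ms pulses with inter-pulse
    intervals uniform on 0-25 ms (mean period 25 ms, like 40 Hz).  Auditory
    stimuli may additionally be returned as a 7 kHz carrier modulated by the
    envelope when fs allows.
    """
    freq = parse_frequency(frequency_or_tag)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    if isinstance(freq, str):
        if freq == "baseline":
            return Stimulus(np.zeros(n), np.array([]), freq, fs, duration)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        onsets = []
        tcur = 0.0
        while tcur + PULSE_WIDTH_S <= duration:
            onsets.append(tcur)
            tcur += PULSE_WIDTH_S + rng.uniform(0.0, 0.025)
        onsets = np.asarray(onsets)
        env = np.zeros(n)
        for o in onsets:
            i0_, i1 = int(round(o * fs)), int(round((o + PULSE_WIDTH_S) * fs))
            env[i0_:i1] = 1.0
    else:
        if freq > fs / 4:
            raise ValueError("stimulation frequency must be <= fs/4")
        phase = (t * freq) % 1.0
        env = (phase < 0.5).astype(float)
        n_pulses = int(np.floor(duration * freq + 1e-9))
        onsets = np.arange(n_pulses) / freq
    if carrier and modality == "auditory" and fs > 14_000:
        env = env * np.sin(2 * np.pi * 7000.0 * t)
    return Stimulus(env, onsets, freq, fs, duration)


# ---------------------------------------------------------------------------
# ground truth

@dataclasses.dataclass
class ChannelGroundTruth:
    """Generating parameters for one synthetic contact."""

    aperiodic_offset: float = 1.0     # log10 power (uV^2/Hz) at 1 Hz
    aperiodic_exponent: float = 1.5
    # endogenous oscillations: (center Hz, log10-power height, width Hz = 2 sd)
    peaks: tuple[tuple[float, float, float], ...] = ()
    response_mode: str = "none"       # none|linear_superposition|resonant|adapting
    steady_fold: float = 0.0          # target power fold-change of injected sinusoid
    jitter_sd: float = 0.0            # per-trial stimulus phase offset SD, radians
    kernel: str = "damped_osc"        # damped_osc | lowpass | delta
    kernel_amp: float = 0.0           # uV scale of the pulse-evoked kernel
    kernel_freq: float = 10.0         # damped-oscillation frequency, Hz
    kernel_tau: float = 0.05          # decay time constant, s
    resonator_center: float = 40.0    # Hz (resonant mode)
    resonator_q: float = 5.0
    adapt_g_inf: float = 0.2          # steady-state per-pulse gain (adapting mode)
    adapt_tau: float = 3.0            # adaptation time constant, pulses


@dataclasses.dataclass
class SpikeGroundTruth:
    """von Mises phase modulation of one unit by the stimulus."""

    rate: float = 5.0        # base rate r0, spikes/s
    kappa: float = 0.0       # von Mises concentration
    phase: float = 0.0       # preferred stimulus phase, radians


@dataclasses.dataclass
class IEDGroundTruth:
    """Piecewise-constant Poisson IED stream parameters."""

    rate_stim: float = 0.05      # events/s during stimulation
    rate_base: float = 0.05      # events/s otherwise
    mean_channels: float = 3.0   # mean size of the channel subset per event
    p_noise: float = 0.0         # probability of a >11-channel noise event


@dataclasses.dataclass
class GroundTruth:
    channels: list[ChannelGroundTruth]
    units: list[SpikeGroundTruth] = dataclasses.field(default_factory=list)
    ied: IEDGroundTruth = dataclasses.field(default_factory=IEDGroundTruth)


# ---------------------------------------------------------------------------
# trial tables

def make_trial_table(
    conditions: list[tuple[str, float | str]],
    n_trials_per_condition: int = 15,
    trial_duration: float = 10.0,
    baseline_after_each: bool = True,
    seed: int = 0,
    start: float = 2.0,
) -> pd.DataFrame:
    """Interleaved stimulation/baseline trial table.

    Conditions are shuffled across the session; each stimulation trial is
    directly followed by a baseline trial of the same duration (the study's
    10 s on / 10 s off structure).
    """
    rng = np.random.default_rng(seed)
    stim = [c for c in conditions for _ in range(n_trials_per_condition)]
    order = rng.permutation(len(stim))
    rows = []
    tcur = start
    tid = 0
    for k in order:
        modality, freq = stim[k]
        rows.append(dict(trial_id=tid, modality=modality, frequency=freq,
                         onset_s=tcur, duration_s=trial_duration))
        tid += 1
        tcur += trial_duration
        if baseline_after_each:
            rows.append(dict(trial_id=tid, modality="none", frequency="baseline",
                             onset_s=tcur, duration_s=trial_duration))
            tid += 1
            tcur += trial_duration
    return validate_trial_table(pd.DataFrame(rows))


def make_trial_table_26freq(
    modality: str = "visual",
    n_trials_per_condition: int = 10,
    trial_duration: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """26-frequency paradigm: each frequency, plus random and baseline."""
    conditions = [(modality, f) for f in FLICKER_26_FREQS] + [(modality, "random")]
    return make_trial_table(conditions, n_trials_per_condition, trial_duration,
                            baseline_after_each=False, seed=seed) .pipe(_append_baselines, n_trials_per_condition, trial_duration)


def _append_baselines(trials: pd.DataFrame, n: int, duration: float) -> pd.DataFrame:
    """Insert n baseline trials spread through the session (no-stim gaps)."""
    # shift every trial to open n evenly spaced baseline slots
    trials = trials.copy()
    total = len(trials)
    slots = np.linspace(0, total, n, endpoint=False).astype(int)
    rows = []
    tcur = float(trials["onset_s"].iloc[0])
    tid = 0
    it = trials.itertuples()
    for i in range(total):
        if i in set(slots):
            rows.append(dict(trial_id=tid, modality="none", frequency="baseline",
                             onset_s=tcur, duration_s=duration))
            tid += 1
            tcur += duration
        r = next(it)
        rows.append(dict(trial_id=tid, modality=r.modality, frequency=r.frequency,
                         onset_s=tcur, duration_s=r.duration_s))
        tid += 1
        tcur += r.duration_s
    return validate_trial_table(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# LFP session synthesis

def _target_psd(gt: ChannelGroundTruth, freqs: np.ndarray) -> np.ndarray:
    """Analytic baseline PSD (uV^2/Hz) of a channel: aperiodic + log-Gaussian bumps."""
    f = np.maximum(np.asarray(freqs, float), 0.5)  # clamp the 1/f divergence
    logp = gt.aperiodic_offset - gt.aperiodic_exponent * np.log10(f)
    for center, height, width in gt.peaks:
        sd = width / 2.0
        logp = logp + height * np.exp(-((np.asarray(freqs, float) - center) ** 2) / (2 * sd ** 2))
    return 10.0 ** logp


def _colored_noise(gt: ChannelGroundTruth, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with one-sided PSD _target_psd, via FFT shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum_sd = np.sqrt(_target_psd(gt, freqs) * fs * n / 4.0)
    z = spectrum_sd * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    z[0] = 0.0
    if n % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2.0)
    return np.fft.irfft(z, n=n)


def pulse_kernel(gt: ChannelGroundTruth, fs: float, length_s: float = 1.0) -> np.ndarray:
    """The pulse-evoked kernel: damped oscillation or low-pass alpha-squared."""
    t = np.arange(int(round(length_s * fs))) / fs
    if gt.kernel == "delta":
        k = np.zeros_like(t)
        k[0] = 1.0
    elif gt.kernel == "lowpass":
        k = (t / gt.kernel_tau) ** 2 * np.exp(-t / gt.kernel_tau)
    else:
        k = np.exp(-t / gt.kernel_tau) * np.sin(2 * np.pi * gt.kernel_freq * t)
    peak = np.max(np.abs(k))
    return gt.kernel_amp * (k / peak if peak > 0 else k)


def _pulse_response(gt: ChannelGroundTruth, stim: Stimulus, fs: float) -> np.ndarray:
    """Deterministic pulse-evoked response over one trial for this channel."""
    n = len(stim.envelope)
    if gt.kernel_amp == 0 or len(stim.onsets) == 0 or gt.response_mode == "none":
        return np.zeros(n)
    train = np.zeros(n)
    idx = np.round(stim.onsets * fs).astype(int)
    gains = np.ones(len(idx))
    if gt.response_mode == "adapting":
        k = np.arange(len(idx))
        gains = gt.adapt_g_inf + (1 - gt.adapt_g_inf) * np.exp(-k / gt.adapt_tau)
    np.add.at(train, idx[idx < n], gains[idx < n])
    resp = sp_signal.fftconvolve(train, pulse_kernel(gt, fs))[:n]
    if gt.response_mode == "resonant":
        b, a = sp_signal.iirpeak(gt.resonator_center, gt.resonator_q, fs=fs)
        resp = sp_signal.lfilter(b, a, resp)
    return resp


@functools.lru_cache(maxsize=128)
def _unit_sine_bin_power(fs: float, duration: float, f: float) -> float:
    """Multitaper power at the stim bin of a unit-amplitude sinusoid trial.

    This is the calibration constant linking an injected sinusoid amplitude
    to the power fold-change the estimator reports.
    """
    t = np.arange(int(round(duration * fs))) / fs
    x = np.sin(2 * np.pi * f * t)[None, None, :]
    res = multitaper_psd(x, fs=fs)
    return float(res.power_at(f)[0, 0])


def expected_fold_change(gt: ChannelGroundTruth, stim: Stimulus, fs: float) -> float:
    """Ground-truth expected power fold-change for one channel x condition.

    Sinusoid injection contributes its target fold directly (power at the
    stimulation bin is phase-invariant); pulse-kernel responses contribute
    their deterministic stim-bin multitaper power over the baseline PSD.
    """
    if isinstance(stim.frequency, str):
        return 0.0
    f = float(stim.frequency)
    fold = gt.steady_fold
    if gt.response_mode != "none" and gt.kernel_amp > 0:
        resp = _pulse_response(gt, stim, fs)
        p_resp = float(multitaper_psd(resp[None, None, :], fs=fs).power_at(f)[0, 0])
        p_bl = float(_target_psd(gt, np.array([f]))[0])
        fold += p_resp / p_bl
    return fold


def steady_state_fold_prediction(
    gt: ChannelGroundTruth, f: float, fs: float,
    duration: float = 10.0, discard: float = 1.0,
) -> float:
    """Noise-free fold prediction from the steady-state fundamental amplitude.

    The onset transient of the pulse-evoked response is discarded and the
    fundamental Fourier amplitude of an integer number of cycles is taken,
    so this ranks conditions by the sustained response alone (the low-pass /
    resonance prediction), not by onset-edge spectral splatter.
    """
    stim = make_stimulus("visual", f, duration, fs, 0)
    resp = _pulse_response(gt, stim, fs)
    seg = resp[int(discard * fs):]
    n_cyc = int(np.floor((duration - discard - 1.0) * f))
    L = int(round(n_cyc / f * fs))
    seg = seg[:L] - seg[:L].mean()
    k = int(round(f * L / fs))
    amp = 2.0 * np.abs(np.fft.rfft(seg)[k]) / L
    p_bl = float(_target_psd(gt, np.array([float(f)]))[0])
    return float(amp ** 2 / 2.0 / p_bl)


def make_lfp_session(
    gt: GroundTruth,
    trials: pd.DataFrame,
    fs: float = 500.0,
    seed: int = 0,
    contacts_per_probe: int = 8,
) -> tuple[Recording, dict]:
    """Synthesize a full multichannel session for a trial table.

    Returns the Recording and a ground-truth dict with, per channel, the
    expected fold-change for every stimulation condition (key
    ``expected_fold[channel_index][condition_key]``) plus the generating
    parameters.  Same seed -> bit-identical output.
    """
    trials = validate_trial_table(trials)
    rng = np.random.default_rng(seed)
    t_end = float(trials["onset_s"].iloc[-1] + trials["duration_s"].iloc[-1]) + 2.0
    n = int(round(t_end * fs))
    n_ch = len(gt.channels)
    samples = np.empty((n_ch, n))

    expected_fold: dict[int, dict[str, float]] = {}
    for ci, ch in enumerate(gt.channels):
        x = _colored_noise(ch, n, fs, rng)
        expected_fold[ci] = {}
        for row in trials.itertuples():
            freq = row.frequency
            if isinstance(freq, str) and freq == "baseline":
                continue
            stim = make_stimulus(row.modality, freq, row.duration_s, fs, seed=rng)
            i0_ = int(round(row.onset_s * fs))
            resp = _pulse_response(ch, stim, fs)
            if not isinstance(freq, str) and ch.steady_fold > 0:
                f = float(freq)
                p_bl = float(_target_psd(ch, np.array([f]))[0])
                c_unit = _unit_sine_bin_power(fs, float(row.duration_s), f)
                amp = np.sqrt(ch.steady_fold * p_bl / c_unit)
                phi = rng.normal(0.0, ch.jitter_sd) if ch.jitter_sd > 0 else 0.0
                tt = np.arange(len(stim.envelope)) / fs
                resp = resp + amp * np.sin(2 * np.pi * f * tt + phi)
            x[i0_:i0_ + len(resp)] += resp
            key = condition_key(row.modality, freq)
            if key not in expected_fold[ci]:
                expected_fold[ci][key] = expected_fold_change(ch, stim, fs)
        samples[ci] = x

    channels = pd.DataFrame(
        dict(
            contact_id=[f"c{i:03d}" for i in range(n_ch)],
            probe_id=[f"p{i // contacts_per_probe}" for i in range(n_ch)],
            probe_index=[i % contacts_per_probe for i in range(n_ch)],
            excluded=[False] * n_ch,
        )
    )
    rec = Recording(samples=samples, fs=fs, channels=channels)
    truth = dict(
        expected_fold=expected_fold,
        channels=[dataclasses.asdict(c) for c in gt.channels],
        fs=fs,
        seed=seed,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# single-pulse sessions

def make_pulse_recording(
    gt: GroundTruth,
    n_pulses: int = 200,
    fs: float = 500.0,
    seed: int = 0,
    occluded: bool = False,
) -> tuple[Recording, np.ndarray]:
    """Recording of isolated 12.5 ms pulses with randomized inter-pulse intervals.

    Inter-pulse intervals are uniform on 987.5-1487.5 ms.  ``occluded=True``
    suppresses all evoked responses (the apparatus control).  Returns the
    recording and the pulse onset times.
    """
    rng = np.random.default_rng(seed)
    ipi = rng.uniform(0.9875, 1.4875, size=n_pulses)
    onsets = 1.0 + np.concatenate([[0.0], np.cumsum(ipi[:-1])])
    t_end = onsets[-1] + 2.5
    n = int(round(t_end * fs))
    n_ch = len(gt.channels)
    samples = np.empty((n_ch, n))
    for ci, ch in enumerate(gt.channels):
        x = _colored_noise(ch, n, fs, rng)
        if not occluded and ch.kernel_amp > 0 and ch.response_mode != "none":
            kern = pulse_kernel(ch, fs)
            for o in onsets:
                i0_ = int(round(o * fs))
                seg = kern[: n - i0_]
                x[i0_:i0_ + len(seg)] += seg
        samples[ci] = x
    channels = pd.DataFrame(
        dict(
            contact_id=[f"c{i:03d}" for i in range(n_ch)],
            probe_id=["p0"] * n_ch,
            probe_index=list(range(n_ch)),
            excluded=[False] * n_ch,
        )
    )
    return Recording(samples=samples, fs=fs, channels=channels), onsets


# ---------------------------------------------------------------------------
# spikes and IEDs

def make_spikes(
    unit: SpikeGroundTruth,
    trials: pd.DataFrame,
    seed: int = 0,
    t_end: float | None = None,
) -> np.ndarray:
    """Spike times of one unit over a session (seconds, sorted).

    During periodic stimulation the rate is the von Mises modulation
    lambda(t) = r0 exp(kappa cos(theta(t) - phi0)) / I0(kappa) with theta the
    stimulus phase; elsewhere (baseline, random) the unit fires homogeneously
    at r0.  Sampled by thinning, so kappa = 0 reduces exactly to a
    homogeneous Poisson process.
    """
    trials = validate_trial_table(trials)
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = float(trials["onset_s"].iloc[-1] + trials["duration_s"].iloc[-1]) + 1.0
    if unit.rate <= 0:
        return np.array([])
    lam_max = unit.rate * np.exp(unit.kappa) / i0(unit.kappa)
    n_cand = rng.poisson(lam_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n_cand))
    accept_u = rng.uniform(0.0, 1.0, size=n_cand)

    lam = np.full(n_cand, unit.rate)
    for row in trials.itertuples():
        freq = row.frequency
        if isinstance(freq, str):
            continue
        in_trial = (cand >= row.onset_s) & (cand < row.onset_s + row.duration_s)
        theta = 2 * np.pi * float(freq) * (cand[in_trial] - row.onset_s)
        lam[in_trial] = unit.rate * np.exp(unit.kappa * np.cos(theta - unit.phase)) / i0(unit.kappa)
    keep = accept_u < lam / lam_max
    return cand[keep]


def make_ieds(
    ied: IEDGroundTruth,
    trials: pd.DataFrame,
    n_channels: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson IED event stream with per-event channel subsets.

    Events occur at ``rate_stim`` inside stimulation trials and ``rate_base``
    elsewhere.  Channel subset sizes are 1 + Poisson(mean_channels - 1),
    except noise events (probability ``p_noise``) which span >11 channels.
    Returns a DataFrame (t_s, channels) with channels a comma-joined id list.
    """
    trials = validate_trial_table(trials)
    rng = np.random.default_rng(seed)
    t_end = float(trials["onset_s"].iloc[-1] + trials["duration_s"].iloc[-1]) + 1.0

    stim_windows = [
        (row.onset_s, row.onset_s + row.duration_s)
        for row in trials.itertuples()
        if not (isinstance(row.frequency, str) and row.frequency == "baseline")
    ]
    times = []
    cursor = 0.0
    events_in = lambda a, b, r: np.sort(rng.uniform(a, b, size=rng.poisson(r * (b - a))))
    for a, b in stim_windows:
        if a > cursor:
            times.append(events_in(cursor, a, ied.rate_base))
        times.append(events_in(a, b, ied.rate_stim))
        cursor = b
    if cursor < t_end:
        times.append(events_in(cursor, t_end, ied.rate_base))
    t = np.sort(np.concatenate(times)) if times else np.array([])

    rows = []
    for ti in t:
        if ied.p_noise > 0 and rng.uniform() < ied.p_noise:
            size = rng.integers(12, max(13, n_channels) + 1)
        else:
            size = 1 + rng.poisson(max(ied.mean_channels - 1.0, 0.0))
        size = int(min(size, n_channels))
        chans = rng.choice(n_channels, size=size, replace=False)
        rows.append(dict(t_s=float(ti), channels=",".join(f"c{c:03d}" for c in sorted(chans))))
    return pd.DataFrame(rows, columns=["t_s", "channels"])


def save_ground_truth(path: str | Path, truth: dict) -> None:
    """YAML sidecar with the generating parameters and expected fold-changes."""
    def _clean(obj):
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj
    Path(path).write_text(yaml.safe_dump(_clean(truth)))
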