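"""Unit spiking analysis: classification, cycle PSTH, and phase locking.

Units are classified single/multi/artifact from a decision table of
waveform and firing-statistics features.  Modulation of included units by
the flicker stimulus is quantified with a peristimulus-time histogram over
overlapping two-cycle windows, the vector strength of spike phases relative
to the stimulus cycle, and the Rayleigh statistic Z = n VS^2.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import parse_frequency, validate_trial_table
from .stats import rayleigh_test, resultant_length


@dataclasses.dataclass
class UnitFeatures:
    """Curated features of one spike-sorted group (visual criteria precomputed)."""

    waveform_looks_artifactual: bool
    firing_rate: float                 # spikes/s
    frac_isi_lt_3ms: float             # fraction of inter-event intervals < 3 ms
    density_peak_narrowing: bool
    n_post_peak_local_peaks: int
    amplitude_distribution: str        # 'unimodal' | 'multimodal'


def classify_unit(f: UnitFeatures) -> str:
    """Single / multi-unit / artifact decision.

    Single unit: all of (non-artifactual waveform, rate > 0.05 Hz,
    ISI<3ms fraction < 0.05, no density narrowing, < 3 post-peak local
    peaks, unimodal amplitudes).  Multi-unit: meets no artifact criterion
    (artifactual waveform, rate <= 0.05, ISI fraction >= 0.1, narrowing,
    >= 4 post-peak peaks) but fails at least one single-unit criterion.
    Anything else is an artifact.
    """
    single = (
        not f.waveform_looks_artifactual
        and f.firing_rate > 0.05
        and f.frac_isi_lt_3ms < 0.05
        and not f.density_peak_narrowing
        and f.n_post_peak_local_peaks < 3
        and f.amplitude_distribution == "unimodal"
    )
    if single:
        return "single"
    artifact = (
        f.waveform_looks_artifactual
        or f.firing_rate <= 0.05
        or f.frac_isi_lt_3ms >= 0.1
        or f.density_peak_narrowing
        or f.n_post_peak_local_peaks >= 4
    )
    return "artifact" if artifact else "multi"


def _cycle_windows(duration: float, cycle_s: float) -> int:
    """Number of overlapping two-cycle windows in one trial (stride one cycle)."""
    n_cycles = int(np.floor(duration / cycle_s + 1e-9))
    return max(n_cycles - 1, 0)


def cycle_psth(
    spike_times: np.ndarray,
    trials,
    f_stim: float | str,
    n_bins_per_cycle: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """PSTH over two-cycle windows, aligned to pairs of stimulus pulses.

    Trials are re-cut into two-cycle windows with one overlapping cycle
    (stride one cycle); spike counts per phase bin are normalized to a rate
    in spikes/s.  The 'random' condition uses consecutive 25 ms
    pseudo-cycles.  Returns (bin_edges_seconds, rate_per_bin) with
    2 * n_bins_per_cycle bins.
    """
    trials = validate_trial_table(trials)
    spike_times = np.asarray(spike_times, float)
    freq = parse_frequency(f_stim) if isinstance(f_stim, (str, float, int)) else f_stim
    cycle_s = 0.025 if isinstance(freq, str) else 1.0 / float(freq)
    n_bins = 2 * n_bins_per_cycle
    wlen = 2 * cycle_s
    counts = np.zeros(n_bins)
    n_windows = 0
    for row in trials.itertuples():
        for k in range(_cycle_windows(row.duration_s, cycle_s)):
            w0 = row.onset_s + k * cycle_s
            sel = spike_times[(spike_times >= w0) & (spike_times < w0 + wlen)]
            if len(sel):
                bins = np.floor((sel - w0) / wlen * n_bins).astype(int)
                np.add.at(counts, np.clip(bins, 0, n_bins - 1), 1)
            n_windows += 1
    if n_windows == 0:
        raise ValueError("no complete two-cycle windows in the trials")
    bin_width = wlen / n_bins
    edges = np.arange(n_bins + 1) * bin_width
    return edges, counts / (n_windows * bin_width)


def include_unit(psths: dict[str, np.ndarray], max_empty_frac: float = 0.2) -> bool:
    """Keep a unit unless every condition has >20% empty PSTH bins."""
    fracs = [(np.asarray(c) == 0).mean() for c in psths.values()]
    return any(f <= max_empty_frac for f in fracs)


def spike_phases(spike_times: np.ndarray, trials, f_stim: float) -> np.ndarray:
    """Stimulus phase (radians) of every spike inside stimulation trials."""
    trials = validate_trial_table(trials)
    spike_times = np.asarray(spike_times, float)
    period = 1.0 / float(f_stim)
    phases = []
    for row in trials.itertuples():
        sel = spike_times[(spike_times >= row.onset_s) & (spike_times < row.onset_s + row.duration_s)]
        phases.append(2 * np.pi * (((sel - row.onset_s) % period) / period))
    return np.concatenate(phases) if phases else np.array([])


def kappa_from_vs(vs: float) -> float:
    """Invert VS = I1(kappa)/I0(kappa) numerically (von Mises concentration)."""
    from scipy.optimize import brentq
    from scipy.special import i0, i1
    vs = float(vs)
    if vs <= 0:
        return 0.0
    if vs >= 0.999:
        return float("inf")
    return float(brentq(lambda k: i1(k) / i0(k) - vs, 1e-9, 500.0))


def vector_strength(
    spike_times: np.ndarray, trials, f_stim: float
) -> tuple[float, float, int]:
    """Vector strength and Rayleigh p of a unit's locking to the stimulus cycle.

    VS = |sum exp(i theta_j)| / n over spike phases theta; the Rayleigh
    statistic Z = n VS^2 is converted to p with the standard approximation.
    Returns (VS, p, n_spikes).
    """
    phases = spike_phases(spike_times, trials, f_stim)
    n = len(phases)
    if n == 0:
        return float("nan"), 1.0, 0
    vs = resultant_length(phases)
    _, p = rayleigh_test(phases)
    return vs, p, n
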