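"""Data containers and on-disk formats.

A session is stored as an HDF5 container (``/lfp`` float32 channels x time,
``/fs`` scalar) plus two TSV sidecars: a channel table (contact_id, probe_id,
probe_index, excluded, anatomical_label, x/y/z mm) and a trial table
(trial_id, modality, frequency, onset_s, duration_s).  Frequencies are floats
in Hz, or the tags ``random`` / ``baseline``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

CHANNEL_COLUMNS = ["contact_id", "probe_id", "probe_index", "excluded"]
TRIAL_COLUMNS = ["trial_id", "modality", "frequency", "onset_s", "duration_s"]

MODALITIES = ("visual", "audiovisual", "auditory", "none")


def parse_frequency(value) -> float | str:
    """Return a frequency in Hz (float) or one of the tags 'random'/'baseline'."""
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("random", "baseline"):
            return v
        return float(v)
    return float(value)


def condition_key(modality: str, frequency) -> str:
    """Canonical string key for a (modality, frequency) condition."""
    f = parse_frequency(frequency)
    if isinstance(f, str):
        return f if f == "baseline" else f"{modality}:{f}"
    return f"{modality}:{f:g}"


@dataclasses.dataclass
class Recording:
    """Multichannel LFP recording with per-contact probe geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        LFP in microvolts.
    fs : float
        Sampling rate in samples/second.
    channels : DataFrame
        One row per contact, columns ``contact_id`` (unique), ``probe_id``,
        ``probe_index`` (deep -> superficial order within probe), ``excluded``
        (bool), and optionally ``anatomical_label``, ``x_mm``/``y_mm``/``z_mm``.
    """

    samples: np.ndarray
    fs: float
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel table length does not match samples")
        ids = self.channels["contact_id"]
        if ids.duplicated().any():
            raise ValueError("contact identifiers must be unique")
        if "excluded" not in self.channels:
            self.channels = self.channels.assign(excluded=False)
        self.channels = self.channels.reset_index(drop=True)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def probes(self) -> dict[str, list[int]]:
        """Ordered row indices per probe (deep -> superficial)."""
        out: dict[str, list[int]] = {}
        for probe_id, grp in self.channels.groupby("probe_id", sort=False):
            out[str(probe_id)] = list(grp.sort_values("probe_index").index)
        return out

    def good_channel_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.channels["excluded"].to_numpy(bool))

    def contact_ids(self, rows: Sequence[int] | None = None) -> list[str]:
        ids = self.channels["contact_id"].astype(str)
        return list(ids if rows is None else ids.iloc[list(rows)])


@dataclasses.dataclass
class TrialTensor:
    """Per-condition stack of equal-length trial segments.

    data has shape (n_trials, n_channels, n_times); ``onset_sample`` is the
    within-segment index of trial onset (= pad * fs), kept for time-locking.
    """

    data: np.ndarray
    fs: float
    condition: str
    pad: float
    onset_sample: int
    channel_rows: np.ndarray
    trial_onsets: np.ndarray  # onset of each trial in the recording, seconds

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def analysis_window(self) -> np.ndarray:
        """Trials trimmed to the unpadded window (pads removed symmetrically)."""
        n_pad = self.onset_sample
        stop = self.data.shape[2] - n_pad
        return self.data[:, :, n_pad:stop]


def validate_trial_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Check and normalize a trial table (sorted, non-overlapping, typed)."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    t = trials.copy()
    t["frequency"] = t["frequency"].map(parse_frequency)
    t["onset_s"] = t["onset_s"].astype(float)
    t["duration_s"] = t["duration_s"].astype(float)
    if (t["duration_s"] <= 0).any():
        raise ValueError("all trial durations must be positive")
    onsets = t["onset_s"].to_numpy()
    if not np.all(np.diff(onsets) > 0):
        raise ValueError("trial onsets must be strictly increasing")
    ends = onsets + t["duration_s"].to_numpy()
    if np.any(onsets[1:] < ends[:-1] - 1e-9):
        raise ValueError("trials overlap")
    return t.reset_index(drop=True)


def save_recording(path: str | Path, rec: Recording, channel_table_path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.samples.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
    rec.channels.to_csv(channel_table_path, sep="\t", index=False)


def load_recording(path: str | Path, channel_table_path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        samples = f["lfp"][...].astype(np.float64)
        fs = float(f["fs"][()])
    channels = pd.read_csv(channel_table_path, sep="\t")
    channels["excluded"] = channels["excluded"].astype(bool)
    return Recording(samples=samples, fs=fs, channels=channels)


def save_trials(path: str | Path, trials: pd.DataFrame) -> None:
    validate_trial_table(trials).to_csv(path, sep="\t", index=False)


def load_trials(path: str | Path) -> pd.DataFrame:
    return validate_trial_table(pd.read_csv(path, sep="\t"))
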