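"""Channel re-referencing, trial segmentation, filtering, and trial balancing.

The Laplacian montage subtracts from each contact the mean of its two nearest
non-excluded neighbors on the same depth probe; probe-end contacts fall back
to bipolar referencing against their single nearest usable neighbor.  Contacts
with no usable neighbor are excluded.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .io import Recording, TrialTensor, condition_key, validate_trial_table

logger = logging.getLogger(__name__)


def _nearest_usable(order: list[int], pos: int, usable: np.ndarray, direction: int) -> int | None:
    """Row index of the nearest usable contact from order[pos] in +/-1 direction."""
    j = pos + direction
    while 0 <= j < len(order):
        if usable[order[j]]:
            return order[j]
        j += direction
    return None


def rereference_laplacian(rec: Recording) -> Recording:
    """Laplacian re-reference a recording probe by probe.

    Interior contacts: x_i - (x_below + x_above)/2 with the nearest
    non-excluded neighbor on each side.  End contacts (or contacts with
    usable neighbors on one side only): bipolar, x_i - x_neighbor.
    Contacts with zero usable neighbors, and single-contact probes, are
    marked excluded in the output.  Excluded input channels stay excluded.
    """
    usable = ~rec.channels["excluded"].to_numpy(bool)
    out = np.zeros_like(rec.samples, dtype=float)
    new_excluded = rec.channels["excluded"].to_numpy(bool).copy()

    for probe_id, order in rec.probes().items():
        if sum(usable[i] for i in order) < 2:
            for i in order:
                if usable[i]:
                    new_excluded[i] = True
                    logger.warning(
                        "probe %s has <2 usable contacts; contact %s excluded",
                        probe_id, rec.channels.at[i, "contact_id"],
                    )
            continue
        for pos, i in enumerate(order):
            if not usable[i]:
                continue
            below = _nearest_usable(order, pos, usable, -1)
            above = _nearest_usable(order, pos, usable, +1)
            if below is not None and above is not None:
                out[i] = rec.samples[i] - 0.5 * (rec.samples[below] + rec.samples[above])
            elif below is not None:
                out[i] = rec.samples[i] - rec.samples[below]
            elif above is not None:
                out[i] = rec.samples[i] - rec.samples[above]
            else:  # unreachable given the <2-usable guard, kept for safety
                new_excluded[i] = True

    channels = rec.channels.copy()
    channels["excluded"] = new_excluded
    return Recording(samples=out, fs=rec.fs, channels=channels)


def segment_trials(
    rec: Recording,
    trials,
    pad: float = 1.0,
    channel_rows: np.ndarray | None = None,
) -> dict[str, TrialTensor]:
    """Cut the recording into per-condition (trials x channels x time) tensors.

    Each trial contributes the window [onset - pad, onset + duration + pad);
    sample indexing is 0-based and windows are half-open.  Only non-excluded
    channels are emitted.
    """
    trials = validate_trial_table(trials)
    if channel_rows is None:
        channel_rows = rec.good_channel_indices()
    channel_rows = np.asarray(channel_rows)

    tensors: dict[str, TrialTensor] = {}
    groups: dict[str, list[int]] = {}
    for idx, row in trials.iterrows():
        key = condition_key(row["modality"], row["frequency"])
        groups.setdefault(key, []).append(idx)

    n_pad = int(round(pad * rec.fs))
    for key, idxs in groups.items():
        segs, onsets = [], []
        n_len = None
        for idx in idxs:
            row = trials.loc[idx]
            start = int(round((row["onset_s"] - pad) * rec.fs))
            length = int(round((row["duration_s"] + 2 * pad) * rec.fs))
            if n_len is None:
                n_len = length
            if length != n_len:
                raise ValueError(f"trial {row['trial_id']} has unequal segment length")
            if start < 0 or start + length > rec.n_times:
                raise ValueError(
                    f"trial {row['trial_id']} (onset {row['onset_s']}s) exceeds recording bounds"
                )
            segs.append(rec.samples[channel_rows, start:start + length])
            onsets.append(row["onset_s"])
        tensors[key] = TrialTensor(
            data=np.stack(segs),
            fs=rec.fs,
            condition=key,
            pad=pad,
            onset_sample=n_pad,
            channel_rows=channel_rows,
            trial_onsets=np.asarray(onsets),
        )
    return tensors


def filter_flicker(
    seg: TrialTensor, band: tuple[float, float] = (2.0, 300.0), order: int = 4
) -> TrialTensor:
    """Zero-phase band-pass + per-segment baseline correction, then trim pads.

    The mean over the whole padded segment is subtracted per trial and
    channel; the band-pass is a forward-backward Butterworth so evoked
    waveforms keep their latencies.  If fs cannot support the upper edge the
    edge is clipped to 0.45*fs with a warning.
    """
    lo, hi = band
    if hi >= seg.fs / 2:
        hi = 0.45 * seg.fs
        logger.warning("band edge clipped to %.1f Hz for fs=%.1f", hi, seg.fs)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=seg.fs, output="sos")
    data = seg.data - seg.data.mean(axis=2, keepdims=True)
    data = signal.sosfiltfilt(sos, data, axis=2)
    n_pad = seg.onset_sample
    stop = data.shape[2] - n_pad
    return TrialTensor(
        data=np.ascontiguousarray(data[:, :, n_pad:stop]),
        fs=seg.fs,
        condition=seg.condition,
        pad=0.0,
        onset_sample=0,
        channel_rows=seg.channel_rows,
        trial_onsets=seg.trial_onsets,
    )


def balance_trials(
    tensors: dict[str, TrialTensor], seed: int
) -> tuple[dict[str, TrialTensor], dict[str, np.ndarray]]:
    """Downsample every condition (without replacement) to the minimum count.

    Returns the balanced tensors and the per-condition selected trial indices
    (sorted, so equal counts reduce to the identity).
    """
    n_min = min(t.n_trials for t in tensors.values())
    rng = np.random.default_rng(seed)
    out: dict[str, TrialTensor] = {}
    picks: dict[str, np.ndarray] = {}
    for key in tensors:
        t = tensors[key]
        sel = np.sort(rng.choice(t.n_trials, size=n_min, replace=False))
        picks[key] = sel
        out[key] = TrialTensor(
            data=t.data[sel],
            fs=t.fs,
            condition=t.condition,
            pad=t.pad,
            onset_sample=t.onset_sample,
            channel_rows=t.channel_rows,
            trial_onsets=t.trial_onsets[sel],
        )
    return out, picks
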