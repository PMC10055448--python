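"""Interictal epileptiform discharge (IED) rate statistics.

Detected spike events are post-processed (polyspike merging, multi-channel
noise rejection), then for each stimulation trial the proportion of IEDs
falling in the 10 s of stimulation out of the 20 s stimulation+baseline
pair is computed, averaged within condition and across conditions to one
value per session, and sessions are tested for a decrease from 50% with a
one-sample one-sided t-test.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io import validate_trial_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class IEDEvent:
    time: float
    channels: frozenset[str]


def _as_events(raw) -> list[IEDEvent]:
    if isinstance(raw, pd.DataFrame):
        out = []
        for row in raw.itertuples():
            chans = row.channels
            if isinstance(chans, str):
                chans = frozenset(c for c in chans.split(",") if c)
            out.append(IEDEvent(float(row.t_s), frozenset(chans)))
        return out
    return [IEDEvent(float(t), frozenset(c)) for t, c in raw]


def merge_and_filter(
    raw_events, merge_window: float = 0.1, max_channels: int = 11
) -> list[IEDEvent]:
    """Chain-merge polyspikes and drop widespread noise events.

    Successive events whose gap is <= ``merge_window`` (100 ms) join one IED
    whose time is the first constituent's and whose channel set is the
    union; merged IEDs spanning more than ``max_channels`` channels are
    considered noise and eliminated.  Idempotent.
    """
    events = sorted(_as_events(raw_events), key=lambda e: e.time)
    merged: list[IEDEvent] = []
    i = 0
    while i < len(events):
        t0 = events[i].time
        chans = set(events[i].channels)
        last = events[i].time
        j = i + 1
        while j < len(events) and events[j].time - last <= merge_window:
            chans |= events[j].channels
            last = events[j].time
            j += 1
        merged.append(IEDEvent(t0, frozenset(chans)))
        i = j
    return [e for e in merged if len(e.channels) <= max_channels]


def stim_proportion(
    events: list[IEDEvent] | pd.DataFrame, trials
) -> tuple[float, pd.DataFrame]:
    """Session-level proportion of IEDs occurring during stimulation.

    For each stimulation trial paired with its directly following baseline
    trial of equal duration, p_t = n_stim / (n_stim + n_base); trial pairs
    with no IEDs are omitted.  Proportions are averaged within condition,
    then across conditions, giving one value in [0, 1] per session (NaN if
    no trial pair contained an IED).  Returns (session_value,
    per-condition DataFrame).
    """
    trials = validate_trial_table(trials)
    events = _as_events(events) if not (
        isinstance(events, list) and all(isinstance(e, IEDEvent) for e in events)
    ) else events
    times = np.array([e.time for e in events])

    rows = []
    tr = trials.reset_index(drop=True)
    for i in range(len(tr) - 1):
        row, nxt = tr.iloc[i], tr.iloc[i + 1]
        if isinstance(row["frequency"], str) and row["frequency"] == "baseline":
            continue
        if not (isinstance(nxt["frequency"], str) and nxt["frequency"] == "baseline"):
            continue
        if abs(nxt["onset_s"] - (row["onset_s"] + row["duration_s"])) > 1e-6:
            continue
        if abs(nxt["duration_s"] - row["duration_s"]) > 1e-6:
            continue
        n_stim = int(((times >= row["onset_s"]) & (times < nxt["onset_s"])).sum())
        n_base = int(((times >= nxt["onset_s"]) & (times < nxt["onset_s"] + nxt["duration_s"])).sum())
        if n_stim + n_base == 0:
            continue
        from .io import condition_key
        rows.append(dict(condition=condition_key(row["modality"], row["frequency"]),
                         proportion=n_stim / (n_stim + n_base)))
    per_trial = pd.DataFrame(rows, columns=["condition", "proportion"])
    if per_trial.empty:
        return float("nan"), pd.DataFrame(columns=["condition", "proportion", "n_trials_used"])
    per_cond = per_trial.groupby("condition", sort=False).agg(
        proportion=("proportion", "mean"), n_trials_used=("proportion", "size")
    ).reset_index()
    return float(per_cond["proportion"].mean()), per_cond


def group_test(session_values) -> dict:
    """One-sample, one-sided t-test of a decrease from 50% across sessions.

    Sessions (including multiple sessions from one subject) are treated as
    independent.  Zero-variance input returns p = 1 with a warning.
    """
    v = np.asarray(session_values, float)
    v = v[np.isfinite(v)]
    mean_dev = float(v.mean() - 0.5)
    if len(v) < 2 or np.allclose(v.std(ddof=1), 0.0):
        logger.warning("degenerate session values (zero variance); reporting p = 1")
        return dict(mean_deviation=mean_dev, t=float("nan"), df=len(v) - 1, p=1.0)
    t, p = sp_stats.ttest_1samp(v, 0.5, alternative="less")
    return dict(mean_deviation=mean_dev, t=float(t), df=len(v) - 1, p=float(p))
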