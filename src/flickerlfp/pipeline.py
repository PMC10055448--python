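"""End-to-end orchestration: synthesize -> preprocess -> analyze -> report.

Stages communicate only through declared files (HDF5 recording + TSV
tables), so each stage can also be run standalone from the CLI.  A run is
fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from . import ied as ied_mod
from . import synth
from .io import (Recording, condition_key, load_recording, load_trials,
                 save_recording, save_trials)
from .preprocess import balance_trials, filter_flicker, rereference_laplacian, segment_trials
from .resonance import frequency_profile
from .spiking import cycle_psth, include_unit, vector_strength
from .steady_state import quantify_steady_state

PARADIGMS = ("flicker_3freq", "single_pulse", "flicker_26freq")


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    paradigm: str = "flicker_3freq"
    seed: int = 0
    fs: float = 500.0
    n_channels: int = 6
    n_trials_per_condition: int = 15
    n_perm: int = 10_000
    n_perm_pulse: int = 500
    alpha: float = 0.05
    modalities: tuple[str, ...] = ("visual",)
    frequencies: tuple[float, ...] = (5.5, 40.0, 80.0)
    laplacian: bool = True

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def demo_ground_truth(n_channels: int = 6) -> synth.GroundTruth:
    """A small mixed population: driven, resonant, adapting, and null contacts."""
    chans = []
    for i in range(n_channels):
        kind = i % 4
        if kind == 0:
            chans.append(synth.ChannelGroundTruth(steady_fold=2.0, jitter_sd=0.2,
                                                  peaks=((10.0, 0.9, 4.0),)))
        elif kind == 1:
            chans.append(synth.ChannelGroundTruth(response_mode="resonant", kernel_amp=8.0,
                                                  resonator_center=40.0, resonator_q=5.0))
        elif kind == 2:
            chans.append(synth.ChannelGroundTruth(response_mode="adapting", kernel_amp=8.0,
                                                  adapt_g_inf=0.2))
        else:
            chans.append(synth.ChannelGroundTruth())
    return synth.GroundTruth(channels=chans,
                             units=[synth.SpikeGroundTruth(rate=8.0, kappa=2.0)],
                             ied=synth.IEDGroundTruth(rate_stim=0.04, rate_base=0.05))


def synth_stage(config: RunConfig) -> dict[str, Path]:
    """Generate a session for the configured paradigm and write it to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = demo_ground_truth(config.n_channels)
    if config.paradigm == "flicker_26freq":
        trials = synth.make_trial_table_26freq(
            modality=config.modalities[0],
            n_trials_per_condition=min(config.n_trials_per_condition, 10),
            seed=config.seed,
        )
    else:
        conditions = [(m, f) for m in config.modalities
                      for f in list(config.frequencies) + ["random"]]
        trials = synth.make_trial_table(conditions, config.n_trials_per_condition,
                                        seed=config.seed)
    rec, truth = synth.make_lfp_session(gt, trials, fs=config.fs, seed=config.seed)
    paths = dict(
        recording=out / "recording.h5",
        channels=out / "channels.tsv",
        trials=out / "trials.tsv",
        ground_truth=out / "ground_truth.yaml",
        spikes=out / "spikes.tsv",
        ied_events=out / "ied_events.tsv",
    )
    save_recording(paths["recording"], rec, paths["channels"])
    save_trials(paths["trials"], trials)
    synth.save_ground_truth(paths["ground_truth"], truth)
    spike_rows = []
    for u, unit in enumerate(gt.units):
        for t in synth.make_spikes(unit, trials, seed=config.seed + 100 + u):
            spike_rows.append(dict(unit_id=f"u{u}", t_s=t))
    pd.DataFrame(spike_rows, columns=["unit_id", "t_s"]).to_csv(
        paths["spikes"], sep="\t", index=False)
    synth.make_ieds(gt.ied, trials, config.n_channels, seed=config.seed + 200).to_csv(
        paths["ied_events"], sep="\t", index=False)
    return paths


def analysis_ready(rec: Recording, laplacian: bool = True) -> Recording:
    return rereference_laplacian(rec) if laplacian else rec


def steady_state_stage(
    rec: Recording, trials: pd.DataFrame, n_perm: int, seed: int,
    laplacian: bool = True, pad: float = 1.0,
) -> pd.DataFrame:
    """Fold-change/PLV table for every stimulation condition vs baseline."""
    rec = analysis_ready(rec, laplacian)
    tensors = segment_trials(rec, trials, pad=pad)
    tensors = {k: filter_flicker(v) for k, v in tensors.items()}
    tensors, _ = balance_trials(tensors, seed=seed)
    if "baseline" not in tensors:
        raise ValueError("fold-change requires baseline trials in the session")
    baseline = tensors["baseline"]
    ids = rec.contact_ids(baseline.channel_rows)
    frames = []
    i = 0
    for key, seg in tensors.items():
        if key == "baseline" or key.endswith(":random"):
            continue
        f_stim = float(key.split(":")[1])
        frames.append(quantify_steady_state(seg, baseline, f_stim, n_perm=n_perm,
                                            seed=seed + 1 + i, contact_ids=ids))
        i += 1
    return pd.concat(frames, ignore_index=True)


def spiking_stage(
    spikes: pd.DataFrame, trials: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """VS / Rayleigh per unit and periodic stimulation condition."""
    rows = []
    stim = trials[trials["frequency"].map(lambda f: not isinstance(f, str))]
    for unit_id, sub in spikes.groupby("unit_id", sort=False):
        times = sub["t_s"].to_numpy(float)
        psths = {}
        for (mod, f), cond_trials in stim.groupby(["modality", "frequency"], sort=False):
            _, rate = cycle_psth(times, cond_trials, f)
            psths[condition_key(mod, f)] = rate
        included = include_unit(psths)
        for (mod, f), cond_trials in stim.groupby(["modality", "frequency"], sort=False):
            vs, p, n = vector_strength(times, cond_trials, float(f))
            rows.append(dict(unit_id=unit_id, condition=condition_key(mod, f),
                             vs=vs, rayleigh_p=p, n_spikes=n, included=included,
                             significant=included and p < alpha))
    return pd.DataFrame(rows)


def ied_stage(events: pd.DataFrame, trials: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    merged = ied_mod.merge_and_filter(events)
    return ied_mod.stim_proportion(merged, trials)


def run(config: RunConfig) -> dict:
    """Full demo run: synthesize a session and emit all stage tables."""
    out = Path(config.out_dir)
    paths = synth_stage(config)
    rec = load_recording(paths["recording"], paths["channels"])
    trials = load_trials(paths["trials"])

    outputs: dict[str, object] = {"inputs": {k: str(v) for k, v in paths.items()}}
    if config.paradigm == "flicker_26freq":
        prof = frequency_profile(analysis_ready(rec, config.laplacian), trials,
                                 modality=config.modalities[0],
                                 n_perm=config.n_perm, seed=config.seed,
                                 alpha=config.alpha)
        prof.table.to_csv(out / "frequency_profile.tsv", sep="\t", index=False)
        prof.summary.to_csv(out / "frequency_summary.tsv", sep="\t", index=False)
        prof.heatmap().to_csv(out / "heatmap_fold_change.tsv", sep="\t")
        outputs["n_contacts_gt6"] = int((prof.summary["n_significant_power"] > 6).sum())
    else:
        ss = steady_state_stage(rec, trials, n_perm=config.n_perm, seed=config.seed,
                                laplacian=config.laplacian)
        ss.to_csv(out / "steady_state.tsv", sep="\t", index=False)
        outputs["n_significant_contacts"] = int(
            (ss["p_perm"] < config.alpha).groupby(ss["contact_id"]).any().sum())
        outputs["median_fold_change"] = float(ss["fold_change"].median())

    spikes = pd.read_csv(paths["spikes"], sep="\t")
    if len(spikes):
        spiking_stage(spikes, trials, alpha=config.alpha).to_csv(
            out / "spiking.tsv", sep="\t", index=False)
    events = pd.read_csv(paths["ied_events"], sep="\t")
    session_value, per_cond = ied_stage(events, trials)
    per_cond.to_csv(out / "ied_proportions.tsv", sep="\t", index=False)
    outputs["ied_session_proportion"] = session_value

    provenance = dict(config=dataclasses.asdict(config), outputs={
        k: v for k, v in outputs.items() if not isinstance(v, dict)})
    (out / "run_summary.json").write_text(json.dumps(provenance, indent=2, default=str))
    return outputs
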