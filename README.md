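# flickerlfp

Analysis of rhythmic sensory ("flicker") stimulation effects in human
intracranial electrophysiology: steady-state evoked potentials in depth-electrode
LFP recordings, single-pulse evoked potentials and the linear-superposition
counterfactual, resonance/entrainment frequency preference, spike-phase
modulation of single units, and interictal epileptiform discharge (IED) rate
statistics. A ground-truth-known synthetic-session generator makes every stage
testable without access to clinical recordings.

The package is aimed at electrophysiologists analyzing stereo-EEG (SEEG)
sessions in which 10 s trials of visual/auditory/audiovisual square-wave
stimulation at fixed frequencies alternate with 10 s no-stimulation baselines.

## Core quantities

For each contact and stimulation condition:

- **Fold-change in power** at the stimulation frequency f:
  `fold = μ_stim / μ_bl − 1`, where `μ_stim` and `μ_bl` are multitaper PSD
  estimates (DPSS tapers, time–bandwidth product 3, 5 tapers, 2–100 Hz) at the
  bin nearest f, averaged over an equal number of stimulation and baseline
  trials. Significance is a one-sided trial-label permutation test
  (10,000 iterations by default, add-one smoothed p).
- **Phase-locking value (PLV)**: the magnitude of the mean unit phasor of the
  LFP–stimulus phase difference at f, extracted from non-overlapping 0.5 s
  windows; significance by Rayleigh's test on per-trial mean angles.
- **Single-pulse EP**: trial-averaged response to isolated 12.5 ms pulses
  (0.1 Hz high-pass, [−0.25, +1.25) s segments, pre-onset baseline correction),
  tested against a sensory-occluded control by permuting trial labels of
  `RMS(mean stim trace) − RMS(mean occluded trace)` over 0–1 s.
- **Linear-superposition simulation**: simulated 40 Hz flicker trials built by
  adding a randomly drawn single-pulse trial trace every 25 ms; comparing the
  simulated and measured fold-changes tests whether the steady-state EP is a
  sum of pulse EPs.
- **Vector strength** of a unit: `VS = |Σ exp(iθ_j)| / n` over spike phases θ
  within the stimulus cycle, with Rayleigh statistic `Z = n·VS²`.
- **IED stimulation proportion**: per stimulation/baseline trial pair,
  `p = n_stim / (n_stim + n_base)` after polyspike merging (100 ms) and
  rejection of events spanning >11 channels; averaged within condition, then
  across conditions to one value per session; sessions tested for a decrease
  from 50% with a one-sample one-sided t-test.

## Worked example

```python
import numpy as np
from flickerlfp import synth, preprocess, steady_state

# one strongly driven contact (target fold-change 2.0) and one silent contact
gt = synth.GroundTruth(channels=[
    synth.ChannelGroundTruth(steady_fold=2.0, jitter_sd=0.2),
    synth.ChannelGroundTruth(),
])
trials = synth.make_trial_table([("visual", 40.0)], n_trials_per_condition=15, seed=21)
rec, truth = synth.make_lfp_session(gt, trials, fs=500.0, seed=21)

tensors = preprocess.segment_trials(rec, trials, pad=1.0)
tensors = {k: preprocess.filter_flicker(v) for k, v in tensors.items()}
tensors, _ = preprocess.balance_trials(tensors, seed=0)
table = steady_state.quantify_steady_state(
    tensors["visual:40"], tensors["baseline"], f_stim=40.0, n_perm=10_000, seed=0)
print(table[["contact_id", "fold_change", "p_perm", "plv", "rayleigh_p"]])
```

prints (seed 21):

```
  contact_id  fold_change    p_perm       plv     rayleigh_p
0          0     2.675219  0.000100  0.559287  2.225074e-308
1          1    -0.180936  0.917708  0.045517   4.685407e-01
```

The driven contact recovers the injected fold-change of 2.0 (2.68 on this
single 15-trial realization; the median over many contacts converges to the
target) with the smallest attainable permutation p (1/10,001) and strong phase
locking; the silent contact shows a fold-change near 0 and a uniform phase
distribution.

The same stages are available from the command line:

```bash
flicker synth --out session/ --seed 1
flicker steady-state --recording session/recording.h5 --channels session/channels.tsv \
    --trials session/trials.tsv --out session/steady_state.tsv --n-perm 10000 --seed 1
```

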