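# Methods

This note documents the models and procedures implemented in `flickerlfp`,
the assumptions behind them, the numerical choices that were genuinely open,
and what the synthetic-data generator does and does not emulate.

## Preprocessing

**Referencing.** Depth-electrode (SEEG) recordings are Laplacian
re-referenced: each contact minus the mean of its two nearest non-excluded
neighbors on the same probe, which suppresses volume-conducted and
common-mode signal while preserving local sources. Probe-end contacts, and
contacts whose neighbors on one side are all excluded, fall back to bipolar
referencing; a contact with no usable neighbor — including any contact on a
single-contact probe — is excluded with a logged warning (the choice for
these degenerate probes was open; exclusion is the conservative option since
no local reference exists).

**Segmentation and filtering.** Trials are cut with a symmetric 1 s pad
(12 s segments for 10 s trials) so that filter edge artifacts fall outside
the analysis window. The 2–300 Hz band-pass is realized as a zero-phase
(forward–backward) Butterworth of order 4: the filter family and order were
unspecified design choices; zero-phase filtering is required because evoked
waveforms are later averaged time-locked to stimulus onset. "Baseline
correction" is mean subtraction per trial and channel over the full padded
segment — the simplest reading, stated explicitly so results are
deterministic. If the sampling rate cannot support the 300 Hz edge, the edge
is clipped to 0.45·fs with a warning. Unequal trial counts across conditions
are balanced by seeded random subsampling (without replacement) to the
minimum count.

## Steady-state quantification

The per-trial PSD uses DPSS multitaper estimation with time–bandwidth
product 3 and 5 tapers on the 10 s window (half-bandwidth 0.3 Hz, native
resolution 0.1 Hz), averaged over tapers with equal weights. "Power at the
stimulation frequency" is the nearest grid bin — at 0.1 Hz resolution the
bin error is negligible, so no interpolation is done.

The permutation test permutes stimulation/baseline labels of per-trial power
values and counts permuted mean differences that meet or exceed the observed
one (one-sided, significant below 5%). The p-value uses add-one smoothing,
`p = (1 + k) / (N + 1)`, so it is never exactly zero; with the default
N = 10,000 the smallest attainable p is ~1e-4. No correction across contacts
is applied by default (results are reported per contact at α = 0.05);
downstream consumers can correct the emitted p columns if needed.

The PLV pools the unit phasors of the LFP–stimulus phase difference over all
(trial, window) pairs before taking the magnitude; whether time-averaging
should occur within trial first was ambiguous, so the pooled average is the
default and `mean_within_trial=True` gives the alternative. The stimulus is
approximated by a sinusoid at the stimulation frequency, phase-aligned to
trial onset; windows are fs/2 samples with no overlap, which requires
f ≥ 4 Hz. Significance uses Rayleigh's test on per-trial mean angles with
the standard approximation `p = exp(−Z)(1 + (2Z − Z²)/(4n))`, Z = n·R²
(clipped into (0, 1]; the approximation goes negative in the extreme tail).

The "random" stimulation condition (12.5 ms pulses, uniform 0–25 ms
inter-pulse gaps, mean rate ≈ 40 Hz) serves as a comparison waveform; its
fold-change is evaluated at 40 Hz only on explicit request.

## Single-pulse EPs and the superposition counterfactual

Pulse responses are extracted after a 0.1 Hz order-4 zero-phase Butterworth
high-pass, segmented [−0.25, +1.25) s around pulse onset and corrected by the
0.25 s pre-onset mean. Response amplitude is the absolute maximum of the mean
trace over 0–1 s. For group comparison, amplitudes are min–max normalized to
[0.001, 1] within (subject, modality) groups and log10-transformed, mapping
each group's minimum to −3 and maximum to 0; constant or singleton groups map
to the maximum with a warning.

The superposition simulation draws, for each 25 ms grid point of each of 15
simulated 10 s trials, one single-pulse trial (with replacement — replacement
was unstated; it is the simplest choice and keeps draws independent of the
library size) and adds its 1 s post-onset trace at that offset, truncating at
the trial edge. Simulated trials are EP-sums only — no background activity is
added — and their fold-change is computed against the same baseline trials as
the measured response. Because individual pulse trials carry background
noise, ~40 traces overlap at any sample and the simulated trial's noise floor
at the stimulation bin is inflated ~40-fold relative to baseline; the
measured-vs-simulated comparison is therefore meaningful for strongly driven
contacts (stimulation-bin power well above 40× the baseline density), and the
validation suite uses pulse kernels in that regime (measured fold ~10³,
within the range observed for strong sensory contacts).

## Endogenous oscillations and resonance

Baseline spectra are parameterized as an aperiodic component
`log10 P(f) = offset − exponent·log10 f` plus up to five Gaussian peaks in
log-power space (peak width 2–10 Hz, minimum height 0.6 log10 units,
range 2–100 Hz). The aperiodic fit is a robust log–log linear fit that
iteratively drops peak-inflated points (three rounds, keeping residuals
below their 60th percentile); peaks are extracted largest-first from the
flattened spectrum, each refined by a bounded Gaussian fit, jointly refit,
and the aperiodic component is refit on the peak-subtracted spectrum. Peak
amplitude is also reported as `model(center)/aperiodic(center) − 1`. A fit
failure yields zero peaks plus logged diagnostics rather than an exception.

The 26-frequency analysis (5.5–80 Hz in ~3 Hz steps, omitting 60 Hz — mains
avoidance presumed) runs the steady-state quantification per frequency and
tabulates per contact the number of frequencies with significant fold-change
and PLV, and the top frequency (argmax fold-change among significant
frequencies; ties — possible in principle — go to the lower frequency and are
logged; fold-change is the default ranking, PLV is also reported). A contact
"entrains" an endogenous oscillation if it is significant at more than 6 of
the 26 frequencies, has at least one detected peak, and its top frequency
lies within 5 Hz of the nearest peak center. Heatmap exports are per-channel
min–max normalized so each row spans [0, 1].

## Spiking

Units are classified single/multi/artifact from a decision table of curated
features (waveform appearance, firing rate vs 0.05 Hz, fraction of
inter-event intervals <3 ms vs 0.05/0.1, waveform-density narrowing,
post-peak local peaks vs 3/4, amplitude-distribution modality). The visual
criteria are consumed as precomputed booleans/ordinals: they codify human
judgments, so the classifier implements only the decision table. Narrowing
is treated as an artifact criterion (the published table is ambiguous on
this row).

The cycle PSTH re-cuts trials into two-cycle windows with one overlapping
cycle (25 ms pseudo-cycles for the random condition) and uses 20 bins per
cycle — an open choice balancing phase resolution (1.25 ms at 40 Hz) against
counts per bin. A unit is excluded only if every condition has >20% empty
PSTH bins. Vector strength and the Rayleigh statistic are computed per
condition from spike phases within the stimulus cycle.

## IEDs

Detected discharge events (detection itself is upstream) are chain-merged:
successive events with gaps ≤100 ms form one IED (polyspike) timestamped at
its first constituent, with the channel union; merged events spanning more
than 11 channels are treated as detector noise and dropped. Chaining (rather
than a fixed window from the first spike) was chosen because a polyspike is
defined by its internal gaps. Each stimulation trial is paired with its
directly following equal-duration baseline; the per-pair proportion
`n_stim/(n_stim + n_base)` is averaged within condition and then across
conditions (not pooled — conditions may retain different trial counts after
omitting IED-free pairs), giving one value per session. Sessions, including
multiple sessions from one subject, are treated as independent in the
one-sample one-sided t-test against 0.5; a zero-variance input returns p = 1
with a warning.

## Anatomical localization

Each contact is assigned the label with the greatest summed "signal
strength" over non-white-matter atlas voxels whose centers lie within a 5 mm
sphere, each voxel weighted min(1, 1/r). The weight is capped at 1 for r < 1
mm (not only at r = 0) to keep weights bounded; a Gaussian-weight option
(σ = radius/2) exists but is non-default, since the explicit 1/r steps take
precedence over the "Gaussian sphere" wording. Background voxels are
excluded; ties go to the lower label id and are logged. Region groupings for
reporting (MTL, PFC, sensory groups) are configuration lists, not code.

## Synthetic-data generator

The generator targets the statistical assumptions of the analyses, not
biophysics:

- **Baseline**: Gaussian noise spectrally shaped by FFT filtering to
  `log10 P(f) = offset − exponent·log10 f + Σ Gaussian bumps`. Endogenous
  oscillations are narrowband Gaussian processes (equivalently, sinusoids
  with slowly drifting phase and amplitude), matching the aperiodic+peaks
  model the detection stage assumes. Default exponent 1.5, offset 1.0
  (log10 µV²/Hz at 1 Hz) — typical cortical LFP values.
- **Steady-state response**: a trial-locked sinusoid whose amplitude is set
  from a target power fold-change via a calibration constant (the
  stimulation-bin multitaper power of a unit sinusoid of the trial length,
  computed once through the package's own estimator — part of the
  measurement definition, since fold-change is defined through that
  estimator). Per-trial phase jitter (Gaussian, configurable SD) makes the
  PLV a free parameter without affecting power.
- **Pulse-evoked response**: a kernel (damped oscillation, low-pass
  alpha-squared, or discrete delta) driven by the stimulus pulse train;
  `linear_superposition` convolves directly, `resonant` passes the response
  through a unit-peak-gain second-order resonator (center, Q configurable),
  `adapting` scales pulse k by `g_k = g_∞ + (1 − g_∞)·exp(−k/τ_a)`.
- **Spikes**: inhomogeneous Poisson with von Mises rate modulation
  `λ(t) = r₀·exp(κ·cos(θ(t) − φ₀))/I₀(κ)` during periodic stimulation,
  homogeneous r₀ elsewhere, sampled by thinning (κ = 0 reduces exactly to
  homogeneous Poisson).
- **IEDs**: piecewise-constant-rate Poisson event times (stimulation vs
  baseline rates) with per-event random channel subsets, including optional
  >11-channel noise events for rejection testing.

Trial structure follows the study design: 10 s stimulation trials each
followed by a 10 s baseline (15 trials per condition in the three-frequency
paradigm; 10 per condition plus 10 random and 10 baseline in the
26-frequency paradigm). The generator does **not** emulate non-stationary
artifacts, cross-channel correlation, volume conduction, harmonics of the
steady-state response, or line noise — so passing tests demonstrate
correctness of the estimators and calibration of the tests under the assumed
signal model, not robustness to every property of clinical recordings.

## Validation conditions and problem sizes

The validation suite and `scripts/acceptance.py` use a 500 Hz sampling rate
and compact sessions (12 contacts × 50 trials for fold-change recovery;
single-contact 26-frequency sessions; 1000 replicates at 1000/500
permutations for test calibration), sizes at which the Monte-Carlo error of
each check is well below its tolerance. Two generator conditions are fixed
deliberately: the superposition-dissociation contacts use strong pulse
kernels (see above), and the resonance-readout contact uses Q = 12 so the
resonance bandwidth (~3 Hz) is resolved against the ~3 Hz stimulation grid;
at broader Q the top-frequency readout is genuinely shared between adjacent
grid frequencies (the deterministic Q = 5 profile still peaks at the
resonator center, which is checked separately).

## Known limitations

- The Rayleigh p approximation loses accuracy for Z ≳ 15 (reported as the
  clipped tail value).
- The spectral parameterization is a deliberately small re-implementation of
  the aperiodic+peaks model; it matches injected ground truth within the
  stated tolerances but is not feature-complete (no knee-mode aperiodic fit).
- `stim_proportion` requires the baseline trial to directly follow its
  stimulation trial; sessions with gaps between pair members are not paired.
- Polyspike merging slightly reallocates events across the
  stimulation/baseline boundary (merged events take the first spike's time);
  the induced bias on the proportion is second-order in rate × window.
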