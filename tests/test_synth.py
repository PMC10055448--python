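"""The synthetic-session generator: stimuli, LFP, spikes, IEDs."""

import numpy as np
import pytest
from scipy.special import i0, i1

from flickerlfp import synth
from flickerlfp.preprocess import filter_flicker, segment_trials
from flickerlfp.resonance import detect_endogenous
from flickerlfp.spiking import vector_strength
from flickerlfp.steady_state import multitaper_psd

from conftest import FS


class TestStimulus:
    def test_40hz_pulse_train_structure(self):
        s = synth.make_stimulus("visual", 40.0, 1.0, 10_000.0)
        assert len(s.onsets) == 40
        assert int(s.envelope[:250].sum()) == 125  # 12.5 ms on per 25 ms period
        assert s.envelope.mean() == pytest.approx(0.5)

    def test_random_train_mean_period(self):
        s = synth.make_stimulus("visual", "random", 200.0, 1000.0, seed=4)
        mean_period = np.diff(s.onsets).mean()
        assert mean_period == pytest.approx(0.025, rel=0.02)

    def test_frequency_above_quarter_fs_rejected(self):
        with pytest.raises(ValueError):
            synth.make_stimulus("visual", 200.0, 1.0, 500.0)


class TestLfpSession:
    def test_same_seed_bit_identical(self):
        gt = synth.GroundTruth(channels=[synth.ChannelGroundTruth(steady_fold=1.0)])
        trials = synth.make_trial_table([("visual", 40.0)], 3, seed=0)
        r1, _ = synth.make_lfp_session(gt, trials, fs=FS, seed=5)
        r2, _ = synth.make_lfp_session(gt, trials, fs=FS, seed=5)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_aperiodic_slope_recovered(self):
        # 10 minutes of pure baseline: log-log slope within +/-0.1 of target
        import pandas as pd
        gt = synth.GroundTruth(channels=[synth.ChannelGroundTruth(
            aperiodic_offset=1.0, aperiodic_exponent=1.5)])
        trials = pd.DataFrame([dict(trial_id=0, modality="none", frequency="baseline",
                                    onset_s=1.0, duration_s=600.0)])
        rec, _ = synth.make_lfp_session(gt, trials, fs=FS, seed=6)
        chunks = rec.samples[0, : int(600 * FS)].reshape(60, 1, -1)
        res = multitaper_psd(chunks, fs=FS)
        fit = detect_endogenous(res.freqs, res.psd[:, 0, :].mean(axis=0))
        assert fit.exponent == pytest.approx(1.5, abs=0.1)
        assert fit.n_peaks == 0

    def test_delta_kernel_matches_analytic_fourier_coefficient(self):
        # periodic delta train, amplitude a, period P samples: fundamental
        # sinusoid amplitude = 2 a / P
        fs, f, amp = 1000.0, 40.0, 5.0
        gt = synth.GroundTruth(channels=[synth.ChannelGroundTruth(
            response_mode="linear_superposition", kernel="delta", kernel_amp=amp,
            aperiodic_offset=-6.0)])  # negligible noise floor
        trials = synth.make_trial_table([("visual", f)], 1, seed=0)
        rec, _ = synth.make_lfp_session(gt, trials, fs=fs, seed=0)
        onset = int(round(trials["onset_s"].iloc[0] * fs))
        x = rec.samples[0, onset:onset + int(10 * fs)]
        spec = np.fft.rfft(x)
        measured_amp = 2 * np.abs(spec[int(f * 10)]) / len(x)
        P = fs / f
        assert measured_amp == pytest.approx(2 * amp / P, rel=0.05)

    def test_adapting_steady_state_attenuation(self):
        # late-pulse amplitude converges to g_inf of the first-pulse amplitude
        ch = synth.ChannelGroundTruth(response_mode="adapting", kernel="delta",
                                      kernel_amp=1.0, adapt_g_inf=0.2, adapt_tau=3.0)
        stim = synth.make_stimulus("visual", 40.0, 10.0, 1000.0)
        resp = synth._pulse_response(ch, stim, 1000.0)
        first = resp[0]
        late = resp[int(5 * 1000):][resp[int(5 * 1000):] != 0]
        assert np.abs(late).max() == pytest.approx(0.2 * first, rel=0.10)

    def test_null_mode_fold_change_centered_on_zero(self):
        gt = synth.GroundTruth(channels=[synth.ChannelGroundTruth() for _ in range(6)])
        trials = synth.make_trial_table([("visual", 40.0)], 15, seed=7)
        rec, truth = synth.make_lfp_session(gt, trials, fs=FS, seed=7)
        tensors = {k: filter_flicker(v) for k, v in segment_trials(rec, trials).items()}
        stim = multitaper_psd(tensors["visual:40"]).power_at(40.0)
        base = multitaper_psd(tensors["baseline"]).power_at(40.0)
        folds = stim.mean(axis=0) / base.mean(axis=0) - 1.0
        assert abs(np.median(folds)) < 0.35
        assert truth["expected_fold"][0]["visual:40"] == 0.0


class TestSpikes:
    def test_unmodulated_unit_has_null_vector_strength(self):
        trials = synth.make_trial_table([("visual", 40.0)], 15, seed=8)
        t = synth.make_spikes(synth.SpikeGroundTruth(rate=20.0, kappa=0.0), trials, seed=8)
        vs, _, n = vector_strength(t, trials[trials.frequency == 40.0], 40.0)
        assert vs < 3.0 / np.sqrt(n)

    def test_strong_modulation_approaches_one(self):
        trials = synth.make_trial_table([("visual", 40.0)], 15, seed=9)
        t = synth.make_spikes(synth.SpikeGroundTruth(rate=20.0, kappa=20.0), trials, seed=9)
        vs, _, _ = vector_strength(t, trials[trials.frequency == 40.0], 40.0)
        assert vs > 0.9

    def test_vs_converges_to_bessel_ratio(self):
        trials = synth.make_trial_table([("visual", 40.0)], 15, seed=10)
        t = synth.make_spikes(synth.SpikeGroundTruth(rate=30.0, kappa=2.0), trials, seed=10)
        vs, _, n = vector_strength(t, trials[trials.frequency == 40.0], 40.0)
        assert n > 1000
        assert vs == pytest.approx(i1(2) / i0(2), abs=0.03)

    def test_zero_rate_empty(self):
        trials = synth.make_trial_table([("visual", 40.0)], 2, seed=0)
        assert len(synth.make_spikes(synth.SpikeGroundTruth(rate=0.0), trials)) == 0


class TestIeds:
    def test_rate_ratio_sets_expected_proportion(self):
        from flickerlfp.ied import stim_proportion
        gt = synth.IEDGroundTruth(rate_stim=0.4, rate_base=0.5, mean_channels=2)
        trials = synth.make_trial_table([("visual", 40.0)], 200, seed=11)
        events = synth.make_ieds(gt, trials, n_channels=20, seed=11)
        value, _ = stim_proportion(events, trials)
        assert value == pytest.approx(0.4 / 0.9, abs=0.03)

    def test_noise_events_span_many_channels(self):
        from flickerlfp.ied import merge_and_filter
        gt = synth.IEDGroundTruth(rate_stim=0.5, rate_base=0.5, p_noise=1.0)
        trials = synth.make_trial_table([("visual", 40.0)], 10, seed=12)
        events = synth.make_ieds(gt, trials, n_channels=20, seed=12)
        assert len(events) > 0
        assert all(len(c.split(",")) >= 12 for c in events["channels"])
        # spaced-out noise events are all rejected downstream
        spaced = events[np.concatenate([[True], np.diff(events["t_s"]) > 0.2])]
        assert merge_and_filter(spaced) == []

    def test_determinism(self):
        gt = synth.IEDGroundTruth()
        trials = synth.make_trial_table([("visual", 40.0)], 5, seed=0)
        e1 = synth.make_ieds(gt, trials, 8, seed=3)
        e2 = synth.make_ieds(gt, trials, 8, seed=3)
        assert e1.equals(e2)
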