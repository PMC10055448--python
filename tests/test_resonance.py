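"""Spectral parameterization and the 26-frequency preference analysis."""

import numpy as np
import pandas as pd
import pytest

from flickerlfp import synth
from flickerlfp.resonance import (FrequencyProfile, OscillationPeak,
                                  detect_endogenous, entrainment_match,
                                  frequency_profile)
from flickerlfp.steady_state import quantify_steady_state
from flickerlfp.preprocess import balance_trials, filter_flicker, segment_trials

from conftest import FS


def synthetic_psd(freqs, offset=1.0, exponent=1.5, peaks=()):
    logp = offset - exponent * np.log10(freqs)
    for c, h, w in peaks:
        logp = logp + h * np.exp(-((freqs - c) ** 2) / (2 * (w / 2) ** 2))
    return 10.0 ** logp


FREQS = np.arange(2.0, 100.01, 0.1)


class TestDetectEndogenous:
    def test_pure_aperiodic_yields_no_peaks(self):
        fit = detect_endogenous(FREQS, synthetic_psd(FREQS))
        assert fit.n_peaks == 0
        assert fit.exponent == pytest.approx(1.5, abs=0.05)
        assert fit.offset == pytest.approx(1.0, abs=0.05)

    def test_single_bump_recovered(self):
        fit = detect_endogenous(FREQS, synthetic_psd(FREQS, peaks=[(10.0, 1.0, 4.0)]))
        assert fit.n_peaks == 1
        assert fit.peaks[0].center == pytest.approx(10.0, abs=1.0)
        assert fit.peaks[0].fold_vs_aperiodic == pytest.approx(10.0 ** 1.0 - 1.0, rel=0.2)

    def test_subthreshold_bump_ignored(self):
        fit = detect_endogenous(FREQS, synthetic_psd(FREQS, peaks=[(10.0, 0.3, 4.0)]))
        assert fit.n_peaks == 0

    def test_multi_peak_recovery_within_tolerance(self, rng):
        # centers recovered within max(1 Hz, width/2) for heights >= 0.8
        n_ok, n_tot = 0, 0
        for trial in range(25):
            c1 = rng.uniform(6, 20)
            c2 = rng.uniform(35, 70)
            w1, w2 = rng.uniform(2.5, 6, size=2)
            psd = synthetic_psd(FREQS, exponent=rng.uniform(1.0, 2.0),
                                peaks=[(c1, 0.9, w1), (c2, 0.8, w2)])
            psd = psd * rng.lognormal(0.0, 0.02, size=len(FREQS))
            fit = detect_endogenous(FREQS, psd)
            for c, w in ((c1, w1), (c2, w2)):
                n_tot += 1
                if any(abs(p.center - c) <= max(1.0, w / 2) for p in fit.peaks):
                    n_ok += 1
        assert n_ok / n_tot >= 0.95

    def test_at_most_five_peaks_and_width_limits(self):
        peaks = [(8 + 12 * i, 1.2, 4.0) for i in range(7)]
        fit = detect_endogenous(FREQS, synthetic_psd(FREQS, peaks=peaks))
        assert fit.n_peaks <= 5
        assert all(2.0 <= p.width <= 10.0 for p in fit.peaks)


@pytest.fixture(scope="module")
def resonant_profile():
    gt = synth.GroundTruth(channels=[
        synth.ChannelGroundTruth(response_mode="resonant", kernel_amp=16.0,
                                 resonator_center=40.0, resonator_q=12.0,
                                 peaks=((38.0, 0.9, 4.0),)),
    ])
    trials = synth.make_trial_table_26freq(n_trials_per_condition=10, seed=41)
    rec, truth = synth.make_lfp_session(gt, trials, fs=FS, seed=41)
    prof = frequency_profile(rec, trials, n_perm=500, seed=41)
    return rec, trials, truth, prof


class TestFrequencyProfile:
    def test_resonant_contact_prefers_resonator_center(self, resonant_profile):
        _, _, _, prof = resonant_profile
        row = prof.summary.iloc[0]
        assert row["top_freq_power"] == 40.0
        assert row["n_significant_power"] > 6

    def test_consistency_with_single_condition_quantification(self, resonant_profile):
        rec, trials, _, prof = resonant_profile
        tensors = {k: filter_flicker(v) for k, v in segment_trials(rec, trials).items()}
        tensors, _ = balance_trials(tensors, seed=41)
        df = quantify_steady_state(tensors["visual:40"], tensors["baseline"], 40.0,
                                   n_perm=100, seed=0,
                                   contact_ids=rec.contact_ids(tensors["baseline"].channel_rows))
        from_profile = prof.table[(prof.table.frequency == 40.0)].iloc[0]
        assert df["fold_change"].iloc[0] == pytest.approx(from_profile["fold_change"])
        assert df["plv"].iloc[0] == pytest.approx(from_profile["plv"])

    def test_heatmap_rows_span_unit_interval(self, resonant_profile):
        _, _, _, prof = resonant_profile
        hm = prof.heatmap()
        np.testing.assert_allclose(hm.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(hm.max(axis=1), 1.0, atol=1e-12)

    def test_lowpass_contact_expected_profile_decreases(self):
        # deterministic (noise-free) fold prediction of a low-pass kernel:
        # the superposition prediction is monotone decreasing in frequency
        ch = synth.ChannelGroundTruth(response_mode="linear_superposition",
                                      kernel="lowpass", kernel_amp=8.0, kernel_tau=0.05)
        folds = [synth.steady_state_fold_prediction(ch, f, FS)
                 for f in synth.FLICKER_26_FREQS]
        assert np.all(np.diff(folds) < 0)

    def test_q5_resonator_expected_profile_peaks_at_center(self):
        ch = synth.ChannelGroundTruth(response_mode="resonant", kernel_amp=16.0,
                                      resonator_center=40.0, resonator_q=5.0)
        folds = [synth.expected_fold_change(
            ch, synth.make_stimulus("visual", f, 10.0, FS, 0), FS)
            for f in synth.FLICKER_26_FREQS]
        assert synth.FLICKER_26_FREQS[int(np.argmax(folds))] == 40.0


class TestEntrainmentMatch:
    def _row(self, n_sig, top):
        return dict(n_significant_power=n_sig, top_freq_power=top,
                    n_significant_plv=0, top_freq_plv=float("nan"))

    def test_within_tolerance_matches(self):
        peaks = [OscillationPeak(38.0, 1.0, 4.0, 9.0)]
        out = entrainment_match(self._row(10, 40.0), peaks)
        assert out["eligible"] and out["matched"]
        assert out["nearest_endog"] == 38.0

    def test_distant_peaks_do_not_match(self):
        peaks = [OscillationPeak(10.0, 1.0, 4.0, 9.0), OscillationPeak(20.0, 1.0, 4.0, 9.0)]
        out = entrainment_match(self._row(10, 40.0), peaks)
        assert out["eligible"] and not out["matched"]

    def test_ineligible_contacts_flagged(self):
        peaks = [OscillationPeak(38.0, 1.0, 4.0, 9.0)]
        assert not entrainment_match(self._row(6, 40.0), peaks)["eligible"]
        assert not entrainment_match(self._row(10, 40.0), [])["eligible"]

    def test_null_match_rate_equals_enumerated_overlap(self, rng):
        # top freq drawn from the 26-grid, endogenous center independent and
        # uniform on 8-78 Hz: match rate equals the brute-force overlap
        # probability of the +/-5 Hz window
        grid = np.array(synth.FLICKER_26_FREQS)
        inner = grid[(grid >= 8) & (grid <= 78)]
        # brute-force probability over a fine enumeration of centers
        centers = np.linspace(8.0, 78.0, 70001)
        p_match = np.mean([
            (np.abs(centers - f) <= 5.0).mean() for f in inner
        ])
        n = 4000
        tops = rng.choice(inner, size=n)
        endo = rng.uniform(8.0, 78.0, size=n)
        hits = sum(
            entrainment_match(self._row(10, t), [OscillationPeak(e, 1.0, 4.0, 9.0)])["matched"]
            for t, e in zip(tops, endo)
        )
        assert hits / n == pytest.approx(p_match, abs=3 * np.sqrt(p_match * (1 - p_match) / n))
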