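"""Re-referencing, segmentation, filtering, and trial balancing."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from flickerlfp.io import Recording
from flickerlfp.preprocess import (balance_trials, filter_flicker,
                                   rereference_laplacian, segment_trials)
from flickerlfp.synth import make_trial_table

from conftest import FS, make_probe_recording


class TestLaplacian:
    def test_hand_computed_four_contact_probe(self):
        rec = make_probe_recording(np.array([[1.0], [2.0], [3.0], [4.0]]))
        out = rereference_laplacian(rec)
        np.testing.assert_allclose(out.samples.ravel(), [-1.0, 0.0, 0.0, 1.0])

    def test_common_signal_vanishes_at_interior_contacts(self, rng):
        c = rng.standard_normal(200)
        rec = make_probe_recording(np.tile(c, (5, 1)))
        out = rereference_laplacian(rec)
        np.testing.assert_allclose(out.samples[1:4], 0.0, atol=1e-12)

    def test_isolated_source_passes_through(self, rng):
        s = rng.standard_normal(100)
        samples = np.zeros((3, 100))
        samples[1] = s
        out = rereference_laplacian(make_probe_recording(samples))
        np.testing.assert_allclose(out.samples[1], s)

    def test_linearity(self, rng):
        x = rng.standard_normal((4, 50))
        y = rng.standard_normal((4, 50))
        a, b = 2.5, -1.3
        lx = rereference_laplacian(make_probe_recording(x)).samples
        ly = rereference_laplacian(make_probe_recording(y)).samples
        lxy = rereference_laplacian(make_probe_recording(a * x + b * y)).samples
        np.testing.assert_allclose(lxy, a * lx + b * ly, atol=1e-12)

    def test_excluded_neighbor_skipped(self):
        # contact 2 excluded: contact 1's neighbors become 0 and 3
        samples = np.array([[1.0], [2.0], [100.0], [4.0]])
        rec = make_probe_recording(samples, excluded=[False, False, True, False])
        out = rereference_laplacian(rec)
        assert out.samples[1, 0] == pytest.approx(2.0 - (1.0 + 4.0) / 2)
        assert out.channels["excluded"].tolist() == [False, False, True, False]

    def test_single_contact_probe_excluded(self):
        rec = Recording(
            samples=np.ones((1, 10)), fs=FS,
            channels=pd.DataFrame(dict(contact_id=["a"], probe_id=["p0"],
                                       probe_index=[0], excluded=[False])),
        )
        out = rereference_laplacian(rec)
        assert out.channels["excluded"].all()


class TestSegmentation:
    def test_padded_segment_length(self):
        rec = make_probe_recording(np.zeros((2, int(30 * 1000))), fs=1000.0)
        trials = pd.DataFrame([dict(trial_id=0, modality="visual", frequency=40.0,
                                    onset_s=5.0, duration_s=10.0)])
        tensors = segment_trials(rec, trials, pad=1.0)
        assert tensors["visual:40"].data.shape[-1] == 12_000

    def test_zero_pad_exact_length(self):
        rec = make_probe_recording(np.zeros((1, int(30 * FS))))
        trials = pd.DataFrame([dict(trial_id=0, modality="visual", frequency=40.0,
                                    onset_s=5.0, duration_s=10.0)])
        tensors = segment_trials(rec, trials, pad=0.0)
        assert tensors["visual:40"].data.shape[-1] == int(10 * FS)

    def test_out_of_bounds_trial_names_trial(self):
        rec = make_probe_recording(np.zeros((1, int(5 * FS))))
        trials = pd.DataFrame([dict(trial_id=7, modality="visual", frequency=40.0,
                                    onset_s=0.0, duration_s=3.0)])
        with pytest.raises(ValueError, match="7"):
            segment_trials(rec, trials, pad=1.0)

    def test_trial_order_invariance(self, rng):
        data = rng.standard_normal((1, int(100 * FS)))
        rec = make_probe_recording(data)
        trials = make_trial_table([("visual", 40.0)], n_trials_per_condition=4,
                                  trial_duration=10.0, seed=0)
        seg = segment_trials(rec, trials, pad=1.0)["visual:40"]
        # each trial's segment depends only on its own onset
        for i, onset in enumerate(seg.trial_onsets):
            start = int(round((onset - 1.0) * FS))
            np.testing.assert_array_equal(seg.data[i, 0], data[0, start:start + seg.data.shape[-1]])


class TestFilter:
    def _tensor(self, data, fs=2048.0):
        rec = make_probe_recording(data, fs=fs)
        n_t = data.shape[1]
        trials = pd.DataFrame([dict(trial_id=0, modality="visual", frequency=40.0,
                                    onset_s=1.0, duration_s=n_t / fs - 2.0)])
        return segment_trials(rec, trials, pad=1.0)["visual:40"]

    def test_dc_removed(self):
        seg = self._tensor(np.full((1, int(12 * 2048)), 50.0))
        out = filter_flicker(seg)
        assert abs(out.data.mean()) < 1e-9 * 50.0

    def test_passband_sinusoid_preserved(self):
        fs = 2048.0
        t = np.arange(int(12 * fs)) / fs
        seg = self._tensor(np.sin(2 * np.pi * 40 * t)[None, :], fs=fs)
        out = filter_flicker(seg).data[0, 0]
        # interior amplitude within passband ripple tolerance
        amp = np.abs(out[1000:-1000]).max()
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        fs = 2048.0
        t = np.arange(int(12 * fs)) / fs
        seg = self._tensor(np.sin(2 * np.pi * 500 * t)[None, :], fs=fs)
        out = filter_flicker(seg).data[0, 0]
        assert np.abs(out).max() < 10 ** (-20 / 20)  # >= 20 dB down

    def test_low_fs_clips_edge_with_warning(self, caplog):
        fs = 500.0
        t = np.arange(int(12 * fs)) / fs
        import logging
        with caplog.at_level(logging.WARNING, logger="flickerlfp.preprocess"):
            filter_flicker(self._tensor(np.sin(2 * np.pi * 40 * t)[None, :], fs=fs))
        assert any("clipped" in r.message for r in caplog.records)


class TestBalance:
    def _tensors(self, counts):
        out = {}
        for key, n in counts.items():
            from flickerlfp.io import TrialTensor
            out[key] = TrialTensor(data=np.arange(n)[:, None, None] * np.ones((n, 1, 4)),
                                   fs=FS, condition=key, pad=0.0, onset_sample=0,
                                   channel_rows=np.array([0]), trial_onsets=np.arange(n, dtype=float))
        return out

    def test_downsampled_to_minimum(self):
        balanced, picks = balance_trials(self._tensors({"a": 15, "b": 15, "baseline": 180}), seed=0)
        assert all(t.n_trials == 15 for t in balanced.values())
        assert len(picks["baseline"]) == 15

    def test_equal_counts_identity(self):
        tensors = self._tensors({"a": 7, "b": 7})
        balanced, picks = balance_trials(tensors, seed=3)
        for key in tensors:
            np.testing.assert_array_equal(balanced[key].data, tensors[key].data)
            np.testing.assert_array_equal(picks[key], np.arange(7))

    def test_same_seed_same_selection(self):
        t1, p1 = balance_trials(self._tensors({"a": 5, "baseline": 50}), seed=9)
        t2, p2 = balance_trials(self._tensors({"a": 5, "baseline": 50}), seed=9)
        np.testing.assert_array_equal(p1["baseline"], p2["baseline"])
        np.testing.assert_array_equal(t1["baseline"].data, t2["baseline"].data)
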