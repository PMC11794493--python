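"""Cleaning-chain contracts: filter responses, zero-phase behavior,
interpolation self-consistency, ocular ICA, re-referencing algebra,
epoching/baseline arithmetic and amplitude rejection."""

import dataclasses

import numpy as np
import pytest

from wplinet import (Recording, SimulationConfig, bandpass,
                     epoch_and_baseline, interpolate_bad, notch,
                     reject_amplitude, remove_ocular_ica,
                     rereference_linked_mastoids)
from wplinet.montage import CHANNELS_64
from wplinet.simulate import (ArtifactSpec, EventList, blink_ground_truth,
                              make_subject_recording)
from conftest import NULL_COUPLING


def tone_recording(freqs, amps, fs=500.0, dur=10.0, label="Cz"):
    t = np.arange(int(dur * fs)) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    return Recording(x[None, :], fs, [label]), t


def mid_amplitude(rec, f, t):
    """Amplitude of a tone estimated away from filter edge transients."""
    n = rec.n_samples
    core = rec.data[0, n // 4: 3 * n // 4]
    ref = np.sin(2 * np.pi * f * t)[n // 4: 3 * n // 4]
    cos = np.cos(2 * np.pi * f * t)[n // 4: 3 * n // 4]
    a = 2 * (core * ref).mean()
    b = 2 * (core * cos).mean()
    return np.hypot(a, b)


class TestFilters:
    def test_bandpass_removes_dc(self):
        rec = Recording(np.full((2, 5000), 42.0), 500.0, ["A", "B"])
        out = bandpass(rec, 0.1, 50.0)
        assert np.abs(out.data).max() < 1e-6 * 42.0

    def test_bandpass_preserves_midband_tone(self):
        rec, t = tone_recording([10.0], [1.0])
        out = bandpass(rec, 0.1, 50.0)
        assert abs(mid_amplitude(out, 10.0, t) - 1.0) < 0.01

    def test_bandpass_attenuates_out_of_band_tone(self):
        rec, t = tone_recording([80.0], [1.0])
        out = bandpass(rec, 0.1, 50.0)
        amp = mid_amplitude(out, 80.0, t)
        assert 20 * np.log10(1.0 / max(amp, 1e-12)) >= 20.0

    def test_notch_kills_line_frequency(self):
        rec, t = tone_recording([50.0], [1.0])
        out = notch(rec, 49.0, 51.0)
        assert mid_amplitude(out, 50.0, t) <= 0.1

    def test_notch_leaves_distant_tone(self):
        rec, t = tone_recording([10.0], [1.0])
        out = notch(rec, 49.0, 51.0)
        assert abs(mid_amplitude(out, 10.0, t) - 1.0) < 0.01

    def test_notch_linearity_on_mixture(self):
        rec, t = tone_recording([10.0, 50.0], [1.0, 1.0])
        out = notch(rec, 49.0, 51.0)
        target = np.sin(2 * np.pi * 10.0 * t)
        n = rec.n_samples
        sl = slice(n // 4, 3 * n // 4)
        rms_err = np.sqrt(np.mean((out.data[0, sl] - target[sl]) ** 2))
        assert rms_err / np.sqrt(np.mean(target[sl] ** 2)) < 0.02

    @pytest.mark.parametrize("op", [bandpass, notch])
    def test_zero_phase_no_lag(self, op):
        rec, _ = tone_recording([10.0], [1.0])
        out = op(rec, *(0.1, 50.0) if op is bandpass else (49.0, 51.0))
        xc = np.correlate(out.data[0], rec.data[0], mode="full")
        lag = int(np.argmax(xc)) - (rec.n_samples - 1)
        assert lag == 0

    def test_nyquist_violation_rejected(self):
        rec, _ = tone_recording([10.0], [1.0], fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(rec, 0.1, 50.0)

    def test_input_not_mutated_and_history_appended(self):
        rec, _ = tone_recording([10.0], [1.0])
        before = rec.data.copy()
        out = bandpass(rec, 0.1, 50.0)
        np.testing.assert_array_equal(rec.data, before)
        assert rec.history == []
        assert "bandpass" in out.history[-1]


class TestInterpolation:
    @pytest.fixture
    def scalp_recording(self, rng):
        labels = list(CHANNELS_64[:10])
        data = rng.standard_normal((10, 2000)) * 10
        return Recording(data, 250.0, labels)

    def test_no_bads_is_identity(self, scalp_recording):
        out = interpolate_bad(scalp_recording, [])
        np.testing.assert_array_equal(out.data, scalp_recording.data)

    def test_corrupted_copy_of_neighbor_recovered(self, rng):
        # Fp1 and Fp2 are close; make Fp1 a noisy copy of Fp2's signal,
        # destroy it, and check spline interpolation rebuilds something
        # close to the neighborhood signal.
        labels = list(CHANNELS_64[:12])
        data = rng.standard_normal((12, 2000)) * 5
        common = rng.standard_normal(2000) * 20
        data += common  # strong shared signal across the neighborhood
        original = data[0].copy()
        data[0] = rng.standard_normal(2000) * 50  # corrupted electrode
        rec = Recording(data, 250.0, labels)
        out = interpolate_bad(rec, ["Fp1"])
        r = np.corrcoef(out.data[0], original)[0, 1]
        assert r > 0.9

    def test_other_channels_untouched(self, scalp_recording):
        out = interpolate_bad(scalp_recording, ["Fp1"])
        np.testing.assert_array_equal(out.data[1:], scalp_recording.data[1:])

    def test_all_bad_rejected(self, scalp_recording):
        with pytest.raises(ValueError, match="4 good"):
            interpolate_bad(scalp_recording, list(scalp_recording.channel_labels))

    def test_unknown_label_rejected(self, scalp_recording):
        with pytest.raises(KeyError, match="nope"):
            interpolate_bad(scalp_recording, ["nope"])


class TestOcularICA:
    @staticmethod
    def ica_config(blink_rate=0.0, seed=0):
        return SimulationConfig(
            n_subjects=1, n_channels=16, fs=128.0, trial_sec=10.0,
            n_trials_per_cell=1, n_coupled=4, gap_sec=2.0, seed=seed,
            band_coupling={k: dict(v) for k, v in NULL_COUPLING.items()},
            artifact_spec=ArtifactSpec(blink_rate_per_min=blink_rate))

    @pytest.mark.parametrize("seed", range(5))
    def test_artifact_free_recording_removes_nothing(self, seed):
        rec, _ = make_subject_recording(self.ica_config(seed=seed), 0)
        cleaned, report = remove_ocular_ica(rec, threshold=0.8)
        assert report["removed"] == []
        np.testing.assert_allclose(cleaned.data, rec.data, atol=1e-6)

    def test_blink_component_removed(self):
        cfg = self.ica_config(blink_rate=20.0, seed=1)
        rec, _ = make_subject_recording(cfg, 0)
        blink = blink_ground_truth(cfg, 0, rec.n_samples)
        assert np.abs(blink).max() > 0
        cleaned, report = remove_ocular_ica(rec, threshold=0.8)
        assert report["removed"]
        scalp = cleaned.scalp_indices()
        b = blink - blink.mean()
        for i in scalp:
            x = cleaned.data[i] - cleaned.data[i].mean()
            r = (x * b).sum() / np.sqrt((x * x).sum() * (b * b).sum())
            assert abs(r) < 0.2

    def test_requires_eog_channel(self, rng):
        rec = Recording(rng.standard_normal((4, 500 * 70)), 500.0,
                        ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="EOG"):
            remove_ocular_ica(rec)

    def test_requires_minimum_duration(self, rng):
        rec = Recording(rng.standard_normal((4, 1000)), 128.0,
                        ["a", "b", "c", "VEOG"], eog_labels=("VEOG",))
        with pytest.raises(ValueError, match="60 s"):
            remove_ocular_ica(rec)


class TestRereference:
    def test_zero_mastoids_identity(self, rng):
        data = rng.standard_normal((4, 100))
        data[2:] = 0.0
        rec = Recording(data, 100.0, ["Fz", "Cz", "TP9", "TP10"])
        out = rereference_linked_mastoids(rec)
        np.testing.assert_allclose(out.data, rec.data)
        assert out.reference == "linked-mastoid"

    def test_mastoids_transform_by_their_own_mean(self, rng):
        data = rng.standard_normal((4, 100))
        rec = Recording(data, 100.0, ["Fz", "Cz", "TP9", "TP10"])
        out = rereference_linked_mastoids(rec)
        mast_mean = data[2:4].mean(axis=0)
        np.testing.assert_allclose(out.data[2], data[2] - mast_mean)
        np.testing.assert_allclose(out.data[3], data[3] - mast_mean)

    def test_second_application_is_identity(self, rng):
        rec = Recording(rng.standard_normal((4, 100)), 100.0,
                        ["Fz", "Cz", "TP9", "TP10"])
        once = rereference_linked_mastoids(rec)
        twice = rereference_linked_mastoids(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_m1_m2_synonyms(self, rng):
        rec = Recording(rng.standard_normal((3, 50)), 100.0,
                        ["Fz", "TP9", "TP10"])
        out = rereference_linked_mastoids(rec, ("M1", "M2"))
        assert "TP9" in out.history[-1]

    def test_missing_mastoid_lists_channels(self, rng):
        rec = Recording(rng.standard_normal((2, 50)), 100.0, ["Fz", "Cz"])
        with pytest.raises(ValueError, match="Fz"):
            rereference_linked_mastoids(rec)


class TestEpoching:
    def test_constant_offset_zeroed_by_baseline(self):
        data = np.full((2, 4000), 7.5)
        rec = Recording(data, 100.0, ["A", "B"])
        ev = EventList(np.array([500, 2000]),
                       [("visual", "nostalgic"), ("visual", "non-nostalgic")])
        ep = epoch_and_baseline(rec, ev, 0.0, 5.0, (-1.0, 0.0))
        np.testing.assert_allclose(ep.epochs, 0.0, atol=1e-12)

    def test_epoch_sample_count(self):
        fs = 500.0
        rec = Recording(np.zeros((1, int(40 * fs))), fs, ["A"])
        ev = EventList(np.array([int(5 * fs)]), [("visual", "nostalgic")])
        ep = epoch_and_baseline(rec, ev, 0.0, 30.0, (-5.0, 0.0))
        assert ep.epochs.shape == (1, 1, 15000)

    def test_event_order_invariance(self, rng):
        data = rng.standard_normal((2, 6000))
        rec = Recording(data, 100.0, ["A", "B"])
        onsets = np.array([500, 2000, 3500])
        labels = [("visual", "nostalgic"), ("auditory", "nostalgic"),
                  ("audiovisual", "non-nostalgic")]
        ep1 = epoch_and_baseline(rec, EventList(onsets, labels), 0, 5, (-1, 0))
        # same trials; EventList requires sorted onsets, so compare content
        # through per-trial lookup instead of raw order
        ep2 = epoch_and_baseline(rec, EventList(onsets[::1], labels), 0, 5, (-1, 0))
        for lab in labels:
            i1 = ep1.labels.index(lab)
            i2 = ep2.labels.index(lab)
            np.testing.assert_array_equal(ep1.epochs[i1], ep2.epochs[i2])

    def test_out_of_range_trial_dropped_not_fatal(self):
        rec = Recording(np.zeros((1, 1000)), 100.0, ["A"])
        ev = EventList(np.array([100, 950]),
                       [("visual", "nostalgic"), ("visual", "non-nostalgic")])
        ep = epoch_and_baseline(rec, ev, 0.0, 5.0, (-1.0, 0.0))
        assert ep.n_trials == 1
        assert "dropped_onsets=[950]" in ep.history[-1]


class TestAmplitudeRejection:
    @staticmethod
    def epochs_with_peaks(peaks):
        n = len(peaks)
        data = np.zeros((n, 2, 100))
        for i, p in enumerate(peaks):
            data[i, 0, 50] = p
        from wplinet import EpochSet
        return EpochSet(data, 100.0, [("visual", "nostalgic")] * n, ["A", "B"])

    def test_strict_threshold_boundary(self):
        ep = reject_amplitude(self.epochs_with_peaks([75.1, 74.9, 75.0]), 75.0)
        assert ep.rejected_mask.tolist() == [True, False, False]

    def test_planted_spikes_all_caught(self):
        cfg = SimulationConfig(
            n_subjects=1, n_channels=8, fs=128.0, trial_sec=4.0,
            n_trials_per_cell=2, n_coupled=4, gap_sec=2.0, seed=9,
            band_coupling={k: dict(v) for k, v in NULL_COUPLING.items()},
            noise_sd=5.0,
            artifact_spec=ArtifactSpec(spike_prob_per_epoch=0.5,
                                       spike_amp_uv=400.0))
        rec, ev = make_subject_recording(cfg, 0)
        ep = epoch_and_baseline(rec, ev, 0, cfg.trial_sec, (-1, 0))
        # ground truth: which epochs contain a sample beyond the threshold
        expected = (np.abs(ep.epochs[:, ep.scalp_indices(), :]) > 75.0).any(
            axis=(1, 2))
        out = reject_amplitude(ep, 75.0)
        assert out.rejected_mask.tolist() == expected.tolist()
        assert 0 < expected.sum() < ep.n_trials

    def test_infinite_threshold_keeps_all(self):
        ep = reject_amplitude(self.epochs_with_peaks([100.0, 500.0]), np.inf)
        assert not ep.rejected_mask.any()

    def test_all_rejected_is_explicit_error(self):
        with pytest.raises(ValueError, match="rejected all"):
            reject_amplitude(self.epochs_with_peaks([100.0, 200.0]), 75.0)

    def test_rejected_excluded_downstream(self):
        ep = reject_amplitude(self.epochs_with_peaks([100.0, 10.0]), 75.0)
        assert ep.retained().tolist() == [1]
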