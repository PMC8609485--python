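"""Filtering, artifact masking, interpolation, referencing and epoching."""

import numpy as np
import pytest

from l2brain import preprocessing as pp
from l2brain.preprocessing import Event, PreprocessingError
from tests.conftest import make_recording


def sinusoid(freq, amp, fs, dur, n_ch=4):
    t = np.arange(int(dur * fs)) / fs
    return np.tile(amp * np.sin(2 * np.pi * freq * t), (n_ch, 1))


class TestBandpassFilter:
    def test_in_band_amplitude_preserved(self):
        rec = make_recording(sinusoid(10, 5.0, 512, 8.0))
        out = pp.bandpass_filter(rec)
        core = out.data[:, 1024:-1024]  # skip edges
        amp = np.sqrt(2) * core.std()
        assert amp == pytest.approx(5.0, rel=0.05)

    def test_out_of_band_attenuated_20db(self):
        rec = make_recording(sinusoid(60, 5.0, 512, 8.0))
        out = pp.bandpass_filter(rec)
        rms_in = 5.0 / np.sqrt(2)
        rms_out = out.data[:, 1024:-1024].std()
        assert 20 * np.log10(rms_in / rms_out) >= 20.0

    def test_dc_removed(self):
        rec = make_recording(np.full((4, 512 * 16), 100.0))
        out = pp.bandpass_filter(rec)
        assert abs(out.data[:, 2048:-2048].mean()) < 1.0

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(sinusoid(10, 1.0, 100, 2.0), fs=100)
        with pytest.raises(PreprocessingError):
            pp.bandpass_filter(rec, high_hz=60.0)


class TestDetectArtifacts:
    def test_zero_signal_fully_flagged_as_flatline(self):
        rec = make_recording(np.zeros((2, 2048)), fs=512)
        mask = pp.detect_artifacts(rec)
        assert (mask.flagged_fraction() == 1.0).all()

    def test_clean_sinusoid_empty_mask(self):
        rec = make_recording(sinusoid(10, 10.0, 512, 4.0))
        mask = pp.detect_artifacts(rec)
        assert all(len(iv) == 0 for iv in mask.intervals)

    def test_single_step_interval(self):
        # 60 µV step at sample k with 200 ms padding at 512 Hz
        data = sinusoid(10, 10.0, 512, 4.0, n_ch=2)
        k = 1000
        data[0, k:] += 60.0
        mask = pp.detect_artifacts(make_recording(data, fs=512))
        assert mask.intervals[0].tolist() == [[k - 102, k + 103]]
        assert len(mask.intervals[1]) == 0  # channel-local masking

    def test_window_longer_than_recording_rejected(self):
        rec = make_recording(np.zeros((2, 40)), fs=512)
        with pytest.raises(PreprocessingError):
            pp.detect_artifacts(rec)

    def test_block_mode_flags_step(self):
        data = sinusoid(10, 10.0, 512, 4.0, n_ch=1)
        data[0, 1000:] += 300.0
        mask = pp.detect_artifacts(make_recording(data, fs=512), windows="block")
        assert len(mask.intervals[0]) >= 1

    def test_detection_does_not_modify_data(self):
        data = sinusoid(10, 10.0, 512, 2.0)
        rec = make_recording(data.copy())
        pp.detect_artifacts(rec)
        np.testing.assert_array_equal(rec.data, data)

    def test_intervals_sorted_and_disjoint(self, rng):
        data = 5 * rng.standard_normal((3, 4096)) + sinusoid(10, 10, 512, 8.0, 3)
        data[1, 500] += 400
        data[1, 900] += 400
        mask = pp.detect_artifacts(make_recording(data, fs=512))
        for iv in mask.intervals:
            if len(iv) > 1:
                assert (iv[1:, 0] > iv[:-1, 1]).all()
            assert (iv[:, 0] < iv[:, 1]).all()


class TestInterpolation:
    def test_replacement_is_neighbor_mean(self):
        data = np.full((6, 1000), 5.0)
        data[0] = 0.0
        rec = make_recording(data, fs=500)
        intervals = [np.array([[0, 1000]])] + [np.empty((0, 2), int)] * 5
        mask = pp.ArtifactMask(intervals, 1000, 0.0)
        out, report = pp.interpolate_bad_channels(rec, mask)
        assert report["replaced"] == [rec.labels[0]]
        np.testing.assert_allclose(out.data[0], 5.0)

    def test_flat_channel_detected_and_replaced(self):
        data = sinusoid(10, 10.0, 512, 4.0, n_ch=6)
        data[2] = 0.123  # flatline
        rec = make_recording(data, fs=512)
        mask = pp.detect_artifacts(rec)
        out, report = pp.interpolate_bad_channels(rec, mask)
        assert report["replaced"] == [rec.labels[2]]
        # replacement equals the mean of in-phase sinusoidal neighbours
        np.testing.assert_allclose(out.data[2], data[0], atol=1e-9)
        np.testing.assert_array_equal(out.data[[0, 1, 3, 4, 5]], data[[0, 1, 3, 4, 5]])

    def test_identity_when_no_channel_qualifies(self):
        rec = make_recording(sinusoid(10, 10.0, 512, 2.0))
        mask = pp.detect_artifacts(rec)
        out, report = pp.interpolate_bad_channels(rec, mask)
        assert report["replaced"] == []
        np.testing.assert_array_equal(out.data, rec.data)

    def test_too_many_bad_channels_is_hard_error(self):
        data = np.zeros((8, 1000))  # every channel flat
        rec = make_recording(data, fs=500)
        mask = pp.detect_artifacts(rec)
        with pytest.raises(PreprocessingError):
            pp.interpolate_bad_channels(rec, mask, max_interp=5)


class TestRereference:
    def test_two_channel_example(self):
        rec = make_recording(np.array([[3.0], [-1.0]]), fs=10)
        out = pp.rereference_average(rec)
        np.testing.assert_allclose(out.data[:, 0], [2.0, -2.0])

    def test_idempotent_on_zero_mean(self, rng):
        data = rng.standard_normal((4, 100))
        data -= data.mean(axis=0)
        rec = make_recording(data, fs=10)
        out = pp.rereference_average(rec)
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_column_means_vanish(self, rng):
        rec = make_recording(rng.standard_normal((8, 500)) * 40, fs=100)
        out = pp.rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9


class TestExtractEcSegments:
    def test_trim_shortens_both_ends(self, ec_events):
        fs = 100.0
        evs, n = ec_events(fs, eo_s=5, ec_s=30)
        rec = make_recording(np.zeros((2, n)), fs=fs, events=evs)
        segs = pp.extract_ec_segments(rec, trim_s=5)
        assert len(segs) == 2
        for s, e in segs:
            assert e - s == 20 * fs

    def test_trim_zero_verbatim(self, ec_events):
        fs = 100.0
        evs, n = ec_events(fs, eo_s=5, ec_s=30)
        rec = make_recording(np.zeros((2, n)), fs=fs, events=evs)
        segs = pp.extract_ec_segments(rec, trim_s=0)
        assert all(e - s == 30 * fs for s, e in segs)

    def test_short_segment_dropped_with_warning(self, ec_events):
        fs = 100.0
        evs, n = ec_events(fs, eo_s=5, ec_s=8, n_cycles=1)
        rec = make_recording(np.zeros((2, n)), fs=fs, events=evs)
        with pytest.warns(UserWarning):
            segs = pp.extract_ec_segments(rec, trim_s=5)
        assert segs == []

    def test_no_ec_events_rejected(self):
        rec = make_recording(np.zeros((2, 100)), fs=10, events=[Event(0, "eyes-open")])
        with pytest.raises(PreprocessingError):
            pp.extract_ec_segments(rec)


class TestEpochFixedOverlap:
    def test_110s_segment_gives_109_epochs(self):
        fs = 512.0
        rec = make_recording(np.zeros((2, int(110 * fs))), fs=fs)
        out = pp.epoch_fixed_overlap(rec, [(0, rec.n_samples)], None, 2.0, 0.5)
        assert out.n_epochs == 109
        assert out.data.shape[2] == 1024

    def test_zero_overlap(self):
        fs = 100.0
        rec = make_recording(np.zeros((2, int(10 * fs))), fs=fs)
        out = pp.epoch_fixed_overlap(rec, [(0, rec.n_samples)], None, 2.0, 0.0)
        assert out.n_epochs == 5

    def test_fully_masked_segment_yields_no_epochs(self):
        rec = make_recording(np.zeros((1, 1000)), fs=100)
        mask = pp.ArtifactMask([np.array([[0, 1000]])], 1000, 0.0)
        out = pp.epoch_fixed_overlap(rec, [(0, 1000)], mask, 2.0, 0.5)
        assert out.n_epochs == 0

    def test_epoch_length_rounds_half_to_even(self):
        # 1.5 s at 341 Hz -> 511.5 samples -> 512
        rec = make_recording(np.zeros((1, 4096)), fs=341.0)
        out = pp.epoch_fixed_overlap(rec, [(0, 4096)], None, 1.5, 0.0)
        assert out.data.shape[2] == 512


class TestEpochEvents:
    def test_baseline_removes_constant(self):
        fs = 100.0
        data = np.full((2, 1000), 7.0)
        evs = [Event(500, "target", {"condition": "switch/congruent"})]
        rec = make_recording(data, fs=fs, events=evs)
        out = pp.epoch_events(rec, None, "target", (-100, 1000), (-100, 0))
        assert out.n_epochs == 1
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)
        assert out.tags == ["switch/congruent"]

    def test_anchor_at_recording_start_dropped(self):
        rec = make_recording(
            np.zeros((2, 500)), fs=100, events=[Event(0, "target", {})]
        )
        out = pp.epoch_events(rec, None, "target")
        assert out.n_epochs == 0

    def test_design_arithmetic_320_anchors(self):
        from l2brain.erp import CONDITIONS

        fs = 128.0
        n_pre, gap = 64, 200
        events = []
        for i in range(320):
            events.append(
                Event(n_pre + i * gap, "target", {"condition": CONDITIONS[i % 4]})
            )
        n = n_pre + 320 * gap + int(1.1 * fs) + 10
        rec = make_recording(np.zeros((2, n)), fs=fs, events=events)
        out = pp.epoch_events(rec, None, "target")
        assert out.n_epochs == 320
        tags = np.array(out.tags)
        assert all((tags == c).sum() == 80 for c in CONDITIONS)


class TestOcularCorrection:
    def test_blink_free_passthrough(self, fast_cfg):
        from dataclasses import replace
        from l2brain.synth import generate_resting_eeg

        cfg = replace(fast_cfg, artifact_rates={"blink": 0.0, "step": 0.0, "flat": 0.0})
        rec, _ = generate_resting_eeg(cfg, 0)
        out, report = pp.correct_ocular(rec)
        assert report["intervals"] == []
        for ch in range(rec.n_channels):
            r = np.corrcoef(rec.data[ch], out.data[ch])[0, 1]
            assert r > 0.99

    def test_blink_variance_halved_in_blink_windows(self, fast_cfg):
        from dataclasses import replace
        from l2brain.montage import frontal_channels
        from l2brain.synth import generate_resting_eeg

        cfg = replace(fast_cfg, artifact_rates={"blink": 12.0, "step": 0.0, "flat": 0.0})
        rec, gt = generate_resting_eeg(cfg, 1)
        out, report = pp.correct_ocular(rec)
        frontal = frontal_channels(cfg.montage())
        fidx = [rec.labels.index(lab) for lab in frontal]
        blink_len = int(0.4 * rec.fs)
        starts = sorted({s for _, s, kind in gt.artifact_log if kind == "blink"})
        assert starts, "expected logged blinks"
        sel = np.zeros(rec.n_samples, bool)
        for s in starts:
            sel[s : s + blink_len] = True
        var_before = rec.data[np.ix_(fidx, np.flatnonzero(sel))].var()
        var_after = out.data[np.ix_(fidx, np.flatnonzero(sel))].var()
        assert var_after <= 0.5 * var_before
        # untouched outside the windows the corrector itself acted on
        touched = np.zeros(rec.n_samples, bool)
        for s, e in report["intervals"]:
            touched[s:e] = True
        outside = np.flatnonzero(~touched)
        np.testing.assert_array_equal(out.data[:, outside], rec.data[:, outside])

    def test_deterministic(self, fast_cfg):
        from l2brain.synth import generate_resting_eeg

        rec, _ = generate_resting_eeg(fast_cfg, 0)
        a, _ = pp.correct_ocular(rec)
        b, _ = pp.correct_ocular(rec)
        np.testing.assert_array_equal(a.data, b.data)
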