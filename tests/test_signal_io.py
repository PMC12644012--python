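"""I/O, Butterworth preprocessing, and clinical windowing rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from szpipe._edf import write_edf
from szpipe.signal_io import (EegSegment, FilterSpec, SeizureAnnotation,
                              bandpass_filter, extract_ictal_windows,
                              extract_interictal_epochs, read_annotation_csv,
                              read_bonn_segment, read_edf_recording,
                              write_annotation_csv, write_bonn_segment)

FS = 256.0


def _seg(x, fs=FS, **kw):
    return EegSegment(np.atleast_2d(x), fs, **kw)


# ---------------------------------------------------------------------- Bonn


class TestBonnIO:
    def test_reads_4097_sample_segment_with_236s_duration(self, tmp_path, rng):
        p = tmp_path / "Z001.txt"
        write_bonn_segment(p, rng.normal(size=4097))
        seg = read_bonn_segment(p)
        assert seg.n_timepoints == 4097
        assert seg.n_channels == 1
        assert seg.label == "unlabeled"
        assert seg.duration_s == pytest.approx(23.6, abs=0.01)

    def test_identity_read_of_zero_samples(self, tmp_path):
        p = tmp_path / "z.txt"
        p.write_text("0\n0\n0\n")
        seg = read_bonn_segment(p)
        assert seg.samples.tolist() == [[0.0, 0.0, 0.0]]

    def test_parse_error_names_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1.5\nabc\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bonn_segment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_bonn_segment(p)

    def test_roundtrip_preserves_values(self, tmp_path, rng):
        x = rng.normal(size=100)
        p = tmp_path / "rt.txt"
        write_bonn_segment(p, x)
        assert np.allclose(read_bonn_segment(p).samples[0], x, atol=1e-6)


# ----------------------------------------------------------------------- EDF


class TestEdfIO:
    def test_multichannel_roundtrip(self, tmp_path, rng):
        names = [f"CH{i:02d}" for i in range(23)]
        x = rng.normal(scale=50, size=(23, int(FS) * 60))
        path = tmp_path / "rec.edf"
        write_edf(path, x, int(FS), names)
        seg = read_edf_recording(path)
        assert seg.samples.shape == (23, 15360)
        assert seg.fs == FS
        assert seg.channel_names == names
        # 16-bit quantization bounds the round-trip error
        assert np.abs(seg.samples - x).max() < 0.02

    def test_channel_subset_in_requested_order(self, tmp_path, rng):
        names = ["FP1-F7", "F7-T7", "T7-P7"]
        x = rng.normal(scale=20, size=(3, int(FS) * 2))
        path = tmp_path / "rec.edf"
        write_edf(path, x, int(FS), names)
        seg = read_edf_recording(path, channels=["T7-P7", "FP1-F7"])
        assert seg.channel_names == ["T7-P7", "FP1-F7"]
        assert seg.samples.shape == (2, int(FS) * 2)
        assert np.abs(seg.samples[0] - x[2]).max() < 0.01

    def test_missing_channel_error_lists_available(self, tmp_path, rng):
        x = rng.normal(size=(2, int(FS)))
        path = tmp_path / "rec.edf"
        write_edf(path, x, int(FS), ["A", "B"])
        with pytest.raises(ValueError, match="XX.*available|available"):
            read_edf_recording(path, channels=["XX"])


# -------------------------------------------------------------------- filter


def _analytic_bandpass_gain2(f, low, high, order, fs):
    """|H|^2 of the bilinear-designed Butterworth bandpass at frequency f."""
    warp = lambda g: 2 * fs * np.tan(np.pi * g / fs)
    w1, w2, w = warp(low), warp(high), warp(f)
    return 1.0 / (1.0 + ((w ** 2 - w1 * w2) / (w * (w2 - w1))) ** (2 * order))


def _steady_state_gain(f_hz, spec, dur=20.0, fs=FS):
    t = np.arange(int(fs * dur)) / fs
    x = np.sin(2 * np.pi * f_hz * t)
    out = bandpass_filter(_seg(x, fs), spec).samples[0]
    mid = out[int(5 * fs):int(15 * fs)]
    return np.sqrt(np.mean(mid ** 2)) / np.sqrt(0.5)


class TestBandpassFilter:
    def test_zero_input_gives_zero_output(self):
        seg = _seg(np.zeros(1024))
        out = bandpass_filter(seg, FilterSpec())
        assert np.allclose(out.samples, 0.0)

    def test_shape_fs_and_label_preserved(self, rng):
        seg = EegSegment(rng.normal(size=(3, 1024)), FS, label="ictal")
        out = bandpass_filter(seg, FilterSpec())
        assert out.samples.shape == (3, 1024)
        assert out.fs == FS and out.label == "ictal"

    def test_channels_filtered_independently(self, rng):
        x = rng.normal(size=(2, 1024))
        both = bandpass_filter(EegSegment(x, FS)).samples
        solo = bandpass_filter(EegSegment(x[:1], FS)).samples
        assert np.allclose(both[0], solo[0])

    def test_cutoff_gain_is_half_power(self):
        # |H|^2 = 1/2 at the designed cutoff for a single forward pass
        g = _steady_state_gain(60.0, FilterSpec(0.5, 60.0, 5, zero_phase=False))
        assert g == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_single_pass_stopband_matches_analytic_magnitude(self):
        g = _steady_state_gain(100.0, FilterSpec(0.5, 60.0, 5, zero_phase=False))
        expect = np.sqrt(_analytic_bandpass_gain2(100.0, 0.5, 60.0, 5, FS))
        assert g == pytest.approx(expect, rel=0.05)

    def test_zero_phase_squares_the_magnitude_response(self):
        g = _steady_state_gain(70.0, FilterSpec(0.5, 60.0, 5, zero_phase=True))
        expect = _analytic_bandpass_gain2(70.0, 0.5, 60.0, 5, FS)
        assert g == pytest.approx(expect, rel=0.05)

    def test_dc_attenuated_at_least_20db(self):
        seg = _seg(np.full(int(FS * 10), 7.5))
        out = bandpass_filter(seg, FilterSpec()).samples[0]
        assert np.sqrt(np.mean(out ** 2)) < 7.5 / 10  # -20 dB

    def test_high_cut_above_nyquist_rejected(self):
        seg = _seg(np.zeros(512), fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(seg, FilterSpec(0.5, 60.0))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(low_hz=10.0, high_hz=5.0)
        with pytest.raises(ValueError):
            FilterSpec(order=0)


# ----------------------------------------------------------------- windowing


def _recording(total_s, fs=16.0):
    n = int(total_s * fs)
    return EegSegment(np.zeros((1, n)), fs, origin="rec")


class TestIctalWindows:
    def test_ten_second_event_gives_nine_windows(self):
        rec = _recording(60)
        ann = SeizureAnnotation([(20.0, 30.0)], 60.0)
        wins = extract_ictal_windows(rec, ann)
        assert len(wins) == 9
        assert all(w.label == "ictal" and w.duration_s == 2.0 for w in wins)

    def test_event_shorter_than_window_yields_nothing(self):
        rec = _recording(60)
        ann = SeizureAnnotation([(10.0, 11.0)], 60.0)
        with pytest.warns(UserWarning, match="shorter"):
            assert extract_ictal_windows(rec, ann) == []

    def test_patient01_bookkeeping_435_windows_from_442_seconds(self):
        # 7 seizures with integer durations summing to 442 s -> sum(L-1) = 435
        durations = [50, 60, 70, 80, 90, 45, 47]
        assert sum(durations) == 442
        starts = np.cumsum([100] + [d + 100 for d in durations[:-1]])
        events = [(float(s), float(s + d)) for s, d in zip(starts, durations)]
        rec = _recording(1500)
        ann = SeizureAnnotation(events, 1500.0)
        assert len(extract_ictal_windows(rec, ann)) == 435

    def test_fractional_event_end_is_floored(self):
        rec = _recording(60)
        ann = SeizureAnnotation([(10.0, 15.7)], 60.0)  # floored to 5 s
        assert len(extract_ictal_windows(rec, ann)) == 4

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=12), min_size=1, max_size=6))
    def test_window_count_equals_sum_of_duration_minus_one(self, durations):
        gap = 20
        events, cursor = [], float(gap)
        for d in durations:
            if d > 0:
                events.append((cursor, cursor + d))
            cursor += d + gap
        rec = _recording(cursor + gap)
        ann = SeizureAnnotation(events, cursor + gap)
        expected = sum(d - 1 for d in durations if d >= 2)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert len(extract_ictal_windows(rec, ann)) == expected


class TestInterictalEpochs:
    def test_four_hour_gap_region_arithmetic(self):
        # 10-h recording, one 60-s seizure at 5 h, 4-h exclusion zone:
        # usable regions are [0, 1 h] and [9 h + 60 s, 10 h]
        rec = _recording(36000, fs=4.0)
        ann = SeizureAnnotation([(18000.0, 18060.0)], 36000.0)
        epochs = extract_interictal_epochs(rec, ann)
        assert len(epochs) == 3600 // 2 + (3600 - 60) // 2  # 1800 + 1770 = 3570
        assert all(e.label == "interictal" for e in epochs)

    def test_no_events_makes_whole_recording_eligible(self):
        rec = _recording(101)
        ann = SeizureAnnotation([], 101.0)
        assert len(extract_interictal_epochs(rec, ann)) == math.floor(101 / 2)

    def test_event_covering_recording_yields_nothing(self):
        rec = _recording(50)
        ann = SeizureAnnotation([(0.0, 50.0)], 50.0)
        with pytest.warns(UserWarning, match="no interictal region"):
            assert extract_interictal_epochs(rec, ann) == []

    def test_epochs_and_ictal_windows_disjoint_in_time(self):
        rec = _recording(4000)
        ann = SeizureAnnotation([(500.0, 540.0), (2000.0, 2025.0)], 4000.0)
        wins = extract_ictal_windows(rec, ann)
        epochs = extract_interictal_epochs(rec, ann, gap_s=100.0)
        assert wins and epochs

        def interval(seg):
            t0 = float(seg.origin.split("@")[1][:-1])
            return t0, t0 + seg.duration_s

        for w in wins:
            a0, a1 = interval(w)
            for e in epochs:
                b0, b1 = interval(e)
                assert a1 <= b0 or b1 <= a0


class TestAnnotations:
    def test_events_sorted_and_validated(self):
        ann = SeizureAnnotation([(30.0, 40.0), (5.0, 10.0)], 100.0)
        assert ann.events == [(5.0, 10.0), (30.0, 40.0)]
        with pytest.raises(ValueError, match="overlap"):
            SeizureAnnotation([(0.0, 10.0), (5.0, 15.0)], 100.0)
        with pytest.raises(ValueError, match="outside"):
            SeizureAnnotation([(90.0, 120.0)], 100.0)

    def test_csv_roundtrip(self, tmp_path):
        ann = SeizureAnnotation([(10.0, 20.0), (50.0, 55.0)], 100.0)
        p = tmp_path / "ann.csv"
        write_annotation_csv(p, ann, "rec1")
        back = read_annotation_csv(p, recording="rec1", recording_length_s=100.0)
        assert back.events == ann.events
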