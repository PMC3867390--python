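"""Spectrogram, element detection, measurement, segmentation, aggregation."""

import numpy as np
import pandas as pd
import pytest

from gibbonsong import acoustics
from gibbonsong.acoustics import (
    Contour, SpectrogramParams, aggregate_call, compute_spectrogram,
    extract_elements, extract_features, measure_element, segment_calls,
)


class TestSpectrogram:
    def test_resolution(self):
        p = SpectrogramParams()
        assert p.hop_s == pytest.approx(0.016)       # 16 ms
        assert p.bin_hz == pytest.approx(31.25)      # reported as 31 Hz

    def test_pure_tone_peak(self):
        t = np.arange(8000) / 8000.0
        wave = np.sin(2 * np.pi * 1000.0 * t)
        freqs, _, S = compute_spectrogram(wave)
        peak = freqs[S.mean(axis=1).argmax()]
        assert abs(peak - 1000.0) <= 31.25 / 2

    def test_resampling_input(self):
        t = np.arange(44100) / 44100.0
        wave = np.sin(2 * np.pi * 700.0 * t)
        freqs, _, S = compute_spectrogram(wave, input_rate=44100)
        peak = freqs[S.mean(axis=1).argmax()]
        assert abs(peak - 700.0) <= 31.25

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(np.array([]))

    @pytest.mark.parametrize("bad", [
        dict(fft_length=200), dict(overlap=1.0), dict(threshold_db=3.0)])
    def test_invalid_params(self, bad):
        with pytest.raises(ValueError):
            SpectrogramParams(**bad)


class TestExtractElements:
    def test_counts_match_truth_at_high_snr(self, clean_song):
        wave, elements = clean_song
        spec = compute_spectrogram(wave)
        contours = extract_elements(spec)
        assert len(contours) == len(elements)

    def test_silence_yields_empty(self, rng):
        wave = 1e-4 * rng.standard_normal(16000)
        wave[0] = 0.5  # a single click sets the recording peak
        contours = extract_elements(compute_spectrogram(wave))
        assert len(contours) <= 1  # nothing beyond the click frame(s)

    def test_threshold_monotonicity(self, clean_song):
        """Lowering the threshold never loses signal frames."""
        wave, _ = clean_song
        spec = compute_spectrogram(wave)
        counts = []
        for thr in (-5.0, -10.0, -15.0, -20.0):
            p = SpectrogramParams(threshold_db=thr)
            n_frames = sum(len(c.times) for c in extract_elements(spec, p))
            counts.append(n_frames)
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_contour_matches_truth_at_high_snr(self, clean_song):
        wave, elements = clean_song
        p = SpectrogramParams()
        contours = extract_elements(compute_spectrogram(wave), p)
        el = elements[0]
        c = contours[0]
        ct, cf = zip(*el.f0_contour)
        truth = np.interp(c.times, ct, cf)
        inside = (c.times > el.onset + 2 * p.hop_s) & \
                 (c.times < el.offset - 2 * p.hop_s)
        assert np.abs(c.freqs[inside] - truth[inside]).max() <= p.bin_hz


class TestMeasureElement:
    def test_hand_computed(self):
        m = measure_element(Contour(np.array([0.0, 0.1, 0.2]),
                                    np.array([700.0, 900.0, 950.0])))
        assert m.start_f0 == 700 and m.end_f0 == 950 and m.max_f0 == 950
        assert m.mean_f0 == pytest.approx(850.0)
        assert m.duration == pytest.approx(0.2)
        assert m.rel_location_max_f0 == pytest.approx(1.0)

    def test_flat_contour_tie_rule(self):
        m = measure_element(Contour(np.array([0.0, 0.1, 0.2]),
                                    np.array([800.0, 800.0, 800.0])))
        assert m.start_f0 == m.end_f0 == m.max_f0 == m.mean_f0 == 800.0
        assert m.rel_location_max_f0 == 0.0  # first attainment of the max

    def test_short_contour_discarded(self):
        assert measure_element(Contour(np.array([0.0]), np.array([700.0]))) is None

    def test_measures_match_truth(self, clean_song):
        """Round trip: truth -> audio -> spectrogram -> measures."""
        wave, elements = clean_song
        p = SpectrogramParams()
        contours = extract_elements(compute_spectrogram(wave), p)
        assert len(contours) == len(elements)
        dur_err, f0_err = [], []
        for c, e in zip(contours, elements):
            m = measure_element(c)
            dur_err.append(abs(m.duration - e.duration))
            f0_err.append(abs(m.max_f0 - e.max_f0))
        assert np.mean(dur_err) < 2 * p.hop_s
        assert np.median(f0_err) <= p.bin_hz


def _el(onset, offset):
    return acoustics.ElementMeasures(700, 900, 950, 800, offset - onset,
                                     0.8, onset, offset)


class TestSegmentCalls:
    def test_threshold_split(self):
        onsets = [0.0, 1.0, 2.0, 10.5, 11.5]
        els = [_el(o, o + 0.5) for o in onsets]  # gaps 0.5,0.5,8.0,0.5
        calls = segment_calls(els, max_gap=5.0)
        assert [len(c) for c in calls] == [3, 2]

    def test_singleton(self):
        calls = segment_calls([_el(0.0, 0.4)])
        assert len(calls) == 1
        assert calls[0][0].duration == pytest.approx(0.4)

    def test_call_counts_match_truth(self, clean_song):
        wave, elements = clean_song
        els, calls = extract_features(wave)
        assert calls["call_index"].nunique() == \
            len({e.call_index for e in elements})

    def test_interval_partition(self, clean_song):
        """Durations plus intervals tile the call span (within a hop)."""
        wave, _ = clean_song
        p = SpectrogramParams()
        _, calls = extract_features(wave, p)
        for _, row in calls.iterrows():
            if row["single_element"]:
                continue
            n = row["n_elements"]
            total = (n * row["mean_element_duration_s"]
                     + (n - 1) * row["mean_interval_duration_s"])
            assert total <= row["call_duration_s"] + p.hop_s


class TestAggregateCall:
    def test_hand_computed_blocks(self):
        els = [_el(0.0, 0.2), _el(1.0, 1.4), _el(2.0, 2.6)]
        calls = segment_calls(els)
        out = aggregate_call(calls[0])
        assert out["mean_element_duration_s"] == pytest.approx(0.4)
        assert out["max_element_duration_s"] == pytest.approx(0.6)
        assert out["var_element_duration_s"] == pytest.approx(0.2)

    def test_exactly_22_parameters(self):
        els = [_el(0.0, 0.2), _el(1.0, 1.4), _el(2.0, 2.6)]
        out = aggregate_call(segment_calls(els)[0])
        acoustic = [k for k in out
                    if k not in ("n_elements", "single_element", "call_index")]
        assert sorted(acoustic) == sorted(acoustics.FEATURE_COLUMNS)
        assert len(acoustic) == 22

    def test_identical_elements_zero_variation(self):
        els = [_el(i * 1.0, i * 1.0 + 0.3) for i in range(4)]
        out = aggregate_call(segment_calls(els)[0])
        for k in out:
            if k.startswith("var_"):
                assert out[k] == pytest.approx(0.0)

    def test_single_element_flagged_missing(self):
        out = aggregate_call([_el(0.0, 0.3)])
        assert out["single_element"]
        assert np.isnan(out["mean_interval_duration_s"])
        assert np.isnan(out["var_start_f0_hz"])

    def test_max_at_least_mean(self, clean_song):
        wave, _ = clean_song
        _, calls = extract_features(wave)
        for m in ("element_duration_s", "start_f0_hz", "max_f0_hz"):
            assert (calls[f"max_{m}"] >= calls[f"mean_{m}"] - 1e-9).all()
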