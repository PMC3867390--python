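"""Acoustic feature extraction for gibbon solo songs.

The pipeline mirrors classic bioacoustic practice for tonal calls whose
fundamental carries the highest amplitude: a Hamming-window spectrogram
(FFT 256 at 8 kHz -> 31.25 Hz bins, 16 ms hop at 50% overlap), an
amplitude threshold relative to the recording peak to separate signal
frames from noise, peak-frequency tracking within a configurable F0 band,
segmentation of signal-frame runs into elements and of element sequences
into calls, and aggregation into the 22 call-level parameters: call
duration plus {mean, maximum, variation} of 7 element measures (element
duration, interval duration, start F0, end F0, mean F0, max F0, relative
location of max F0).

"Variation" is the sample standard deviation of a measure across the
elements of a call (the coefficient of variation is available as an
option).  Single-element calls have no intervals and no within-call
variation; those entries are recorded as missing and the call is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

logger = logging.getLogger(__name__)

__all__ = [
    "SpectrogramParams",
    "ElementMeasures",
    "compute_spectrogram",
    "extract_elements",
    "measure_element",
    "segment_calls",
    "aggregate_call",
    "extract_features",
    "FEATURE_COLUMNS",
]

#: the seven per-element measures aggregated at call level
ELEMENT_MEASURES = (
    "element_duration_s",
    "interval_duration_s",
    "start_f0_hz",
    "end_f0_hz",
    "mean_f0_hz",
    "max_f0_hz",
    "loc_max_f0",
)

#: the 22 call-level acoustic parameter names
FEATURE_COLUMNS = ["call_duration_s"] + [
    f"{block}_{m}" for block in ("mean", "max", "var") for m in ELEMENT_MEASURES
]


@dataclass
class SpectrogramParams:
    fft_length: int = 256
    overlap: float = 0.5
    window: str = "hamming"
    sample_rate: int = 8000
    threshold_db: float = -12.8   # relative to recording peak
    f0_band: tuple = (100.0, 2000.0)

    def __post_init__(self):
        if self.fft_length < 2 or (self.fft_length & (self.fft_length - 1)):
            raise ValueError("fft_length must be a power of two")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if self.threshold_db >= 0:
            raise ValueError("threshold_db must be negative (dB re recording peak)")

    @property
    def hop_s(self) -> float:
        return self.fft_length * (1.0 - self.overlap) / self.sample_rate

    @property
    def bin_hz(self) -> float:
        return self.sample_rate / self.fft_length


@dataclass
class ElementMeasures:
    start_f0: float
    end_f0: float
    max_f0: float
    mean_f0: float
    duration: float
    rel_location_max_f0: float
    onset: float
    offset: float
    interval_to_next: float | None = None


@dataclass
class Contour:
    """Per-frame F0 track of one detected element."""
    times: np.ndarray
    freqs: np.ndarray


def _resample(waveform: np.ndarray, input_rate: int, target_rate: int) -> np.ndarray:
    from math import gcd
    g = gcd(int(input_rate), int(target_rate))
    return signal.resample_poly(waveform, target_rate // g, input_rate // g)


def compute_spectrogram(waveform, params: SpectrogramParams | None = None,
                        input_rate: int | None = None):
    """Magnitude spectrogram of a mono waveform.

    Returns ``(freqs, times, S)`` with ``S`` of shape (n_bins, n_frames).
    A waveform at a different rate is anti-alias resampled to
    ``params.sample_rate`` first.
    """
    params = params or SpectrogramParams()
    waveform = np.asarray(waveform, dtype=np.float64)
    if waveform.ndim != 1 or waveform.size == 0:
        raise ValueError("waveform must be a non-empty 1-D array")
    if input_rate is not None and input_rate != params.sample_rate:
        waveform = _resample(waveform, input_rate, params.sample_rate)
    noverlap = int(round(params.fft_length * params.overlap))
    freqs, times, S = signal.spectrogram(
        waveform, fs=params.sample_rate, window=params.window,
        nperseg=params.fft_length, noverlap=noverlap, mode="magnitude",
        detrend=False)
    return freqs, times, S


def extract_elements(spectrogram, params: SpectrogramParams | None = None):
    """Detect elements as maximal runs of signal frames; track F0 per frame.

    A frame is signal when its band-limited peak magnitude is within
    ``threshold_db`` dB of the recording's peak band-limited magnitude.
    Per frame the F0 is the frequency of the maximum-magnitude bin inside
    ``f0_band`` (valid where the fundamental carries the highest
    amplitude).  Returns a list of :class:`Contour`; an empty list (pure
    noise below threshold) is a valid result.
    """
    params = params or SpectrogramParams()
    freqs, times, S = spectrogram
    band = (freqs >= params.f0_band[0]) & (freqs <= params.f0_band[1])
    if not band.any():
        raise ValueError("f0_band contains no spectrogram bins")
    Sb = S[band]
    fb = freqs[band]
    peak_per_frame = Sb.max(axis=0)
    ref = peak_per_frame.max()
    if ref <= 0:
        return []
    with np.errstate(divide="ignore"):
        rel_db = 20.0 * np.log10(peak_per_frame / ref)
    is_signal = rel_db >= params.threshold_db
    f0 = fb[Sb.argmax(axis=0)]

    contours = []
    in_run = False
    start = 0
    for i, s in enumerate(np.append(is_signal, False)):
        if s and not in_run:
            in_run, start = True, i
        elif not s and in_run:
            in_run = False
            contours.append(Contour(times[start:i].copy(), f0[start:i].copy()))
    return contours


def measure_element(contour, min_frames: int = 2) -> ElementMeasures | None:
    """Summarize one F0 contour; ``None`` (discard) if shorter than
    ``min_frames`` frames (sub-resolution artifacts).

    Start/end F0 are the first/last frame's peak frequency, max F0 the
    maximum over frames (first attainment breaks ties for its temporal
    location), mean F0 the arithmetic mean, and the location of max F0 is
    expressed relative to the element duration (0 = onset, 1 = offset).
    """
    t = np.asarray(contour.times, dtype=float)
    f = np.asarray(contour.freqs, dtype=float)
    if len(t) < min_frames:
        logger.debug("discarding %d-frame contour (< %d frames)", len(t), min_frames)
        return None
    duration = float(t[-1] - t[0])
    imax = int(np.argmax(f))
    rel = float((t[imax] - t[0]) / duration) if duration > 0 else 0.0
    return ElementMeasures(
        start_f0=float(f[0]), end_f0=float(f[-1]), max_f0=float(f.max()),
        mean_f0=float(f.mean()), duration=duration,
        rel_location_max_f0=rel, onset=float(t[0]), offset=float(t[-1]))


def segment_calls(elements, max_gap: float = 5.0):
    """Group time-ordered elements into calls.

    Consecutive elements whose silent gap (next onset minus previous
    offset — the inter-element interval) is at most ``max_gap`` seconds
    belong to the same call.  Fills in ``interval_to_next`` for elements
    followed by another element of the same call.
    """
    calls = []
    current: list = []
    for el in elements:
        if current and (el.onset - current[-1].offset) > max_gap:
            calls.append(current)
            current = []
        if current:
            current[-1].interval_to_next = el.onset - current[-1].offset
        current.append(el)
    if current:
        calls.append(current)
    return calls


def _variation(values: np.ndarray, kind: str) -> float:
    sd = float(np.std(values, ddof=1))
    if kind == "cv":
        m = float(np.mean(values))
        return sd / m if m != 0 else np.nan
    return sd


def aggregate_call(call, variation: str = "sd") -> dict:
    """Aggregate one call's elements into the 22 acoustic parameters.

    Returns a dict with ``call_duration_s`` and, for each of the seven
    element measures, its mean, maximum and variation across the call's
    elements (intervals use the n-1 gaps between consecutive elements).
    A single-element call yields missing interval and variation entries
    and ``single_element=True``.
    """
    if len(call) < 1:
        raise ValueError("call must contain at least one element")
    out = {"call_duration_s": call[-1].offset - call[0].onset,
           "n_elements": len(call), "single_element": len(call) == 1}
    per_measure = {
        "element_duration_s": np.array([e.duration for e in call]),
        "interval_duration_s": np.array(
            [e.interval_to_next for e in call[:-1]], dtype=float),
        "start_f0_hz": np.array([e.start_f0 for e in call]),
        "end_f0_hz": np.array([e.end_f0 for e in call]),
        "mean_f0_hz": np.array([e.mean_f0 for e in call]),
        "max_f0_hz": np.array([e.max_f0 for e in call]),
        "loc_max_f0": np.array([e.rel_location_max_f0 for e in call]),
    }
    for name, vals in per_measure.items():
        if len(vals) == 0:
            out[f"mean_{name}"] = np.nan
            out[f"max_{name}"] = np.nan
            out[f"var_{name}"] = np.nan
            continue
        out[f"mean_{name}"] = float(np.mean(vals))
        out[f"max_{name}"] = float(np.max(vals))
        out[f"var_{name}"] = _variation(vals, variation) if len(vals) > 1 else np.nan
    return out


def extract_features(waveform, params: SpectrogramParams | None = None,
                     max_gap: float = 5.0, input_rate: int | None = None,
                     variation: str = "sd", min_frames: int = 2):
    """Full audio -> features chain for one recording.

    Returns ``(elements_df, calls_df)``: one row per retained element and
    one row per call carrying the 22 acoustic parameters.
    """
    params = params or SpectrogramParams()
    spec = compute_spectrogram(waveform, params, input_rate=input_rate)
    contours = extract_elements(spec, params)
    measures = [m for m in (measure_element(c, min_frames) for c in contours)
                if m is not None]
    n_discarded = len(contours) - len(measures)
    if n_discarded:
        logger.info("discarded %d sub-resolution contours", n_discarded)
    calls = segment_calls(measures, max_gap=max_gap)

    el_rows, call_rows = [], []
    for ci, call in enumerate(calls):
        for el in call:
            el_rows.append({
                "call_index": ci, "onset_s": el.onset, "offset_s": el.offset,
                "element_duration_s": el.duration,
                "interval_duration_s": el.interval_to_next,
                "start_f0_hz": el.start_f0, "end_f0_hz": el.end_f0,
                "mean_f0_hz": el.mean_f0, "max_f0_hz": el.max_f0,
                "loc_max_f0": el.rel_location_max_f0})
        row = aggregate_call(call, variation=variation)
        row["call_index"] = ci
        call_rows.append(row)
    return pd.DataFrame(el_rows), pd.DataFrame(call_rows)
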