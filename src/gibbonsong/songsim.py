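"""Synthetic gibbon solo-song generator with ground-truth annotations.

Every downstream stage of the package (feature extraction, factor
analysis, permuted DFA, hormone matching, mixed models) is exercised and
validated against data produced here, because no field recordings are
distributed.  The generator emulates a wild white-handed gibbon study
population: ~14 adult males across pair-living and unifemale/multimale
groups, each male singing solo songs composed of calls, each call a run
of frequency-modulated elements, with dated fecal androgen series whose
day-3 excretion value reflects the hormone level on the recording day.

Injected, recoverable structure:

* a between-male androgen -> pitch effect (``effect_androgen_pitch``,
  in SDs of baseline pitch per SD of log androgen level),
* an age effect on call duration (senior calls shorter by the factor
  ``effect_age_callduration``),
* an optional, smaller within-male day-level androgen -> pitch effect,
* day-scale temporal autocorrelation in the per-call pitch residuals,
  built by Gaussian-kernel smoothing of white noise with bandwidth
  ``ac_sigma_true`` days.

All randomness flows from a single integer seed; the same config yields
byte-identical tables and sample-identical waveforms.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "MaleProfile",
    "ElementTruth",
    "FecalSample",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_population",
    "synthesize_song",
    "simulate_androgen_series",
    "simulate_dataset",
    "simulate_call_features",
    "simulate_planted_factors",
    "simulate_glmm_dataset",
    "write_dataset",
    "read_dataset",
]

STUDY_START = date(2008, 10, 1)

# Population-scale acoustic anchors (start F0 median ~700 Hz in adults,
# end/max ~950 Hz, element durations a few hundred ms).
START_F0_MEAN = 700.0     # Hz, population mean of per-male baseline start F0
PITCH_SD_BETWEEN = 60.0   # Hz, between-male SD of baseline start F0
PITCH_SD_RESID = 15.0     # Hz, call-level pitch residual SD (autocorrelated)
ANDROGEN_LOG_MEDIAN = np.log(500.0)  # ng/g EA equivalents
ANDROGEN_LOG_SD = 0.5


class ConfigurationError(ValueError):
    pass


@dataclass
class MaleProfile:
    male_id: str
    group_id: str
    status: str          # pair_primary | multi_primary | secondary
    age_class: str       # adult | senior | subadult
    baseline_f0: float   # Hz, male's typical start F0
    androgen_mean: float  # ng/g, male's long-run mean fecal androgen
    androgen_sd: float   # ng/g, day-to-day SD around the mean
    n_recording_days: int

    def __post_init__(self):
        if not (400.0 <= self.baseline_f0 <= 1600.0):
            raise ValueError(f"baseline_f0 {self.baseline_f0} outside [400, 1600] Hz")
        if self.androgen_mean <= 0:
            raise ValueError("androgen_mean must be positive")


@dataclass
class ElementTruth:
    """Ground-truth annotation of one frequency-modulated element."""

    onset: float
    offset: float
    f0_contour: list  # [(time_s, freq_hz), ...] with times inside [onset, offset]
    call_index: int
    song_index: int

    def __post_init__(self):
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def start_f0(self) -> float:
        return self.f0_contour[0][1]

    @property
    def end_f0(self) -> float:
        return self.f0_contour[-1][1]

    @property
    def max_f0(self) -> float:
        return max(f for _, f in self.f0_contour)


@dataclass
class FecalSample:
    male_id: str
    collection_date: date
    androgen: float  # ng/g EA equivalents

    def __post_init__(self):
        if self.androgen <= 0:
            raise ValueError("androgen must be positive")


@dataclass
class SimulationConfig:
    n_males: int = 14
    effect_androgen_pitch: float = 0.5   # SD of pitch per SD of log androgen, between males
    effect_androgen_within: float = 0.1  # same units, day-level within-male effect
    effect_age_callduration: float = 0.8  # multiplicative factor on senior element/interval durations
    ac_sigma_true: float = 2.0           # days, bandwidth of injected residual autocorrelation
    snr_db: float = 30.0
    seed: int = 0
    study_span: int = 180                # days
    sample_rate: int = 8000
    songs_per_day: int = 1
    calls_per_song: tuple = (8, 18)      # uniform integer range, inclusive low, exclusive high
    elements_per_call: tuple = (3, 51)
    samples_per_male: tuple = (5, 30)    # fecal sample count range
    day3_coverage: float = 0.95          # fraction of recording days given an in-window sample

    def __post_init__(self):
        if self.n_males < 2:
            raise ConfigurationError("n_males must be at least 2")
        for name in ("effect_androgen_pitch", "effect_androgen_within",
                     "effect_age_callduration", "ac_sigma_true", "snr_db"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


def _child_rng(seed: int, *offsets: int) -> np.random.Generator:
    """Derive an independent generator from the master seed and a stage tag."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *offsets]))


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def simulate_population(config: SimulationConfig):
    """Draw male profiles and a group assignment table.

    Returns ``(profiles, groups)`` where ``groups`` is a DataFrame with one
    row per male (male_id, group_id, status, age_class).  Composition
    emulates the analysed study population: mostly pair-living primary
    males plus a handful of secondary males concentrated in a few
    unifemale/multimale units, with adult, senior and (for n >= 10)
    subadult age classes all represented.
    """
    rng = _child_rng(config.seed, 1)
    n = config.n_males

    n_secondary = 0 if n < 6 else max(1, round(n * 5 / 14))
    n_multi_groups = min(4, n_secondary) if n_secondary else 0
    n_multi_primary = n_multi_groups
    n_pair = n - n_secondary - n_multi_primary
    if n_pair < 1:  # tiny populations: keep at least one pair-living male
        n_pair, n_secondary, n_multi_primary, n_multi_groups = 1, n - 2, 1, 1

    statuses = (["pair_primary"] * n_pair
                + ["multi_primary"] * n_multi_primary
                + ["secondary"] * n_secondary)

    # age classes: mostly adult, some senior, a couple of subadults
    n_subadult = round(0.15 * n) if n >= 10 else 0
    n_senior = max(1, round(0.2 * (n - n_subadult))) if n - n_subadult >= 3 else 0
    ages = ["adult"] * (n - n_subadult - n_senior) + ["senior"] * n_senior \
        + ["subadult"] * n_subadult
    ages = list(rng.permutation(ages))

    log_a = ANDROGEN_LOG_MEDIAN + ANDROGEN_LOG_SD * rng.standard_normal(n)
    z_a = (log_a - ANDROGEN_LOG_MEDIAN) / ANDROGEN_LOG_SD
    eff = config.effect_androgen_pitch
    resid_scale = np.sqrt(max(0.0, 1.0 - min(eff * eff, 1.0)))
    baseline = START_F0_MEAN + PITCH_SD_BETWEEN * (
        eff * z_a + resid_scale * rng.standard_normal(n))
    baseline = np.clip(baseline, 420.0, 1550.0)

    profiles, rows = [], []
    multi_group_ids = [f"M{i+1}" for i in range(n_multi_groups)]
    pair_counter = 0
    sec_counter = 0
    for i in range(n):
        status = statuses[i]
        if status == "pair_primary":
            group_id = f"P{pair_counter + 1}"
            pair_counter += 1
        elif status == "multi_primary":
            group_id = multi_group_ids[i - n_pair]
        else:
            group_id = multi_group_ids[sec_counter % n_multi_groups]
            sec_counter += 1
        a_mean = float(np.exp(log_a[i]))
        profile = MaleProfile(
            male_id=f"male_{i+1:02d}",
            group_id=group_id,
            status=status,
            age_class=ages[i],
            baseline_f0=float(baseline[i]),
            androgen_mean=a_mean,
            androgen_sd=0.35 * a_mean,
            n_recording_days=int(rng.integers(2, 5)),
        )
        profiles.append(profile)
        rows.append({"male_id": profile.male_id, "group_id": group_id,
                     "status": status, "age_class": profile.age_class})
    groups = pd.DataFrame(rows)
    return profiles, groups


# ---------------------------------------------------------------------------
# song truth and waveform synthesis
# ---------------------------------------------------------------------------

def _element_contour(start_f0, max_f0, end_f0, onset, duration, n_points=25,
                     rel_max=0.85):
    """Smooth rising F0 contour peaking late in the element.

    Monotone half-cosine rise from start to max over [0, rel_max], then an
    easing from max down to end over the final stretch (end ~ max), so
    start F0 < end F0 <= max F0.
    """
    u = np.linspace(0.0, 1.0, n_points)
    f = np.empty_like(u)
    rise = u <= rel_max
    f[rise] = start_f0 + (max_f0 - start_f0) * 0.5 * (
        1 - np.cos(np.pi * u[rise] / rel_max))
    tail = ~rise
    v = (u[tail] - rel_max) / (1.0 - rel_max)
    f[tail] = max_f0 + (end_f0 - max_f0) * 0.5 * (1 - np.cos(np.pi * v))
    times = onset + u * duration
    return list(zip(times.tolist(), f.tolist()))


def _draw_call_elements(rng, call_pitch, n_elements, dur_scale, onset0,
                        song_index, call_index):
    """Draw per-element truth for one call; returns (elements, call_offset)."""
    elements = []
    t = onset0
    for j in range(n_elements):
        start = call_pitch * float(np.exp(0.04 * rng.standard_normal()))
        mx = start * float(rng.uniform(1.25, 1.45))
        end = mx * float(rng.uniform(0.94, 0.999))
        dur = float(np.clip(np.exp(rng.normal(np.log(0.30), 0.45)), 0.08, 2.0)) * dur_scale
        elements.append(ElementTruth(
            onset=t, offset=t + dur,
            f0_contour=_element_contour(start, mx, end, t, dur),
            call_index=call_index, song_index=song_index))
        if j < n_elements - 1:
            gap = float(np.clip(np.exp(rng.normal(np.log(0.5), 0.5)), 0.08, 4.4)) * dur_scale
            t = t + dur + gap
        else:
            t = t + dur
    return elements, t


def _gaussian_smoothed_noise(times, sigma, rng):
    """Unit-variance noise with Gaussian-kernel temporal autocorrelation."""
    times = np.asarray(times, dtype=float)
    g = rng.standard_normal(len(times))
    if sigma <= 0:
        return g
    w = np.exp(-((times[:, None] - times[None, :]) ** 2) / (2.0 * sigma ** 2))
    norm = np.sqrt((w ** 2).sum(axis=1))
    return (w @ g) / norm


def _render_waveform(elements, total_duration, snr_db, sample_rate, rng):
    """Render FM-tone elements plus broadband noise; int16-quantized floats."""
    n = int(np.ceil(total_duration * sample_rate)) + 1
    wave = np.zeros(n)
    taper = 0.005  # s, raised-cosine edges against clicks
    for el in elements:
        i0 = int(round(el.onset * sample_rate))
        i1 = int(round(el.offset * sample_rate))
        if i1 <= i0 + 1:
            continue
        tt = np.arange(i1 - i0) / sample_rate
        ct, cf = zip(*el.f0_contour)
        f_inst = np.interp(tt + el.onset, ct, cf)
        phase = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate
        seg = np.sin(phase)
        nt = max(2, int(taper * sample_rate))
        env = np.ones_like(seg)
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nt) / nt))
        env[:nt] *= ramp
        env[-nt:] *= ramp[::-1]
        wave[i0:i1] += 0.7 * seg * env
    voiced = np.abs(wave) > 1e-6
    sig_rms = np.sqrt(np.mean(wave[voiced] ** 2)) if voiced.any() else 1.0
    noise_sd = sig_rms * 10.0 ** (-snr_db / 20.0)
    wave = wave + noise_sd * rng.standard_normal(n)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave / (1.05 * peak)
    # quantize so in-memory waveform == WAV round-trip
    return np.round(wave * 32767.0).astype(np.int16).astype(np.float64) / 32767.0


def synthesize_song(profile: MaleProfile, n_calls: int, seed: int,
                    config: SimulationConfig | None = None,
                    call_pitches=None, song_index: int = 0):
    """Synthesize one solo song: (waveform, elements) at 8 kHz mono.

    ``call_pitches`` optionally fixes the per-call pitch anchor (Hz); by
    default each call sits at the male's baseline F0 with small jitter.
    """
    if n_calls < 1:
        raise ConfigurationError("n_calls must be >= 1")
    cfg = config or SimulationConfig(seed=seed)
    rng = _child_rng(seed, 7, song_index)
    dur_scale = cfg.effect_age_callduration if profile.age_class == "senior" else \
        (1.4 if profile.age_class == "subadult" else 1.0)
    elements = []
    t = 0.5
    for c in range(n_calls):
        pitch = (call_pitches[c] if call_pitches is not None
                 else profile.baseline_f0 * float(np.exp(0.02 * rng.standard_normal())))
        n_el = int(np.clip(round(np.exp(rng.normal(np.log(9.0), 0.45))),
                           cfg.elements_per_call[0], cfg.elements_per_call[1] - 1))
        els, t_end = _draw_call_elements(rng, pitch, n_el, dur_scale, t,
                                         song_index, c)
        elements.extend(els)
        t = t_end + float(rng.uniform(6.0, 15.0))
    total = elements[-1].offset + 0.5
    wave = _render_waveform(elements, total, cfg.snr_db, cfg.sample_rate, rng)
    return wave, elements


# ---------------------------------------------------------------------------
# androgens
# ---------------------------------------------------------------------------

def _day_level(profile: MaleProfile, z: float) -> float:
    """Day-level androgen given a standard-normal day deviate.

    Log-normal around the male mean with the male's CV, parameterized so
    the expectation equals ``androgen_mean`` exactly (and collapses to it
    when ``androgen_sd`` is zero).
    """
    if profile.androgen_sd == 0:
        return profile.androgen_mean
    cv = profile.androgen_sd / profile.androgen_mean
    s2 = np.log1p(cv * cv)
    return float(profile.androgen_mean * np.exp(np.sqrt(s2) * z - s2 / 2.0))


def simulate_androgen_series(profile: MaleProfile, recording_days, seed: int,
                             day_levels: dict | None = None,
                             coverage: float = 0.95,
                             n_extra: int | None = None):
    """Dated fecal samples for one male.

    For all but a deterministic ~``1 - coverage`` fraction of recording
    days, a sample is placed exactly 3 days after the recording carrying
    the androgen level that drove that day's songs (the excretion-lag
    construction the matcher must invert).  Extra samples on unrelated
    days pad the series into the realistic 5-29 per male range.
    """
    if len(recording_days) == 0:
        raise ConfigurationError("recording_days must be non-empty")
    rng = _child_rng(seed, 11)
    recording_days = sorted(recording_days)
    n_days = len(recording_days)
    n_skip = int((1.0 - coverage) * n_days)  # floor => coverage guaranteed
    skip = set(rng.choice(n_days, size=n_skip, replace=False).tolist()) if n_skip else set()

    samples = []
    for i, d in enumerate(recording_days):
        if i in skip:
            continue
        level = (day_levels or {}).get(d)
        if level is None:
            level = _day_level(profile, float(rng.standard_normal()))
        samples.append(FecalSample(profile.male_id, d + timedelta(days=3), level))

    if n_extra is None:
        lo, hi = 5, 30
        n_extra = max(0, int(rng.integers(lo, hi)) - len(samples))
    span_lo = recording_days[0] - timedelta(days=20)
    used = {s.collection_date for s in samples}
    in_window = set()
    for d in recording_days:
        for k in range(0, 8):
            in_window.add(d + timedelta(days=k))
    placed = 0
    attempts = 0
    while placed < n_extra and attempts < 50 * (n_extra + 1):
        attempts += 1
        cand = span_lo + timedelta(days=int(rng.integers(0, 240)))
        if cand in used or cand in in_window:
            continue  # keep the matcher's day-3 construction unambiguous
        used.add(cand)
        samples.append(FecalSample(
            profile.male_id, cand,
            _day_level(profile, float(rng.standard_normal()))))
        placed += 1
    samples.sort(key=lambda s: s.collection_date)
    return samples


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    profiles: list
    groups: pd.DataFrame
    males: pd.DataFrame
    songs: pd.DataFrame
    calls: pd.DataFrame       # per-call truth incl. injected pitch
    elements: pd.DataFrame    # per-element truth table
    fecal_samples: pd.DataFrame
    waveforms: dict = field(default_factory=dict)  # song_id -> float array


def simulate_dataset(config: SimulationConfig, synth_audio: bool = True) -> SimulatedDataset:
    """Run the whole generator: population, songs, waveforms, hormone series."""
    profiles, groups = simulate_population(config)
    rng = _child_rng(config.seed, 3)

    song_rows, call_rows, el_rows, fecal_rows = [], [], [], []
    waveforms = {}
    song_counter = 0
    for im, profile in enumerate(profiles):
        # recording days cluster in a short burst per male (field teams
        # follow a group for a stretch), so day lags span ac_sigma_true
        window = max(14, profile.n_recording_days)
        start = int(rng.integers(0, max(1, config.study_span - window)))
        days = start + np.sort(rng.choice(window, size=profile.n_recording_days,
                                          replace=False))
        rec_dates = [STUDY_START + timedelta(days=int(d)) for d in days]
        # day-level androgen (drives within-male pitch + the day-3 fecal value)
        day_z = rng.standard_normal(len(rec_dates))
        day_levels = {d: _day_level(profile, float(z))
                      for d, z in zip(rec_dates, day_z)}

        # lay out call times for all this male's songs, then one smoothed
        # residual process across them (day-scale autocorrelation)
        male_calls = []  # (date, day_float_time, song_local_idx, call_idx_in_song)
        for sidx, (d, doff) in enumerate(zip(rec_dates, days)):
            n_calls = int(rng.integers(*config.calls_per_song))
            start_hour = 6.0 + float(rng.uniform(0, 2))
            t_day = float(doff) + start_hour / 24.0
            for c in range(n_calls):
                male_calls.append([d, t_day, sidx, c])
                t_day += float(rng.uniform(15.0, 45.0)) / 86400.0
        times = np.array([mc[1] for mc in male_calls])
        resid = PITCH_SD_RESID * _gaussian_smoothed_noise(times, config.ac_sigma_true, rng)

        within = config.effect_androgen_within * PITCH_SD_BETWEEN
        pitch_by_call = []
        for (d, t, sidx, c), r in zip(male_calls, resid):
            zday = (np.log(day_levels[d] / profile.androgen_mean)
                    / ANDROGEN_LOG_SD) if profile.androgen_sd > 0 else 0.0
            pitch_by_call.append(profile.baseline_f0 + within * zday + r)

        # synthesize per-song
        call_ptr = 0
        for sidx, (d, doff) in enumerate(zip(rec_dates, days)):
            n_calls = sum(1 for mc in male_calls if mc[2] == sidx)
            pitches = pitch_by_call[call_ptr:call_ptr + n_calls]
            song_id = f"song_{song_counter + 1:03d}"
            seed_s = int(config.seed) * 100003 + song_counter
            if synth_audio:
                wave, els = synthesize_song(profile, n_calls, seed_s, config,
                                            call_pitches=pitches, song_index=song_counter)
                waveforms[song_id] = wave
            else:
                _, els = _truth_only_song(profile, n_calls, seed_s, config,
                                          pitches, song_counter)
            song_rows.append({
                "song_id": song_id, "male_id": profile.male_id,
                "group_id": profile.group_id, "recording_date": d.isoformat(),
                "n_calls": n_calls})
            by_call = {}
            for el in els:
                by_call.setdefault(el.call_index, []).append(el)
                el_rows.append({
                    "song_id": song_id, "male_id": profile.male_id,
                    "call_index": el.call_index, "onset_s": el.onset,
                    "offset_s": el.offset, "start_f0_hz": el.start_f0,
                    "end_f0_hz": el.end_f0, "max_f0_hz": el.max_f0})
            for c in sorted(by_call):
                cels = by_call[c]
                call_rows.append({
                    "song_id": song_id, "male_id": profile.male_id,
                    "call_id": f"{song_id}_c{c:03d}",
                    "recording_date": d.isoformat(),
                    "time_days": male_calls[call_ptr + c][1],
                    "n_elements": len(cels),
                    "call_duration_s": cels[-1].offset - cels[0].onset,
                    "pitch_true_hz": pitches[c]})
            call_ptr += n_calls
            song_counter += 1

        for s in simulate_androgen_series(
                profile, rec_dates, int(config.seed) * 7919 + im,
                day_levels=day_levels, coverage=config.day3_coverage):
            fecal_rows.append({"male_id": s.male_id,
                               "collection_date": s.collection_date.isoformat(),
                               "androgen_ng_g": s.androgen})

    males = pd.DataFrame([{**asdict(p)} for p in profiles])
    return SimulatedDataset(
        config=config, profiles=profiles, groups=groups, males=males,
        songs=pd.DataFrame(song_rows), calls=pd.DataFrame(call_rows),
        elements=pd.DataFrame(el_rows), fecal_samples=pd.DataFrame(fecal_rows),
        waveforms=waveforms)


def _truth_only_song(profile, n_calls, seed, cfg, call_pitches, song_index):
    """Element truth without rendering audio (fast path for large sims)."""
    rng = _child_rng(seed, 7, song_index)
    dur_scale = cfg.effect_age_callduration if profile.age_class == "senior" else \
        (1.4 if profile.age_class == "subadult" else 1.0)
    elements = []
    t = 0.5
    for c in range(n_calls):
        pitch = (call_pitches[c] if call_pitches is not None
                 else profile.baseline_f0 * float(np.exp(0.02 * rng.standard_normal())))
        n_el = int(np.clip(round(np.exp(rng.normal(np.log(9.0), 0.45))),
                           cfg.elements_per_call[0], cfg.elements_per_call[1] - 1))
        els, t_end = _draw_call_elements(rng, pitch, n_el, dur_scale, t,
                                         song_index, c)
        elements.extend(els)
        t = t_end + float(rng.uniform(6.0, 15.0))
    return None, elements


# ---------------------------------------------------------------------------
# focused generators for statistical-stage validation
# ---------------------------------------------------------------------------

def simulate_call_features(n_males=10, calls_per_male=30, n_days=3,
                           separation=5.0, n_features=22, day_sd=0.0,
                           seed=0):
    """Call-level feature table with controllable between-male separation.

    Male centroids sit on scaled coordinate axes so every pair of males is
    ``separation * sqrt(2)`` apart in units of the within-male SD (1.0).
    ``day_sd`` adds a shared day-level random offset to every call from
    the same (male, day) block — the non-independence that day-wise
    permutation must respect.  ``separation=0`` gives pure noise.
    """
    rng = _child_rng(seed, 21)
    rows = []
    for m in range(n_males):
        centroid = np.zeros(n_features)
        centroid[m % n_features] = separation
        for d in range(n_days):
            day_shift = day_sd * rng.standard_normal(n_features)
            n_calls_day = calls_per_male // n_days + (1 if d < calls_per_male % n_days else 0)
            for _ in range(n_calls_day):
                x = centroid + day_shift + rng.standard_normal(n_features)
                rows.append({"male_id": f"male_{m+1:02d}",
                             "recording_day": f"d{d+1}",
                             **{f"f{k+1}": x[k] for k in range(n_features)}})
    return pd.DataFrame(rows)


def simulate_planted_factors(n_rows=600, n_factors=6, noise_sd=0.15,
                             n_variables=22, seed=0):
    """Table of ``n_variables`` built from ``n_factors`` orthogonal latents.

    Returns ``(table, latents)``; each variable equals one latent plus
    independent noise, so a correctly working factor analysis retains
    exactly ``n_factors`` factors and loads each variable on its
    generating latent.
    """
    rng = _child_rng(seed, 23)
    latents = rng.standard_normal((n_rows, n_factors))
    assign = np.arange(n_variables) % n_factors
    cols = {}
    for v in range(n_variables):
        cols[f"v{v+1}"] = latents[:, assign[v]] + noise_sd * rng.standard_normal(n_rows)
    return pd.DataFrame(cols), pd.DataFrame(
        latents, columns=[f"latent_{k+1}" for k in range(n_factors)])


def simulate_glmm_dataset(n_males=12, days_per_male=4, calls_per_day=10,
                          day_window=10,
                          effect_androgen_between=0.5, effect_androgen_within=0.0,
                          effect_age=0.0, effect_status=0.0,
                          ac_sigma=0.0, ac_share=0.5, resid_sd=1.0,
                          male_sd=0.5, day_sd=0.3, song_sd=0.2, group_sd=0.2,
                          slope_sd=0.0, seed=0, n_groups=None,
                          outlier_male=None, outlier_shift=0.0):
    """Observation table for mixed-model validation, no audio involved.

    The response is a factor-score-like variable built from known fixed
    effects (between/within androgen, age, status), nested random effects
    (group > male > date > song) and optionally Gaussian-kernel
    autocorrelated residuals with bandwidth ``ac_sigma`` days;
    ``ac_share`` is the fraction of residual variance carried by the
    smooth (autocorrelated) component, the rest being white measurement
    noise.
    """
    rng = _child_rng(seed, 29)
    rows = []
    if n_groups is None:
        n_groups = max(2, n_males // 2)
    group_effects: dict = {}
    for m in range(n_males):
        male = f"male_{m+1:02d}"
        grp = f"grp_{m % n_groups + 1:02d}"
        age = "senior" if m % 4 == 3 else "adult"
        status = ["pair_primary", "multi_primary", "secondary"][m % 3]
        a_between = rng.standard_normal()
        u_male = male_sd * rng.standard_normal()
        u_slope = slope_sd * rng.standard_normal()
        # each male is followed over a burst of nearby days (field teams work
        # a group for a stretch), so day lags span the scale of ac_sigma
        window = max(day_window, days_per_male)
        start = float(rng.integers(0, 120))
        days = start + np.sort(
            rng.choice(window, size=days_per_male, replace=False)).astype(float)
        times, metas = [], []
        for di, d in enumerate(days):
            u_day = day_sd * rng.standard_normal()
            a_within = rng.standard_normal()
            u_song = song_sd * rng.standard_normal()
            t0 = d + 0.27
            for c in range(calls_per_day):
                times.append(t0 + c * 30.0 / 86400.0)
                metas.append((di, d, u_day, a_within, u_song))
        times = np.asarray(times)
        if ac_sigma > 0:
            smooth = _gaussian_smoothed_noise(times, ac_sigma, rng)
            white = rng.standard_normal(len(times))
            eps = resid_sd * (np.sqrt(ac_share) * smooth
                              + np.sqrt(1.0 - ac_share) * white)
        else:
            eps = resid_sd * rng.standard_normal(len(times))
        group_effects.setdefault(grp, group_sd * rng.standard_normal())
        for (di, d, u_day, a_within, u_song), t, e in zip(metas, times, eps):
            y = (effect_androgen_between * a_between
                 + (effect_androgen_within + u_slope) * a_within
                 + (effect_age if age == "senior" else 0.0)
                 + (effect_status if status != "pair_primary" else 0.0)
                 + group_effects[grp] + u_male + u_day + u_song + e)
            if outlier_male is not None and m == outlier_male:
                y += outlier_shift
            rows.append({"male_id": male, "group_id": grp, "age_class": age,
                         "status": status, "date": f"{male}_day{di}",
                         "song_id": f"{male}_song{di}", "time_days": t,
                         "androgen_between": a_between,
                         "androgen_within": a_within, "response": y})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

#: attribute -> CSV file name (truth tables carry an explicit suffix so
#: they cannot be confused with the extracted-feature tables)
_TABLES = {"males": "males.csv", "groups": "groups.csv",
           "songs": "songs.csv", "calls": "calls_truth.csv",
           "elements": "elements_truth.csv",
           "fecal_samples": "fecal_samples.csv"}


def write_dataset(dataset: SimulatedDataset, out_dir) -> list:
    """Write the dataset to ``out_dir``: CSV tables + one WAV per song."""
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, fname in _TABLES.items():
        path = os.path.join(out_dir, fname)
        getattr(dataset, name).to_csv(path, index=False)
        written.append(path)
    wav_dir = os.path.join(out_dir, "audio")
    if dataset.waveforms:
        os.makedirs(wav_dir, exist_ok=True)
    for song_id, wave in dataset.waveforms.items():
        path = os.path.join(wav_dir, f"{song_id}.wav")
        wavfile.write(path, dataset.config.sample_rate,
                      np.round(wave * 32767.0).astype(np.int16))
        written.append(path)
    cfg_path = os.path.join(out_dir, "config.json")
    pd.Series(asdict(dataset.config)).to_json(cfg_path)
    written.append(cfg_path)
    return written


def read_dataset(out_dir) -> SimulatedDataset:
    """Re-read a written dataset; inverse of :func:`write_dataset`."""
    import json
    with open(os.path.join(out_dir, "config.json")) as fh:
        raw = json.load(fh)
    for key in ("calls_per_song", "elements_per_call", "samples_per_male"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    config = SimulationConfig(**raw)
    tables = {name: pd.read_csv(os.path.join(out_dir, fname))
              for name, fname in _TABLES.items()}
    profiles = [MaleProfile(**{k: row[k] for k in (
        "male_id", "group_id", "status", "age_class", "baseline_f0",
        "androgen_mean", "androgen_sd", "n_recording_days")})
        for _, row in tables["males"].iterrows()]
    waveforms = {}
    wav_dir = os.path.join(out_dir, "audio")
    if os.path.isdir(wav_dir):
        for fn in sorted(os.listdir(wav_dir)):
            if fn.endswith(".wav"):
                _, data = wavfile.read(os.path.join(wav_dir, fn))
                waveforms[fn[:-4]] = data.astype(np.float64) / 32767.0
    return SimulatedDataset(config=config, profiles=profiles,
                            groups=tables["groups"], males=tables["males"],
                            songs=tables["songs"], calls=tables["calls"],
                            elements=tables["elements"],
                            fecal_samples=tables["fecal_samples"],
                            waveforms=waveforms)
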