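"""Matching fecal androgen measurements to song recordings.

Steroid metabolites appear in gibbon feces with a delay; a sample
collected ~3 days after a recording best reflects the circulating
androgen level on the recording day.  The matcher therefore considers
samples collected between the recording day and 7 days later, picks those
closest to the optimal day-3 lag, and averages when several samples tie
at the minimal distance.  Recordings with no in-window sample yield no
match and are excluded downstream (never imputed).

Lag distance is counted in calendar days, ignoring time of day: samples
are collected during daylight hours and songs around dawn, so sub-day
precision is unavailable.

Matched values are then z-transformed over all observations and split by
within-subject centering into a between-male term (the male's mean
z-value, constant within male) and a within-male term (deviation from
that mean), which separates effects of a male's overall hormone level
from effects of its short-term fluctuations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedAndrogen",
    "match_samples",
    "match_recordings",
    "center_androgens",
    "lag_distribution",
]

OPTIMAL_LAG = 3
MAX_LAG = 7


class DataError(ValueError):
    pass


@dataclass
class MatchedAndrogen:
    raw_value: float          # ng/g (mean over tied samples)
    lag_days: int             # lag of the matched sample (smallest among ties)
    n_samples_averaged: int


def _as_date(x):
    return pd.Timestamp(x).normalize()


def match_samples(recording_date, samples: pd.DataFrame,
                  date_col: str = "collection_date",
                  value_col: str = "androgen_ng_g") -> MatchedAndrogen | None:
    """Match one recording date against one male's dated samples.

    Among samples with lag in [0, 7] days, those minimizing |lag - 3| are
    selected; ties at the minimal distance are averaged.  Returns ``None``
    when no sample falls in the window.  Order-independent and idempotent.
    """
    if len(samples) == 0:
        return None
    rec = _as_date(recording_date)
    lags = np.array([( _as_date(d) - rec).days for d in samples[date_col]])
    in_window = (lags >= 0) & (lags <= MAX_LAG)
    if not in_window.any():
        return None
    lags_w = lags[in_window]
    vals_w = samples.loc[in_window, value_col].to_numpy(dtype=float)
    dist = np.abs(lags_w - OPTIMAL_LAG)
    best = dist == dist.min()
    return MatchedAndrogen(
        raw_value=float(vals_w[best].mean()),
        lag_days=int(lags_w[best].min()),
        n_samples_averaged=int(best.sum()))


def match_recordings(songs: pd.DataFrame, fecal_samples: pd.DataFrame,
                     male_col: str = "male_id",
                     rec_date_col: str = "recording_date") -> pd.DataFrame:
    """Match every song/recording row to its androgen value.

    Returns ``songs`` with ``androgen_ng_g``, ``lag_days`` and
    ``n_samples_averaged`` columns; unmatched rows keep NaN and are
    counted in the log.
    """
    out = songs.copy()
    values, lags, ns = [], [], []
    by_male = dict(tuple(fecal_samples.groupby(male_col)))
    for _, row in songs.iterrows():
        sub = by_male.get(row[male_col])
        m = match_samples(row[rec_date_col], sub) if sub is not None else None
        if m is None:
            values.append(np.nan), lags.append(np.nan), ns.append(0)
        else:
            values.append(m.raw_value), lags.append(m.lag_days), ns.append(m.n_samples_averaged)
    out["androgen_ng_g"] = values
    out["lag_days"] = lags
    out["n_samples_averaged"] = ns
    n_miss = int(out["androgen_ng_g"].isna().sum())
    if n_miss:
        logger.info("%d recordings without an in-window fecal sample "
                    "(excluded downstream)", n_miss)
    return out


def center_androgens(matched: pd.DataFrame, male_col: str = "male_id",
                     value_col: str = "androgen_ng_g") -> pd.DataFrame:
    """Global z-transform followed by within-subject centering.

    Adds ``androgen_z`` (mean 0, SD 1 over non-missing observations),
    ``androgen_between`` (the male's mean z-value) and ``androgen_within``
    (z minus male mean), so between + within = z exactly.
    """
    out = matched.copy()
    vals = out[value_col].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if ok.sum() < 2 or np.nanstd(vals) == 0:
        raise DataError("need >= 2 distinct androgen values to z-transform")
    z = np.full_like(vals, np.nan)
    z[ok] = (vals[ok] - vals[ok].mean()) / vals[ok].std(ddof=0)
    out["androgen_z"] = z
    between = out.groupby(male_col)["androgen_z"].transform("mean")
    out["androgen_between"] = between
    out["androgen_within"] = out["androgen_z"] - between
    return out


def lag_distribution(matched: pd.DataFrame) -> pd.Series:
    """Counts of matched lags 0..7 (diagnostic mirroring field reporting)."""
    lags = matched["lag_days"].dropna().astype(int)
    return lags.value_counts().reindex(range(MAX_LAG + 1), fill_value=0)
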