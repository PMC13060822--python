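"""Accelerometer-derived physical-activity (PA) summaries.

Eleven participant-level summaries are derived from minute-level ENMO
(Euclidean norm minus one g, floored at zero, in milli-g) traces:

==========  ==============================================================
TLAC        total log acceleration, sum of log(1 + ENMO) per day
LIPA        minutes of light-intensity activity per day
MVPA        minutes of moderate-to-vigorous activity per day (>= 193 mg)
SBout       mean sedentary bout duration (minutes)
ABout       mean active bout duration (minutes)
SATP        sedentary-to-active minute transition probability
ASTP        active-to-sedentary minute transition probability
DARE        daytime activity ratio estimate (daytime / total log accel.)
M10         mean log acceleration over the most active 10-hour window
L5          mean log acceleration over the least active 5-hour window
RA          relative amplitude (M10 - L5) / (M10 + L5)
==========  ==============================================================

Conventions (each exposed as a keyword): a minute is *active* when its ENMO
is at or above ``sedentary_cut`` (default 30 mg); LIPA covers
[sedentary_cut, mvpa_cut) and MVPA [mvpa_cut, inf) with the 193 mg
cut-point separating them; transition denominators exclude each day's final
minute; M10/L5 windows are contiguous within a day and do not wrap
midnight; the daytime window for DARE defaults to 08:00-20:00; log
acceleration is log(1 + x) (``log1p``; plain log on positive minutes
available via ``tlac_log="log"``).  Per-day quantities are averaged across
days, skipping days where a quantity is undefined.

Upstream raw-signal calibration, 5-second epoching and non-wear handling
are out of scope: inputs are assumed to be clean minute-level series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "MINUTES_PER_DAY",
    "MVPA_CUT_MG",
    "PA_COLUMNS",
    "MinuteSeries",
    "PASummary",
    "PAFeatureExtractor",
    "bout_summaries",
    "circadian_summaries",
    "compute_pa_summaries",
    "read_minute_csv",
    "transition_probabilities",
]

MINUTES_PER_DAY = 1440
#: moderate-to-vigorous cut-point in milli-g (NHANES quantile-matched)
MVPA_CUT_MG = 193.0
#: canonical column order of the 11 PA summaries
PA_COLUMNS = [
    "TLAC",
    "LIPA",
    "MVPA",
    "SBout",
    "ABout",
    "SATP",
    "ASTP",
    "DARE",
    "M10",
    "L5",
    "RA",
]

_M10_MINUTES = 600
_L5_MINUTES = 300
_DEFAULT_DAYTIME = (8 * 60, 20 * 60)  # 08:00-20:00


@dataclass
class MinuteSeries:
    """One participant's minute-level acceleration trace.

    Parameters
    ----------
    participant_id : str
    values : ndarray
        Minute-level ENMO in milli-g, time ordered, non-negative and
        finite; length a multiple of 1440 (whole days).
    start_minute : int
        Clock offset of the first minute, in minutes past midnight.
    """

    participant_id: str
    values: np.ndarray = field(repr=False)
    start_minute: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("minute values must be finite and non-negative")
        if self.values.size % MINUTES_PER_DAY:
            raise ValueError(
                f"series length {self.values.size} is not a multiple of "
                f"{MINUTES_PER_DAY}; trim to whole days first"
            )
        if not 0 <= self.start_minute < MINUTES_PER_DAY:
            raise ValueError("start_minute must lie in [0, 1440)")

    @property
    def n_days(self) -> int:
        return self.values.size // MINUTES_PER_DAY

    def days(self) -> np.ndarray:
        """(n_days, 1440) view of the trace."""
        return self.values.reshape(self.n_days, MINUTES_PER_DAY)

    def minute_of_day(self) -> np.ndarray:
        """Clock minute-of-day for each sample."""
        return (self.start_minute + np.arange(self.values.size)) % MINUTES_PER_DAY


@dataclass
class PASummary:
    """The 11 PA summaries for one participant (NaN marks undefined)."""

    TLAC: float
    LIPA: float
    MVPA: float
    SBout: float
    ABout: float
    SATP: float
    ASTP: float
    DARE: float
    M10: float
    L5: float
    RA: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in PA_COLUMNS], dtype=float)


def _log_accel(values: np.ndarray, tlac_log: str) -> np.ndarray:
    if tlac_log == "log1p":
        return np.log1p(values)
    if tlac_log == "log":
        out = np.zeros_like(values)
        pos = values > 0
        out[pos] = np.log(values[pos])
        return out
    raise ValueError("tlac_log must be 'log1p' or 'log'")


def transition_probabilities(active_indicator) -> tuple[float, float]:
    """Sedentary->active and active->sedentary transition probabilities.

    ASTP is the number of active->sedentary transitions divided by the
    number of active minutes excluding the final minute; SATP swaps the
    roles.  A probability with no eligible minutes is returned as NaN
    (missing), never as 0.

    Returns
    -------
    (SATP, ASTP) floats in [0, 1] or NaN.
    """
    a = np.asarray(active_indicator, dtype=bool)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("need a 1-d indicator of length >= 2")
    head, nxt = a[:-1], a[1:]
    n_active = int(head.sum())
    n_sed = int((~head).sum())
    astp = float(np.sum(head & ~nxt)) / n_active if n_active else np.nan
    satp = float(np.sum(~head & nxt)) / n_sed if n_sed else np.nan
    return satp, astp


def _run_lengths(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lengths and values of maximal constant runs of a boolean vector."""
    change = np.flatnonzero(np.diff(a.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [a.size]))
    lengths = np.diff(bounds)
    values = a[bounds[:-1]]
    return lengths, values


def bout_summaries(active_indicator) -> tuple[float, float]:
    """Mean sedentary and active bout durations in minutes.

    A bout is a maximal run of consecutive minutes of one kind; a kind
    with no runs yields NaN.

    Returns
    -------
    (SBout, ABout)
    """
    a = np.asarray(active_indicator, dtype=bool)
    if a.size < 1:
        raise ValueError("need at least one minute")
    lengths, values = _run_lengths(a)
    sed = lengths[~values]
    act = lengths[values]
    sbout = float(sed.mean()) if sed.size else np.nan
    about = float(act.mean()) if act.size else np.nan
    return sbout, about


def _window_means(x: np.ndarray, width: int) -> np.ndarray:
    """Means of all contiguous windows of the given width (cumsum scan)."""
    cs = np.concatenate(([0.0], np.cumsum(x)))
    return (cs[width:] - cs[:-width]) / width


def circadian_summaries(
    series: MinuteSeries,
    daytime_window: tuple[int, int] = _DEFAULT_DAYTIME,
    *,
    tlac_log: str = "log1p",
) -> tuple[float, float, float, float]:
    """M10, L5, RA and DARE from whole-day log-acceleration profiles.

    Per day, M10 (L5) is the mean log acceleration over the contiguous
    600-minute (300-minute) window maximizing (minimizing) that mean;
    windows do not wrap midnight.  DARE is the day's daytime
    log-acceleration sum divided by its total (NaN on an all-zero day).
    Day values are averaged, then RA = (M10 - L5) / (M10 + L5), reported
    as 0 with a logged warning when the denominator vanishes.

    Returns
    -------
    (M10, L5, RA, DARE)
    """
    log_days = _log_accel(series.values, tlac_log).reshape(
        series.n_days, MINUTES_PER_DAY
    )
    minute_clock = series.minute_of_day().reshape(series.n_days, MINUTES_PER_DAY)
    lo, hi = daytime_window
    if not (0 <= lo < hi <= MINUTES_PER_DAY):
        raise ValueError("daytime_window must satisfy 0 <= lo < hi <= 1440")
    is_day = (minute_clock >= lo) & (minute_clock < hi)

    m10_days, l5_days, dare_days = [], [], []
    for d in range(series.n_days):
        x = log_days[d]
        m10_days.append(_window_means(x, _M10_MINUTES).max())
        l5_days.append(_window_means(x, _L5_MINUTES).min())
        total = x.sum()
        dare_days.append(x[is_day[d]].sum() / total if total > 0 else np.nan)

    m10 = float(np.mean(m10_days))
    l5 = float(np.mean(l5_days))
    dare = float(np.nanmean(dare_days)) if not np.all(np.isnan(dare_days)) else np.nan
    denom = m10 + l5
    if denom == 0:
        logger.warning(
            "M10 + L5 = 0 for participant %s: RA reported as 0",
            series.participant_id,
        )
        ra = 0.0
    elif abs(m10 - l5) <= 1e-12 * max(abs(m10), abs(l5)):
        ra = 0.0  # numerically constant profile
    else:
        ra = (m10 - l5) / denom
    return m10, l5, ra, dare


def compute_pa_summaries(
    series: MinuteSeries,
    *,
    sedentary_cut: float = 30.0,
    mvpa_cut: float = MVPA_CUT_MG,
    daytime_window: tuple[int, int] = _DEFAULT_DAYTIME,
    tlac_log: str = "log1p",
) -> PASummary:
    """Derive all 11 PA summaries for one participant.

    Minutes with ENMO in [sedentary_cut, mvpa_cut) count as LIPA, at or
    above mvpa_cut as MVPA, below sedentary_cut as sedentary; LIPA + MVPA
    + sedentary minutes conserve each day's 1440 total.  Fragmentation
    (bouts, transition probabilities) is computed within days and averaged
    across them; undefined days are skipped and a quantity undefined on
    every day is NaN.
    """
    if not 0 < sedentary_cut < mvpa_cut:
        raise ValueError("need 0 < sedentary_cut < mvpa_cut")
    days = series.days()
    log_days = _log_accel(series.values, tlac_log).reshape(days.shape)

    tlac = float(log_days.sum(axis=1).mean())
    lipa = float(((days >= sedentary_cut) & (days < mvpa_cut)).sum(axis=1).mean())
    mvpa = float((days >= mvpa_cut).sum(axis=1).mean())

    satp_d, astp_d, sbout_d, about_d = [], [], [], []
    for d in range(days.shape[0]):
        active = days[d] >= sedentary_cut
        satp, astp = transition_probabilities(active)
        sbout, about = bout_summaries(active)
        satp_d.append(satp)
        astp_d.append(astp)
        sbout_d.append(sbout)
        about_d.append(about)

    def _avg(vals):
        vals = np.asarray(vals, dtype=float)
        return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan

    m10, l5, ra, dare = circadian_summaries(
        series, daytime_window, tlac_log=tlac_log
    )
    return PASummary(
        TLAC=tlac,
        LIPA=lipa,
        MVPA=mvpa,
        SBout=_avg(sbout_d),
        ABout=_avg(about_d),
        SATP=_avg(satp_d),
        ASTP=_avg(astp_d),
        DARE=dare,
        M10=m10,
        L5=l5,
        RA=ra,
    )


def read_minute_csv(path) -> list[MinuteSeries]:
    """Read a long-format minute CSV (participant_id, minute_index, enmo_mg)."""
    df = pd.read_csv(path)
    required = {"participant_id", "minute_index", "enmo_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"minute CSV missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("minute_index")
        out.append(MinuteSeries(str(pid), grp["enmo_mg"].to_numpy()))
    return out


class PAFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping minute-level traces to the 11-column PA table.

    Stateless (``fit`` records parameters only); ``transform`` accepts a
    list of :class:`MinuteSeries` or a long-format DataFrame with columns
    ``participant_id``, ``minute_index``, ``enmo_mg`` and returns a
    participant-indexed DataFrame with the canonical 11 PA columns.

    Parameters
    ----------
    sedentary_cut : float, milli-g (active threshold; default 30)
    mvpa_cut : float, milli-g (default 193)
    daytime_window : (start, end) minutes past midnight for DARE
    tlac_log : {"log1p", "log"}
    """

    def __init__(
        self,
        sedentary_cut: float = 30.0,
        mvpa_cut: float = MVPA_CUT_MG,
        daytime_window: tuple[int, int] = _DEFAULT_DAYTIME,
        tlac_log: str = "log1p",
    ):
        self.sedentary_cut = sedentary_cut
        self.mvpa_cut = mvpa_cut
        self.daytime_window = daytime_window
        self.tlac_log = tlac_log

    def fit(self, X=None, y=None):
        if not 0 < self.sedentary_cut < self.mvpa_cut:
            raise ValueError("need 0 < sedentary_cut < mvpa_cut")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        self.fit()
        if isinstance(X, pd.DataFrame):
            series_list = _series_from_long(X)
        else:
            series_list = list(X)
        rows, ids = [], []
        for s in series_list:
            summary = compute_pa_summaries(
                s,
                sedentary_cut=self.sedentary_cut,
                mvpa_cut=self.mvpa_cut,
                daytime_window=self.daytime_window,
                tlac_log=self.tlac_log,
            )
            rows.append(summary.to_array())
            ids.append(s.participant_id)
        return pd.DataFrame(rows, index=pd.Index(ids, name="participant_id"),
                            columns=PA_COLUMNS)


def _series_from_long(df: pd.DataFrame) -> list[MinuteSeries]:
    required = {"participant_id", "minute_index", "enmo_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long-format frame missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("minute_index")
        out.append(MinuteSeries(str(pid), grp["enmo_mg"].to_numpy()))
    return out
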