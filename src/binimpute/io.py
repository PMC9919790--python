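"""Device-style CSV input, minute-level resampling, and the day × minute matrix.

Wearable trackers emit heart-rate samples every few seconds.  The analysis
works on a fixed grid instead: one row per calendar day, one column per
minute of day (0–1439), beats/min values, ``NaN`` marking missing minutes.
Everything downstream (gap masking, binning, imputation, scoring) consumes
that :class:`DayMatrix`.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyInputError,
    FormatError,
    InsufficientDaysError,
)

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440

#: Default CSV column names; remappable via the ``dialect`` argument.
DEFAULT_DIALECT = {"timestamp": "timestamp", "value": "heart_rate"}


@dataclass
class RawSampleSeries:
    """Sub-minute device samples for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque identifier.
    timestamps : np.ndarray
        ``datetime64[ns]`` array, strictly increasing.
    values : np.ndarray
        Heart rate in beats/min, finite and > 0.
    nominal_interval_s : int
        The device's nominal sampling interval in seconds (e.g. 5).
    """

    subject_id: str
    timestamps: np.ndarray
    values: np.ndarray
    nominal_interval_s: int = 5

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.nominal_interval_s <= 0:
            raise ValueError("nominal_interval_s must be a positive integer")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > np.timedelta64(0, "ns")):
            raise ValueError("timestamps must be strictly increasing")
        if len(self.values) and not (np.all(np.isfinite(self.values)) and np.all(self.values > 0)):
            raise ValueError("heart-rate values must be finite and > 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MinuteSeries:
    """One calendar day resampled to 1440 minute slots (NaN = no samples)."""

    date: _dt.date
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (MINUTES_PER_DAY,):
            raise ValueError(f"MinuteSeries needs exactly {MINUTES_PER_DAY} slots")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not (np.all(np.isfinite(obs)) and np.all(obs > 0)):
            raise ValueError("non-missing values must be finite and > 0")


@dataclass
class DayMatrix:
    """D × C grid of beats/min values; ``NaN`` marks a missing minute.

    Rows are days (in chronological/input order), column ``j`` is
    minute-of-day ``col_offset + j``.  A full day has ``col_offset == 0``
    and ``C == 1440``; a *bin* extracted around a gap is a narrower slice.
    """

    days: list = field(default_factory=list)
    values: np.ndarray = None
    col_offset: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (days × minutes)")
        d, c = self.values.shape
        if d < 1 or not (1 <= c <= MINUTES_PER_DAY):
            raise ValueError(f"invalid matrix shape {self.values.shape}")
        if len(self.days) != d:
            raise ValueError("len(days) must equal the number of rows")
        if not (0 <= self.col_offset and self.col_offset + c <= MINUTES_PER_DAY):
            raise ValueError("columns must lie within one day (0–1439)")
        self.days = list(self.days)

    # -- conveniences -----------------------------------------------------
    @property
    def n_days(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean D × C mask, True where the value is missing."""
        return np.isnan(self.values)

    def copy(self) -> "DayMatrix":
        return DayMatrix(list(self.days), self.values.copy(), self.col_offset)

    def col_index(self, minute_of_day: int) -> int:
        """Translate a minute-of-day into a column index of this matrix."""
        j = minute_of_day - self.col_offset
        if not 0 <= j < self.n_cols:
            raise IndexError(
                f"minute {minute_of_day} outside columns "
                f"[{self.col_offset}, {self.col_offset + self.n_cols})"
            )
        return j

    def equals(self, other: "DayMatrix") -> bool:
        return (
            self.days == other.days
            and self.col_offset == other.col_offset
            and self.values.shape == other.values.shape
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def read_samples_csv(path, dialect=None, subject_id: str = "", nominal_interval_s: int = 5) -> RawSampleSeries:
    """Read a device-style CSV of (timestamp, heart-rate) samples.

    Duplicate timestamps are collapsed by their mean (devices retransmit);
    rows whose value does not parse as a number are dropped and counted in
    the log.  Raises :class:`FormatError` if a required column is absent and
    :class:`EmptyInputError` if no row survives parsing.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path)
    ts_col, val_col = dialect["timestamp"], dialect["value"]
    for col in (ts_col, val_col):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} not found in {path}")

    ts = pd.to_datetime(df[ts_col], errors="coerce")
    vals = pd.to_numeric(df[val_col], errors="coerce")
    ok = ts.notna() & vals.notna() & np.isfinite(vals) & (vals > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_samples_csv: dropped %d unparseable row(s) from %s", n_dropped, path)
    ts, vals = ts[ok], vals[ok]
    if len(ts) == 0:
        raise EmptyInputError(f"no parseable samples in {path}")

    collapsed = (
        pd.DataFrame({"t": ts.values, "v": vals.values})
        .groupby("t", sort=True)["v"]
        .mean()
    )
    return RawSampleSeries(
        subject_id=subject_id,
        timestamps=collapsed.index.values,
        values=collapsed.values,
        nominal_interval_s=nominal_interval_s,
    )


def to_minute_series(series: RawSampleSeries, date: _dt.date) -> MinuteSeries:
    """Average samples into half-open minute buckets [m:00, m+1:00) on `date`.

    A minute with no samples stays missing.  Applying this to already
    minute-spaced samples returns those values unchanged (idempotence).
    """
    out = np.full(MINUTES_PER_DAY, np.nan)
    if len(series) == 0:
        return MinuteSeries(date, out)
    day_start = np.datetime64(pd.Timestamp(date), "ns")
    offs_min = (series.timestamps - day_start) // np.timedelta64(60, "s")
    in_day = (offs_min >= 0) & (offs_min < MINUTES_PER_DAY)
    idx = offs_min[in_day].astype(np.int64)
    vals = series.values[in_day]
    if idx.size:
        sums = np.zeros(MINUTES_PER_DAY)
        counts = np.zeros(MINUTES_PER_DAY)
        np.add.at(sums, idx, vals)
        np.add.at(counts, idx, 1.0)
        filled = counts > 0
        out[filled] = sums[filled] / counts[filled]
    return MinuteSeries(date, out)


def build_day_matrix(days: list) -> DayMatrix:
    """Stack MinuteSeries into a D × 1440 matrix (rows in input order)."""
    if not days:
        raise EmptyInputError("build_day_matrix needs at least one MinuteSeries")
    dates = [d.date for d in days]
    if len(set(dates)) != len(dates):
        raise ValueError("duplicate dates passed to build_day_matrix")
    values = np.vstack([d.values for d in days])
    return DayMatrix([d.isoformat() for d in dates], values, col_offset=0)


def select_complete_days(matrix: DayMatrix, n: int, seed: int, min_completeness: float = 1.0) -> DayMatrix:
    """Uniformly sample ``n`` complete rows without replacement (seeded).

    "Complete" means a fraction of observed minutes ≥ ``min_completeness``
    (default 1.0, i.e. zero missing minutes).  The chosen rows keep their
    original chronological order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    frac = 1.0 - matrix.missing_mask.mean(axis=1)
    eligible = np.flatnonzero(frac >= min_completeness)
    if eligible.size < n:
        raise InsufficientDaysError(n, int(eligible.size))
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=n, replace=False))
    return DayMatrix(
        [matrix.days[i] for i in chosen], matrix.values[chosen].copy(), matrix.col_offset
    )


def write_matrix_csv(matrix: DayMatrix, path) -> None:
    """Write a DayMatrix as CSV: header ``day,m0000,...``; missing = empty cell."""
    cols = [f"m{matrix.col_offset + j:04d}" for j in range(matrix.n_cols)]
    df = pd.DataFrame(matrix.values, index=pd.Index(matrix.days, name="day"), columns=cols)
    df.to_csv(path, na_rep="")


def read_matrix_csv(path) -> DayMatrix:
    """Read a DayMatrix written by :func:`write_matrix_csv` (lossless round-trip)."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.index.name != "day":
        raise FormatError(f"first header cell must be 'day', got {df.index.name!r}")
    minutes = []
    for c in df.columns:
        if not (len(c) == 5 and c[0] == "m" and c[1:].isdigit()):
            raise FormatError(f"malformed minute column header {c!r}")
        minutes.append(int(c[1:]))
    if not minutes:
        raise FormatError("matrix CSV has no minute columns")
    offset = minutes[0]
    if minutes != list(range(offset, offset + len(minutes))):
        raise FormatError("minute columns must be consecutive")
    raw = df.to_numpy()
    values = np.full(raw.shape, np.nan)
    nonempty = raw != ""
    try:
        values[nonempty] = raw[nonempty].astype(float)
    except ValueError as e:
        raise FormatError(f"non-numeric cell in matrix CSV: {e}") from None
    return DayMatrix(list(df.index), values, col_offset=offset)
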