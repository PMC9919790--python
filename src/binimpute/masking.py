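"""Deliberate removal of contiguous windows, retaining ground truth.

Evaluation masks a known-good window (15 min or 1 h of a day), lets an
imputer fill it, and scores the fill against the held-out truth.  The truth
is stored *outside* the matrix so no imputer can see it by construction.

Two masking modes exist:

* leave-one-day-out (default): one experiment per evaluated day, masking
  only that day's window while the other days keep their values as donors;
* simultaneous: the window is masked on every listed day at once (the
  literal protocol reading; requires the training bin to be wider than the
  gap, otherwise nothing observed remains in the gap columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import GapError
from .io import MINUTES_PER_DAY, DayMatrix


@dataclass(frozen=True)
class GapSpec:
    """A contiguous masked interval on one day.

    ``start_min`` is a minute of day (0–1439); ``length_min`` is the gap
    length in minutes; ``target_day`` is the row index being masked.
    """

    start_min: int
    length_min: int
    target_day: int = 0

    def __post_init__(self):
        if self.length_min < 1:
            raise GapError("length_min must be >= 1")
        if not (0 <= self.start_min and self.start_min + self.length_min <= MINUTES_PER_DAY):
            raise GapError("gap must lie within [0, 1440)")

    @property
    def end_min(self) -> int:
        return self.start_min + self.length_min


@dataclass
class MaskedExperiment:
    """A masked matrix plus the held-out truth, keyed by (day index, minute of day)."""

    masked: DayMatrix
    truth: dict = field(default_factory=dict)
    gap: GapSpec = None


def apply_gap(matrix: DayMatrix, gap: GapSpec) -> MaskedExperiment:
    """Mask exactly the cells (gap.target_day, start_min .. end_min-1).

    All other cells are untouched; previously observed values in the window
    are recorded as truth.  Raises :class:`GapError` if the window falls
    outside the matrix columns, the day index is invalid, or the window is
    already entirely missing (nothing to evaluate).
    """
    if not 0 <= gap.target_day < matrix.n_days:
        raise GapError(f"target_day {gap.target_day} outside 0..{matrix.n_days - 1}")
    lo, hi = gap.start_min, gap.end_min
    if lo < matrix.col_offset or hi > matrix.col_offset + matrix.n_cols:
        raise GapError(
            f"gap [{lo}, {hi}) outside matrix columns "
            f"[{matrix.col_offset}, {matrix.col_offset + matrix.n_cols})"
        )
    j0, j1 = lo - matrix.col_offset, hi - matrix.col_offset
    row = matrix.values[gap.target_day, j0:j1]
    observed = ~np.isnan(row)
    if not observed.any():
        raise GapError("window is already fully missing on the target day")

    masked = matrix.copy()
    truth = {
        (gap.target_day, lo + k): float(row[k])
        for k in range(j1 - j0)
        if observed[k]
    }
    masked.values[gap.target_day, j0:j1] = np.nan
    return MaskedExperiment(masked=masked, truth=truth, gap=gap)


def iterate_gap_days(matrix: DayMatrix, start_min: int, length_min: int, days):
    """Yield one leave-one-day-out MaskedExperiment per listed day index."""
    days = list(days)
    if not days:
        raise GapError("days list must be non-empty")
    for d in days:
        yield apply_gap(matrix, GapSpec(start_min, length_min, target_day=d))


def apply_gap_all_days(matrix: DayMatrix, start_min: int, length_min: int, days=None) -> MaskedExperiment:
    """Simultaneous mode: mask the window on every listed day at once.

    Truth pools all masked cells; ``gap.target_day`` is meaningless here and
    set to the first masked day.
    """
    days = list(days) if days is not None else list(range(matrix.n_days))
    if not days:
        raise GapError("days list must be non-empty")
    masked = matrix.copy()
    truth = {}
    gap0 = GapSpec(start_min, length_min, target_day=days[0])
    j0 = start_min - matrix.col_offset
    j1 = j0 + length_min
    if j0 < 0 or j1 > matrix.n_cols:
        raise GapError("gap outside matrix columns")
    any_observed = False
    for d in days:
        row = matrix.values[d, j0:j1]
        for k in range(length_min):
            if not np.isnan(row[k]):
                truth[(d, start_min + k)] = float(row[k])
                any_observed = True
        masked.values[d, j0:j1] = np.nan
    if not any_observed:
        raise GapError("window is already fully missing on all listed days")
    return MaskedExperiment(masked=masked, truth=truth, gap=gap0)


def restore_truth(experiment: MaskedExperiment) -> DayMatrix:
    """Put the held-out values back (round-trip identity with the source)."""
    out = experiment.masked.copy()
    for (d, minute), v in experiment.truth.items():
        out.values[d, minute - out.col_offset] = v
    return out
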