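"""Bin construction: a minute-of-day window centered on the missing gap.

Instead of training an imputer on the whole 24-h record, a *bin* of a chosen
size (15 min up to 6 h, or the literal token ``"total"`` for the full day)
is cut around the gap across all days.  Centering pads the gap evenly on
both sides; an odd leftover minute goes after the gap.  Bins never wrap
across midnight — an error is raised instead of silently clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import BinError
from .io import MINUTES_PER_DAY, DayMatrix

#: Token selecting the full 1440-column matrix instead of a window.
TOTAL = "total"

#: The bin-size ladder used throughout (minutes, plus the whole-day token).
DEFAULT_BINS = [15, 30, 45, 60, 120, 180, 240, 300, 360, TOTAL]


@dataclass(frozen=True)
class BinWindow:
    """Half-open minute-of-day window [start_min, end_min) containing the gap."""

    start_min: int
    end_min: int

    def __post_init__(self):
        if not (0 <= self.start_min < self.end_min <= MINUTES_PER_DAY):
            raise BinError(f"invalid bin window [{self.start_min}, {self.end_min})")

    @property
    def size_min(self) -> int:
        return self.end_min - self.start_min


def bin_bounds(gap_start: int, gap_len: int, bin_size: int) -> BinWindow:
    """Center a bin of ``bin_size`` minutes on the gap [gap_start, gap_start+gap_len).

    pad_total = bin_size - gap_len is split as floor(pad/2) before the gap
    and the remainder after it, so |pad_before - pad_after| <= 1.  Raises
    :class:`BinError` if the bin is smaller than the gap or would cross a
    day boundary (shrink the bin instead).
    """
    if bin_size < gap_len:
        raise BinError(f"bin size {bin_size} smaller than gap length {gap_len}")
    pad_total = bin_size - gap_len
    pad_before = pad_total // 2
    pad_after = pad_total - pad_before
    start = gap_start - pad_before
    end = gap_start + gap_len + pad_after
    if start < 0 or end > MINUTES_PER_DAY:
        raise BinError(
            f"bin [{start}, {end}) crosses the day boundary; "
            f"use a smaller bin for a gap at minute {gap_start}"
        )
    return BinWindow(start, end)


def extract_bin(matrix: DayMatrix, window) -> DayMatrix:
    """Cut the D × size submatrix for ``window`` (missing cells preserved).

    ``window`` may be a :class:`BinWindow` or the token ``"total"``, which
    returns a copy of the full matrix.
    """
    if window == TOTAL:
        return matrix.copy()
    lo = window.start_min - matrix.col_offset
    hi = window.end_min - matrix.col_offset
    if lo < 0 or hi > matrix.n_cols:
        raise BinError(
            f"window [{window.start_min}, {window.end_min}) outside matrix columns "
            f"[{matrix.col_offset}, {matrix.col_offset + matrix.n_cols})"
        )
    return DayMatrix(
        list(matrix.days), matrix.values[:, lo:hi].copy(), col_offset=window.start_min
    )
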