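"""Scoring and the full factorial masking/binning/imputation experiment.

For every evaluated day a gap is masked, a bin of each candidate size is cut
around it, every method imputes the bin, and the fill is scored by RMSE
against the held-out truth.  Two summary statistics follow the experiment's
design:

* **success rate** — the fraction of days on which a method's RMSE with
  binned data is *strictly* lower than with the whole-day (``total``) data;
  ties and increases count as failures;
* **optimal bin size** — per day, the bin minimizing the five methods'
  summed RMSE (ties go to the smallest bin).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import DEFAULT_BINS, TOTAL, bin_bounds, extract_bin
from .exceptions import IncompleteGridError
from .imputers import METHODS, ImputerConfig, impute
from .io import DayMatrix
from .masking import GapSpec, apply_gap, apply_gap_all_days

#: The four gap frames: (start minute, length) for 3–4 am / 3–4 pm and the
#: 15-min variants 3–3:15 am / 3–3:15 pm.
DEFAULT_FRAMES = [(180, 60), (900, 60), (180, 15), (900, 15)]


def frame_label(start_min: int, length_min: int) -> str:
    end = start_min + length_min
    return f"{start_min // 60:02d}:{start_min % 60:02d}-{end // 60:02d}:{end % 60:02d}"


def bin_sort_key(b):
    """Numeric bins ascending; the ``total`` token sorts last."""
    return 10**6 if b == TOTAL else int(b)


@dataclass
class ExperimentConfig:
    """The factorial design: frames × days × bin sizes × methods.

    Bins smaller than a frame's gap are inadmissible and skipped for that
    frame (the 1-h gap's smallest bin is 1 h).  ``imputer_options`` carries
    per-method hyperparameter overrides, keyed by lower-case method name;
    the factorial default uses 25 trees per forest (a problem-size choice —
    see docs/methods.md), while stand-alone ``ImputerConfig`` keeps the
    missForest default of 100.
    """

    frames: list = field(default_factory=lambda: list(DEFAULT_FRAMES))
    bins: list = field(default_factory=lambda: list(DEFAULT_BINS))
    methods: list = field(default_factory=lambda: list(METHODS))
    days: int = 30
    seed: int = 0
    mask_mode: str = "leave-one-out"
    imputer_options: dict = field(default_factory=lambda: {"rf": {"n_trees": 25}})

    def __post_init__(self):
        if self.mask_mode not in ("leave-one-out", "simultaneous"):
            raise ValueError("mask_mode must be 'leave-one-out' or 'simultaneous'")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        self.methods = [str(m).upper() for m in self.methods]
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")

    def admissible_bins(self, gap_len: int) -> list:
        """Bins usable for a gap: >= gap length (strictly > in simultaneous mode)."""
        out = []
        for b in self.bins:
            if b == TOTAL:
                out.append(b)
            elif self.mask_mode == "simultaneous":
                if int(b) > gap_len:
                    out.append(int(b))
            elif int(b) >= gap_len:
                out.append(int(b))
        return sorted(out, key=bin_sort_key)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(truth: dict, imputed: DayMatrix) -> float:
    """Root mean square error over the held-out cells: sqrt(sum (R-I)^2 / N)."""
    if not truth:
        raise ValueError("truth map is empty")
    sq = 0.0
    for (d, minute), actual in truth.items():
        val = imputed.values[d, minute - imputed.col_offset]
        if np.isnan(val):
            raise ValueError(
                f"cell (day {d}, minute {minute}) is still missing — imputer "
                "contract violation"
            )
        sq += (actual - val) ** 2
    return float(np.sqrt(sq / len(truth)))


def _pivot_day_bins(records: pd.DataFrame, method: str, frame: str = None) -> pd.DataFrame:
    sel = records[records["method"] == method]
    if frame is not None:
        sel = sel[sel["frame"] == frame]
    if sel.empty:
        raise IncompleteGridError(f"no records for method {method!r}, frame {frame!r}")
    return sel.pivot_table(index="day", columns="bin", values="rmse", aggfunc="first")


def success_rate(records: pd.DataFrame, method: str, frame: str = None, reference_bin="smallest") -> float:
    """Fraction of days where RMSE(reference bin) < RMSE(total), strictly.

    ``reference_bin`` may be ``"smallest"`` (default: smallest numeric bin
    present), ``"best"`` (each day's lowest-RMSE numeric bin), or an explicit
    bin size.  Ties and increases count as failures.
    """
    table = _pivot_day_bins(records, method, frame)
    if TOTAL not in table.columns:
        raise IncompleteGridError(f"no '{TOTAL}' records for method {method!r}")
    numeric = sorted((b for b in table.columns if b != TOTAL), key=bin_sort_key)
    if not numeric:
        raise IncompleteGridError("no binned records to compare against total")
    if reference_bin == "smallest":
        ref = table[numeric[0]]
    elif reference_bin == "best":
        ref = table[numeric].min(axis=1)
    else:
        if reference_bin not in table.columns:
            raise IncompleteGridError(f"no records at reference bin {reference_bin!r}")
        ref = table[reference_bin]
    pair = pd.concat([ref.rename("ref"), table[TOTAL].rename("total")], axis=1)
    absent = pair[pair.isna().any(axis=1)].index.tolist()
    if absent:
        raise IncompleteGridError(f"days missing (reference, total) RMSE pairs: {absent}")
    return float((pair["ref"] < pair["total"]).mean())


def optimal_bin_size(day_records: pd.DataFrame, mode: str = "aggregate"):
    """The bin minimizing all methods' RMSE for one day's records.

    ``aggregate`` (default): argmin over bins of the methods' summed RMSE.
    ``simultaneous``: the bin at which *every* method attains its own
    minimum; returns ``None`` when no such bin exists.  Ties break toward
    the smallest bin.
    """
    grid = day_records.pivot_table(index="method", columns="bin", values="rmse", aggfunc="first")
    if grid.isna().any().any():
        missing = [
            (m, b) for m in grid.index for b in grid.columns if pd.isna(grid.at[m, b])
        ]
        raise IncompleteGridError(f"incomplete (method, bin) grid: {missing}")
    bins = sorted(grid.columns, key=bin_sort_key)
    if mode == "aggregate":
        agg = grid.sum(axis=0)
        best = min(bins, key=lambda b: (agg[b], bin_sort_key(b)))
        return best
    if mode == "simultaneous":
        per_method = [set(grid.columns[grid.loc[m] == grid.loc[m].min()]) for m in grid.index]
        common = set.intersection(*per_method) if per_method else set()
        if not common:
            return None
        return min(common, key=bin_sort_key)
    raise ValueError("mode must be 'aggregate' or 'simultaneous'")


def optimal_bin_histogram(records: pd.DataFrame, frame: str, mode: str = "aggregate") -> dict:
    """Count, over days, how often each bin is the optimal one."""
    sel = records[records["frame"] == frame]
    counts = Counter()
    for _day, day_records in sel.groupby("day"):
        counts[optimal_bin_size(day_records, mode=mode)] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _imputer_config(config: ExperimentConfig, method: str, seed: int) -> ImputerConfig:
    opts = dict(config.imputer_options.get(method.lower(), {}))
    opts.setdefault("seed", seed)
    return ImputerConfig(method=method, **opts)


def _coord_seed(base: int, fi: int, d: int, b, mi: int) -> int:
    code = 1440 if b == TOTAL else int(b)
    return (base * 1_000_003 + fi * 101_159 + d * 13_007 + code * 97 + mi) % 2_147_483_647


def run_experiment(matrix: DayMatrix, config: ExperimentConfig, metric=rmse) -> pd.DataFrame:
    """Run the full factorial and return the records table.

    One record per frame × day × admissible bin × method, with columns
    ``frame, day, method, bin, rmse``.  Deterministic for a fixed seed.
    ``metric(truth, imputed)`` defaults to RMSE and is pluggable.
    """
    if matrix.n_days < config.days:
        raise ValueError(f"matrix has {matrix.n_days} days; config asks for {config.days}")
    day_idx = list(range(config.days))
    rows = []

    def _score(masked, truth, m, cfg, coord):
        try:
            res = impute(masked, cfg)
            return metric(truth, res.imputed)
        except Exception as e:
            e.args = (f"{e} [frame={coord[0]}, day={coord[1]}, bin={coord[2]}, method={m}]",)
            raise

    for fi, (start, length) in enumerate(config.frames):
        label = frame_label(start, length)
        for b in config.admissible_bins(length):
            window = TOTAL if b == TOTAL else bin_bounds(start, length, b)
            sub = extract_bin(matrix, window)
            if config.mask_mode == "leave-one-out":
                for d in day_idx:
                    exp = apply_gap(sub, GapSpec(start, length, target_day=d))
                    for mi, m in enumerate(config.methods):
                        cfg = _imputer_config(config, m, _coord_seed(config.seed, fi, d, b, mi))
                        score = _score(exp.masked, exp.truth, m, cfg, (label, matrix.days[d], b))
                        rows.append((label, matrix.days[d], m, b, score))
            else:
                exp = apply_gap_all_days(sub, start, length, days=day_idx)
                for mi, m in enumerate(config.methods):
                    cfg = _imputer_config(config, m, _coord_seed(config.seed, fi, 0, b, mi))
                    try:
                        res = impute(exp.masked, cfg)
                    except Exception as e:
                        e.args = (f"{e} [frame={label}, bin={b}, method={m}]",)
                        raise
                    for d in day_idx:
                        t_d = {k: v for k, v in exp.truth.items() if k[0] == d}
                        rows.append((label, matrix.days[d], m, b, metric(t_d, res.imputed)))
    return pd.DataFrame(rows, columns=["frame", "day", "method", "bin", "rmse"])


def summarize(records: pd.DataFrame, reference_bin="smallest") -> pd.DataFrame:
    """Per (frame, method) success rates: columns frame, method, success_rate, n_days."""
    rows = []
    for frame in records["frame"].unique():
        sel = records[records["frame"] == frame]
        n_days = sel["day"].nunique()
        for m in sel["method"].unique():
            rows.append((frame, m, success_rate(records, m, frame, reference_bin), n_days))
    return pd.DataFrame(rows, columns=["frame", "method", "success_rate", "n_days"])


def optimal_bins_table(records: pd.DataFrame, mode: str = "aggregate") -> pd.DataFrame:
    """Per-frame optimal-bin histograms: columns frame, bin, count."""
    rows = []
    for frame in records["frame"].unique():
        hist = optimal_bin_histogram(records, frame, mode=mode)
        for b in sorted(hist, key=lambda x: bin_sort_key(x) if x is not None else -1):
            rows.append((frame, b, hist[b]))
    return pd.DataFrame(rows, columns=["frame", "bin", "count"])
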