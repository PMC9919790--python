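"""Synthetic minute-level heart-rate and step-count days.

The generator emulates the statistical structure that makes window-centered
binning interesting for wearable data:

* strong cross-day similarity at the same minute of day (daily routine),
* within-day nonstationarity — a low, flat sleep period and an elevated
  active period whose schedule jitters a little from day to day,
* a day-level random effect (some days run a few bpm hot or cold), and
* minute-level AR(1) noise.

The model for heart rate is additive::

    hr(d, m) = baseline + circadian(m) + activity(d, m) + delta_d + eps(d, m)

where ``circadian`` is a 24-h sinusoid with its trough at the center of the
sleep window, ``activity`` adds a constant boost on the day's (jittered)
active window, ``delta_d ~ N(0, day_effect_sd^2)`` i.i.d. per day, and
``eps`` is a per-day AR(1) process with coefficient ``ar1_rho`` whose
innovations are scaled so the *marginal* sd equals ``noise_sd`` for any rho.

Step counts are exactly 0 throughout the sleep window (the operational
definition of "inactive"), Poisson with mean 40 in the active window, and
small Poisson counts elsewhere.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .io import MINUTES_PER_DAY, DayMatrix, RawSampleSeries


@dataclass
class SynthConfig:
    """Parameters of the synthetic day generator (units: minutes and bpm)."""

    n_days: int = 30
    baseline_bpm: float = 62.0
    circadian_amplitude: float = 10.0
    sleep_window: tuple = (60, 420)     # 1–7 am; trough centered at 4 am
    active_window: tuple = (840, 1080)  # 2–6 pm
    activity_boost_bpm: float = 25.0
    routine_jitter_min: int = 10
    day_effect_sd: float = 2.0
    ar1_rho: float = 0.7
    noise_sd: float = 3.0
    sample_jitter_sd: float = 1.0       # within-minute sd of 5-s samples
    steps_active_mean: float = 40.0
    steps_other_mean: float = 3.0
    start_date: _dt.date = _dt.date(2024, 1, 1)
    seed: int = 0

    def __post_init__(self):
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for name in ("day_effect_sd", "noise_sd", "sample_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.circadian_amplitude < 0 or self.activity_boost_bpm < 0:
            raise ValueError("amplitude and activity boost must be >= 0")
        for lo, hi in (self.sleep_window, self.active_window):
            if not (0 <= lo < hi <= MINUTES_PER_DAY):
                raise ValueError("windows must be within [0, 1440) with start < end")
        if self.routine_jitter_min < 0:
            raise ValueError("routine_jitter_min must be >= 0")


def circadian_component(config: SynthConfig) -> np.ndarray:
    """The smooth 24-h component: trough at the sleep-window center."""
    m = np.arange(MINUTES_PER_DAY)
    trough = 0.5 * (config.sleep_window[0] + config.sleep_window[1])
    return -config.circadian_amplitude * np.cos(
        2.0 * np.pi * (m - trough) / MINUTES_PER_DAY
    )


def _day_ids(config: SynthConfig) -> list:
    return [
        (config.start_date + _dt.timedelta(days=d)).isoformat()
        for d in range(config.n_days)
    ]


def _deterministic_parts(config: SynthConfig, rng: np.random.Generator):
    """Draw per-day jitters/effects and assemble the noiseless mean surface."""
    D = config.n_days
    jit = config.routine_jitter_min
    jitters = (
        rng.integers(-jit, jit + 1, size=D) if jit > 0 else np.zeros(D, dtype=int)
    )
    day_effects = (
        rng.normal(0.0, config.day_effect_sd, size=D)
        if config.day_effect_sd > 0
        else np.zeros(D)
    )
    mean = np.tile(config.baseline_bpm + circadian_component(config), (D, 1))
    a0, a1 = config.active_window
    active = np.zeros((D, MINUTES_PER_DAY), dtype=bool)
    m = np.arange(MINUTES_PER_DAY)
    for d in range(D):
        lo = max(0, a0 + int(jitters[d]))
        hi = min(MINUTES_PER_DAY, a1 + int(jitters[d]))
        active[d] = (m >= lo) & (m < hi)
    mean += config.activity_boost_bpm * active
    mean += day_effects[:, None]
    return mean, active, jitters, day_effects


def _ar1_noise(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """AR(1) noise with marginal sd = noise_sd regardless of rho."""
    D, C = config.n_days, MINUTES_PER_DAY
    if config.noise_sd == 0:
        return np.zeros((D, C))
    rho = config.ar1_rho
    innov_sd = config.noise_sd * np.sqrt(1.0 - rho**2)
    z = rng.normal(size=(D, C))
    eps = np.empty((D, C))
    eps[:, 0] = config.noise_sd * z[:, 0]  # stationary start
    for t in range(1, C):
        eps[:, t] = rho * eps[:, t - 1] + innov_sd * z[:, t]
    return eps


def generate_days(config: SynthConfig):
    """Generate (heart-rate DayMatrix, step-count DayMatrix).

    Deterministic: the same config (including seed) yields bitwise-identical
    matrices.  No missing values are produced.
    """
    rng = np.random.default_rng(config.seed)
    mean, active, _, _ = _deterministic_parts(config, rng)
    hr = mean + _ar1_noise(config, rng)

    s0, s1 = config.sleep_window
    steps = rng.poisson(config.steps_other_mean, size=hr.shape).astype(float)
    n_active = int(active.sum())
    if n_active:
        steps[active] = np.maximum(
            rng.poisson(config.steps_active_mean, size=n_active), 1
        )
    steps[:, s0:s1] = 0.0  # asleep: step count is exactly 0

    days = _day_ids(config)
    return (
        DayMatrix(days, hr, col_offset=0),
        DayMatrix(list(days), steps, col_offset=0),
    )


def generate_sample_stream(config: SynthConfig, date: _dt.date) -> RawSampleSeries:
    """Emit a day of 5-s samples consistent with :func:`generate_days`.

    ``date`` must be one of the generator's day identifiers (anchored at
    ``config.start_date``).  Each 5-s sample equals that minute's model value
    plus independent N(0, sample_jitter_sd^2) jitter, so per-minute averaging
    recovers the minute value up to jitter_sd/sqrt(12).  With jitter 0 the
    round trip through minute resampling is exact.
    """
    day_index = (date - config.start_date).days
    if not 0 <= day_index < config.n_days:
        raise ValueError(f"{date} outside the configured day range")
    hr, _ = generate_days(config)
    minute_vals = hr.values[day_index]

    per_min = 60 // 5
    vals = np.repeat(minute_vals, per_min)
    rng = np.random.default_rng([config.seed, 7919, day_index])
    if config.sample_jitter_sd > 0:
        vals = vals + rng.normal(0.0, config.sample_jitter_sd, size=vals.size)
    t0 = np.datetime64(f"{date.isoformat()}T00:00:00", "ns")
    timestamps = t0 + np.arange(vals.size) * np.timedelta64(5, "s")
    return RawSampleSeries(
        subject_id="synthetic",
        timestamps=timestamps,
        values=vals,
        nominal_interval_s=5,
    )
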