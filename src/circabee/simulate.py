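"""Seeded synthetic forager cohorts with known circadian and sleep structure.

Each simulated forager emits per-minute non-negative integer counts from a
sinusoidally rate-modulated Poisson process, interrupted by sleep bouts from
a two-state (wake/sleep) Markov chain with phase-dependent sleep-onset hazard
and geometrically distributed bout durations.  Sleep fully suppresses counts.

By default, waking minutes draw counts from a *zero-truncated* Poisson law at
the instantaneous rate, so a waking minute always registers at least one
count.  This makes sleep-bout recovery from the count series exact: a run of
zero minutes is a sleep run and vice versa.  Set ``allow_wake_zeros=True``
for an unrestricted Poisson law (at the cost of occasional spurious
inactivity runs at the trough of the cycle).

Treatment presets (``control``, ``imidacloprid_1``, ``imidacloprid_10``)
encode the qualitative effect directions of chronic low-dose neonicotinoid
exposure: reduced modulation depth, reduced daytime rate, elevated daytime
sleep-onset hazard, unchanged sleep-bout length.  Their numeric values live
in ``presets.yaml`` and are generator conventions, not measurements.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .schedule import LightSchedule
from .series import MINUTES_PER_DAY, ActivitySeries, Modality

#: default clock time of lights-on for simulated schedules (08:00)
DEFAULT_LIGHTS_ON = 480
#: default recording start: lights-on of LD day 0
DEFAULT_START = pd.Timestamp("2020-01-01 08:00")


@dataclass(frozen=True)
class ForagerParams:
    """Generator parameters for one synthetic forager.

    ``amplitude`` is the relative modulation depth of the waking rate in
    [0, 1]; ``base_rate`` is the expected counts per waking minute at the
    cycle mean; ``acrophase_hours`` is the clock time (hours after midnight)
    of peak activity on day 0; ``day_rate_factor`` scales the waking rate
    during the (subjective) day; sleep-onset rates are per-minute
    wake-to-sleep hazards and ``mean_bout_min`` the geometric mean sleep-bout
    duration.
    """

    period_hours: float = 24.0
    amplitude: float = 0.8
    base_rate: float = 2.0
    acrophase_hours: float = 14.0
    day_rate_factor: float = 1.0
    sleep_onset_rate_day: float = 0.002
    sleep_onset_rate_night: float = 0.012
    mean_bout_min: float = 20.0
    n_days_ld: int = 5
    n_days_dd: int = 5
    seed: int = 0
    allow_wake_zeros: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")
        if self.period_hours <= 0:
            raise ValueError("period_hours must be positive")
        for name in ("base_rate", "sleep_onset_rate_day", "sleep_onset_rate_night",
                     "day_rate_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mean_bout_min < 1:
            raise ValueError("mean_bout_min must be at least 1 minute")
        if self.n_days_ld + self.n_days_dd < 1:
            raise ValueError("simulation must span at least one day")


@dataclass(frozen=True)
class GroundTruth:
    """Latent state of a simulated forager: the per-minute sleep trace plus
    the true period and modulation depth."""

    sleep_state: np.ndarray  # bool, one per minute
    true_period: float
    true_amplitude: float
    params: ForagerParams


def schedule_for(
    params: ForagerParams,
    lights_on_clock: int = DEFAULT_LIGHTS_ON,
    start: pd.Timestamp = DEFAULT_START,
) -> LightSchedule:
    """The light schedule a simulated forager is generated under."""
    return LightSchedule(
        entrain_days=params.n_days_ld,
        dd_days=params.n_days_dd,
        lights_on_clock=lights_on_clock,
        reference_start=start,
    )


def _truncated_poisson(rng: np.random.Generator, lam: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws via inverse-CDF conditioning on X >= 1."""
    p0 = np.exp(-lam)
    q = p0 + rng.random(lam.size) * (1.0 - p0)
    # guard against q rounding to exactly 1.0 for tiny lam
    q = np.minimum(q, 1.0 - 1e-12)
    return sps.poisson.ppf(q, lam).astype(np.int64)


def simulate_forager(
    params: ForagerParams,
    subject_id: str = "sim",
    lights_on_clock: int = DEFAULT_LIGHTS_ON,
    start: pd.Timestamp = DEFAULT_START,
    modality: Modality = Modality.LOCOMOTION,
) -> tuple[ActivitySeries, GroundTruth]:
    """Simulate one forager; identical parameters and seed give identical output."""
    rng = np.random.default_rng(params.seed)
    schedule = schedule_for(params, lights_on_clock, start)
    n_min = (params.n_days_ld + params.n_days_dd) * MINUTES_PER_DAY

    # waking rate: free-running cosine anchored so the day-0 peak falls at the
    # acrophase clock time, with an optional daytime multiplier
    start_clock_h = (start.hour * 60 + start.minute) / 60.0
    t_h = np.arange(n_min) / 60.0
    phase0_h = (params.acrophase_hours - start_clock_h) % 24.0
    rate = params.base_rate * (
        1.0 + params.amplitude * np.cos(2 * np.pi * (t_h - phase0_h) / params.period_hours)
    )
    minute_offsets = (np.arange(n_min) + start.hour * 60 + start.minute) % MINUTES_PER_DAY
    in_light = ((minute_offsets - lights_on_clock) % MINUTES_PER_DAY) < schedule.photoperiod
    rate = np.where(in_light, rate * params.day_rate_factor, rate)

    # two-state sleep/wake chain, per-minute transitions
    p_onset = np.where(in_light, params.sleep_onset_rate_day, params.sleep_onset_rate_night)
    p_onset = np.clip(p_onset, 0.0, 1.0)
    p_wake = min(1.0 / params.mean_bout_min, 1.0)
    u = rng.random(n_min)
    asleep = np.zeros(n_min, dtype=bool)
    state = False
    for i in range(n_min):
        state = (u[i] >= p_wake) if state else (u[i] < p_onset[i])
        asleep[i] = state

    counts = np.zeros(n_min, dtype=np.int64)
    awake = ~asleep
    lam = np.maximum(rate[awake], 1e-12)
    if params.allow_wake_zeros:
        counts[awake] = rng.poisson(lam)
    else:
        counts[awake] = _truncated_poisson(rng, lam)

    series = ActivitySeries(
        subject_id=subject_id,
        start_time=start,
        bin_width=1,
        counts=counts,
        modality=modality,
    )
    truth = GroundTruth(
        sleep_state=asleep,
        true_period=params.period_hours,
        true_amplitude=params.amplitude,
        params=params,
    )
    return series, truth


@lru_cache(maxsize=1)
def _load_presets() -> dict:
    text = importlib.resources.files("circabee").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset_names() -> list[str]:
    return sorted(_load_presets())


def treatment_preset(name: str, **overrides) -> ForagerParams:
    """Parameters for a named treatment group.

    Known presets: ``control``, ``imidacloprid_1``, ``imidacloprid_10``.
    Keyword overrides (e.g. ``n_days_dd=0``, ``seed=...``) are applied on top.
    """
    presets = _load_presets()
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {', '.join(sorted(presets))}")
    cfg = dict(presets[name])
    cfg.update(overrides)
    return ForagerParams(**cfg)


def simulate_cohort(
    n: int,
    params: ForagerParams | str,
    seed: int,
    subject_prefix: str | None = None,
    **kwargs,
) -> list[tuple[ActivitySeries, GroundTruth]]:
    """Simulate ``n`` independent foragers with per-subject seeds derived
    deterministically from the master seed.

    ``params`` may be a :class:`ForagerParams` or a preset name.  Extra
    keyword arguments are forwarded to :func:`simulate_forager`.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if isinstance(params, str):
        prefix = subject_prefix or params
        params = treatment_preset(params)
    else:
        prefix = subject_prefix or "subject"
    child_seeds = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    cohort = []
    for i in range(n):
        p = replace(params, seed=int(child_seeds[i]) & 0x7FFFFFFF)
        cohort.append(simulate_forager(p, subject_id=f"{prefix}_{i:03d}", **kwargs))
    return cohort
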