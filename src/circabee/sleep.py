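"""Sleep scoring from inactivity and per-phase activity summaries.

Sleep is scored with the standard insect proxy: any maximal run of zero
activity counts lasting at least 5 minutes (configurable) is one sleep bout.
Scoring requires 1-minute bins — wider bins destroy the run structure and
cannot be recovered by rebinning.

A bout is *counted* (episode tally) in the phase in which it starts; its
*minutes* are apportioned to the phases they actually occupy, so per-phase
minute totals always sum to the total detected sleep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .schedule import LightSchedule, Phase
from .series import MINUTES_PER_DAY, ActivitySeries

SLEEP_THRESHOLD_MIN = 5
PROFILE_BIN_MIN = 30


@dataclass(frozen=True)
class SleepBout:
    """One maximal inactivity run of at least the sleep threshold."""

    start: pd.Timestamp
    duration_min: int
    phase_at_start: Optional[Phase] = None

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(minutes=self.duration_min)


@dataclass(frozen=True)
class SleepSummary:
    """Per-subject sleep metrics over the analysed days.

    Totals are summed minutes over the analysed days (divide by ``n_days``
    for per-day means); mean bout lengths are means over the bouts *counted*
    in that phase and are ``None`` when no bout started there.
    ``profile_30min`` holds, for each of the 48 time-of-day bins, the mean
    minutes asleep per 30-min bin across the analysed days.
    """

    total_sleep_day: float
    total_sleep_night: float
    bouts_day: int
    bouts_night: int
    mean_bout_day: Optional[float]
    mean_bout_night: Optional[float]
    profile_30min: np.ndarray
    n_days: int


def detect_sleep_bouts(
    series: ActivitySeries,
    threshold: int = SLEEP_THRESHOLD_MIN,
    schedule: Optional[LightSchedule] = None,
) -> list[SleepBout]:
    """All maximal runs of zero-count minutes with length >= ``threshold``.

    Returned in chronological order; bouts never overlap.  If a schedule is
    given, each bout is tagged with the phase in which it starts.
    """
    if series.bin_width != 1:
        raise ValueError(
            f"sleep scoring requires 1-min bins, got {series.bin_width}-min bins; "
            "rebinning cannot recover sub-bin inactivity runs, so re-read the "
            "data at 1-min resolution"
        )
    if threshold < 1:
        raise ValueError("sleep threshold must be at least 1 minute")
    inactive = np.concatenate(([0], (series.counts == 0).astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(inactive))
    starts, ends = edges[::2], edges[1::2]
    bouts = []
    for s, e in zip(starts, ends):
        if e - s >= threshold:
            start = series.bin_start(int(s))
            phase = schedule.phase_of(start) if schedule is not None else None
            bouts.append(SleepBout(start=start, duration_min=int(e - s), phase_at_start=phase))
    return bouts


def _minute_phases(bout: SleepBout, schedule: LightSchedule) -> list[Phase]:
    return [
        schedule.phase_of(bout.start + pd.Timedelta(minutes=m))
        for m in range(bout.duration_min)
    ]


def summarize_sleep(
    bouts: Sequence[SleepBout],
    schedule: LightSchedule,
    ld_only: bool = True,
    profile_bin_min: int = PROFILE_BIN_MIN,
) -> SleepSummary:
    """Aggregate bouts into per-phase totals, episode counts, mean lengths and
    a time-of-day sleep profile.

    By default only the LD (entrained) days are analysed, reporting day/night;
    with ``ld_only=False`` the DD days are analysed instead, reporting
    subjective day/night under the same field names.
    """
    if ld_only:
        light, dark = Phase.DAY, Phase.NIGHT
        n_days = schedule.entrain_days
    else:
        light, dark = Phase.SUBJECTIVE_DAY, Phase.SUBJECTIVE_NIGHT
        n_days = schedule.dd_days
    if n_days == 0:
        raise ValueError("schedule has no days in the requested regime")

    minutes = {light: 0, dark: 0}
    counts = {light: 0, dark: 0}
    durations: dict[Phase, list[int]] = {light: [], dark: []}
    n_profile = MINUTES_PER_DAY // profile_bin_min
    profile = np.zeros(n_profile)

    for bout in bouts:
        start_phase = bout.phase_at_start or schedule.phase_of(bout.start)
        if start_phase in counts:
            counts[start_phase] += 1
            durations[start_phase].append(bout.duration_min)
        for m, phase in enumerate(_minute_phases(bout, schedule)):
            if phase not in minutes:
                continue  # minute falls in the other regime's days
            minutes[phase] += 1
            t = bout.start + pd.Timedelta(minutes=m)
            offset = (t - schedule.reference_start).total_seconds() / 60.0
            profile[int(offset % MINUTES_PER_DAY) // profile_bin_min] += 1

    return SleepSummary(
        total_sleep_day=float(minutes[light]),
        total_sleep_night=float(minutes[dark]),
        bouts_day=counts[light],
        bouts_night=counts[dark],
        mean_bout_day=float(np.mean(durations[light])) if durations[light] else None,
        mean_bout_night=float(np.mean(durations[dark])) if durations[dark] else None,
        profile_30min=profile / n_days,
        n_days=n_days,
    )


@dataclass(frozen=True)
class PhaseActivity:
    """Per-phase mean activity per day for one subject.

    ``means`` maps each phase present in the schedule to total counts in that
    phase divided by the number of full days of its regime.  A trailing
    partial day is excluded; ``excluded_trailing_min`` reports how much.
    """

    means: dict[Phase, float]
    n_days_ld: int
    n_days_dd: int
    excluded_trailing_min: int


def phase_activity(series: ActivitySeries, schedule: LightSchedule) -> PhaseActivity:
    """Mean activity per day in each phase (day/night and, when DD days are
    covered, subjective day/night)."""
    totals: dict[Phase, int] = {}
    days_seen = {"ld": 0, "dd": 0}
    last_covered_end = series.start_time
    for day in schedule.days():
        day_start = schedule.day_start(day)
        day_end = day_start + pd.Timedelta(minutes=MINUTES_PER_DAY)
        if day_start < series.start_time or day_end > series.end_time:
            continue
        days_seen["dd" if schedule.is_dd_day(day) else "ld"] += 1
        last_covered_end = max(last_covered_end, day_end)
        first_bin = int(
            (day_start - series.start_time).total_seconds() // 60 // series.bin_width
        )
        for i in range(first_bin, first_bin + MINUTES_PER_DAY // series.bin_width):
            phase = schedule.phase_of(series.bin_midpoint(i))
            totals[phase] = totals.get(phase, 0) + int(series.counts[i])
    if days_seen["ld"] + days_seen["dd"] == 0:
        raise ValueError("series does not cover a single full schedule day")
    excluded = int(
        (min(series.end_time, schedule.window_end) - last_covered_end).total_seconds() // 60
    )
    means = {}
    for phase, total in totals.items():
        n = days_seen["dd"] if phase.is_subjective else days_seen["ld"]
        means[phase] = total / n
    return PhaseActivity(
        means=means,
        n_days_ld=days_seen["ld"],
        n_days_dd=days_seen["dd"],
        excluded_trailing_min=max(excluded, 0),
    )
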