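"""Light schedules and the timestamp -> phase mapping.

The entrainment regime is a block of 12 h:12 h light:dark (LD) days followed
by a block of constant-darkness (DD) days.  During LD, timestamps map to
``day`` (lights on) or ``night``; during DD they map to ``subjective_day`` /
``subjective_night``, the halves of each DD day obtained by extrapolating the
LD lights-on time.  Phase intervals are half-open ``[lights_on, lights_off)``:
a boundary timestamp belongs to the phase it begins.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import pandas as pd

from .series import MINUTES_PER_DAY, ActivitySeries

PHOTOPERIOD_MIN = 720  # 12 h photophase; only 12:12 regimes are in scope


class Phase(str, Enum):
    DAY = "day"
    NIGHT = "night"
    SUBJECTIVE_DAY = "subjective_day"
    SUBJECTIVE_NIGHT = "subjective_night"

    @property
    def is_subjective(self) -> bool:
        return self in (Phase.SUBJECTIVE_DAY, Phase.SUBJECTIVE_NIGHT)

    @property
    def is_light_phase(self) -> bool:
        """True for the photophase and its DD extrapolation."""
        return self in (Phase.DAY, Phase.SUBJECTIVE_DAY)


class OutOfScheduleError(ValueError):
    """Raised when a timestamp falls outside the scheduled recording window."""


@dataclass(frozen=True)
class LightSchedule:
    """A 12:12 LD entrainment block followed by a DD block.

    Parameters
    ----------
    entrain_days:
        Number of LD days at the start of the recording.
    dd_days:
        Number of constant-darkness days following entrainment.
    lights_on_clock:
        Clock time of lights-on, in minutes after midnight (e.g. 480 = 08:00).
    reference_start:
        Timestamp of the start of the recording window (start of LD day 0).
    photoperiod:
        Length of the photophase in minutes; fixed at 720 (12 h).
    """

    entrain_days: int
    dd_days: int
    lights_on_clock: int
    reference_start: pd.Timestamp
    photoperiod: int = PHOTOPERIOD_MIN

    def __post_init__(self) -> None:
        if self.entrain_days < 0 or self.dd_days < 0:
            raise ValueError("day counts must be non-negative")
        if self.entrain_days + self.dd_days < 1:
            raise ValueError("schedule must span at least one day")
        if self.photoperiod != PHOTOPERIOD_MIN:
            raise ValueError("only 12:12 schedules (photoperiod=720) are supported")
        if not 0 <= self.lights_on_clock < MINUTES_PER_DAY:
            raise ValueError("lights_on_clock must be in [0, 1440)")
        object.__setattr__(
            self, "reference_start", pd.Timestamp(self.reference_start).floor("min")
        )

    # -- window geometry ----------------------------------------------------

    @property
    def total_days(self) -> int:
        return self.entrain_days + self.dd_days

    @property
    def window_end(self) -> pd.Timestamp:
        return self.reference_start + pd.Timedelta(minutes=self.total_days * MINUTES_PER_DAY)

    def day_index(self, t: pd.Timestamp) -> int:
        """0-based schedule day containing ``t`` (days start at reference_start)."""
        delta = (pd.Timestamp(t) - self.reference_start).total_seconds() / 60.0
        if delta < 0 or delta >= self.total_days * MINUTES_PER_DAY:
            raise OutOfScheduleError(
                f"timestamp {t} outside recording window "
                f"[{self.reference_start}, {self.window_end})"
            )
        return int(delta // MINUTES_PER_DAY)

    def is_dd_day(self, day: int) -> bool:
        if not 0 <= day < self.total_days:
            raise OutOfScheduleError(f"day index {day} outside schedule")
        return day >= self.entrain_days

    def day_start(self, day: int) -> pd.Timestamp:
        return self.reference_start + pd.Timedelta(minutes=day * MINUTES_PER_DAY)

    def days(self) -> Iterable[int]:
        return range(self.total_days)

    # -- phase mapping ------------------------------------------------------

    def in_photophase(self, t: pd.Timestamp) -> bool:
        """True if the clock time of ``t`` lies in [lights_on, lights_off)."""
        t = pd.Timestamp(t)
        minutes_after_midnight = t.hour * 60 + t.minute + t.second / 60.0
        return ((minutes_after_midnight - self.lights_on_clock) % MINUTES_PER_DAY
                < self.photoperiod)

    def phase_of(self, t) -> Phase:
        """Map a timestamp to day/night (LD) or subjective day/night (DD)."""
        t = pd.Timestamp(t)
        dd = self.is_dd_day(self.day_index(t))
        light = self.in_photophase(t)
        if dd:
            return Phase.SUBJECTIVE_DAY if light else Phase.SUBJECTIVE_NIGHT
        return Phase.DAY if light else Phase.NIGHT

    def starts_on_phase_boundary(self) -> bool:
        """True if reference_start falls exactly at lights-on or lights-off."""
        mam = self.reference_start.hour * 60 + self.reference_start.minute
        offset = (mam - self.lights_on_clock) % MINUTES_PER_DAY
        return offset in (0, self.photoperiod)

    # -- serialisation ------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "LightSchedule":
        return cls(
            entrain_days=int(cfg["entrain_days"]),
            dd_days=int(cfg.get("dd_days", 0)),
            lights_on_clock=_parse_clock(cfg["lights_on"]),
            reference_start=pd.Timestamp(cfg["reference_start"]),
        )

    def to_dict(self) -> dict:
        return {
            "entrain_days": self.entrain_days,
            "dd_days": self.dd_days,
            "lights_on": f"{self.lights_on_clock // 60:02d}:{self.lights_on_clock % 60:02d}",
            "reference_start": self.reference_start.isoformat(),
        }


def _parse_clock(value) -> int:
    """Accept minutes-after-midnight or an 'HH:MM' clock string."""
    if isinstance(value, (int, float)):
        return int(value)
    hh, mm = str(value).split(":")
    return int(hh) * 60 + int(mm)


def phase_of(t, schedule: LightSchedule) -> Phase:
    """Functional form of :meth:`LightSchedule.phase_of`."""
    return schedule.phase_of(t)


def slice_phase(
    series: ActivitySeries, schedule: LightSchedule, phase: Phase
) -> list[ActivitySeries]:
    """Extract, for each full schedule day the series covers, the sub-series of
    bins whose midpoint maps to ``phase``.

    Returns one contiguous :class:`ActivitySeries` per matching day; an empty
    list when the requested phase never occurs (e.g. a subjective phase
    requested for an LD-only schedule).  Requires the schedule to start on a
    phase boundary so that each day's phase block is contiguous.
    """
    if not schedule.starts_on_phase_boundary():
        raise ValueError(
            "slice_phase requires reference_start at lights-on or lights-off so "
            "each per-day phase slice is a single contiguous block"
        )
    bins_per_day = MINUTES_PER_DAY // series.bin_width
    out: list[ActivitySeries] = []
    for day in schedule.days():
        day_start = schedule.day_start(day)
        if day_start < series.start_time:
            continue
        day_end = day_start + pd.Timedelta(minutes=MINUTES_PER_DAY)
        if day_end > series.end_time:
            break  # partial trailing day: excluded
        first_bin = int(
            (day_start - series.start_time).total_seconds() // 60 // series.bin_width
        )
        idx = [
            i
            for i in range(first_bin, first_bin + bins_per_day)
            if schedule.phase_of(series.bin_midpoint(i)) == phase
        ]
        if not idx:
            continue
        if idx != list(range(idx[0], idx[-1] + 1)):  # pragma: no cover - guarded above
            raise ValueError("phase slice is not contiguous; check schedule alignment")
        out.append(
            ActivitySeries(
                subject_id=series.subject_id,
                start_time=series.bin_start(idx[0]),
                bin_width=series.bin_width,
                counts=series.counts[idx[0] : idx[-1] + 1],
                modality=series.modality,
            )
        )
    return out
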