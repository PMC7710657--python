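"""Activity time series: the core container for per-bin behavioural counts.

An :class:`ActivitySeries` holds one subject's non-negative integer counts in
contiguous, fixed-width time bins.  Counts may be beam-break locomotion counts
(isolated foragers in monitor tubes) or foraging-trip events (colony foragers);
downstream analyses treat both identically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

MINUTES_PER_DAY = 1440


class Modality(str, Enum):
    """What a count represents: tube locomotion or colony foraging trips."""

    LOCOMOTION = "locomotion"
    FORAGING_TRIPS = "foraging_trips"


@dataclass(frozen=True)
class ActivitySeries:
    """One subject's binned activity counts.

    Parameters
    ----------
    subject_id:
        Stable identifier for the animal (or monitor channel).
    start_time:
        Timestamp of the left edge of the first bin, minute resolution.
    bin_width:
        Bin width in minutes; must divide 1440 so day boundaries align.
    counts:
        Non-negative integer counts, one per bin, contiguous in time.
    modality:
        Whether counts are locomotion beam breaks or foraging-trip events.
    """

    subject_id: str
    start_time: pd.Timestamp
    bin_width: int
    counts: np.ndarray
    modality: Modality = Modality.LOCOMOTION

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not (isinstance(self.bin_width, (int, np.integer)) and self.bin_width > 0):
            raise ValueError("bin_width must be a positive integer number of minutes")
        if MINUTES_PER_DAY % int(self.bin_width) != 0:
            raise ValueError(
                f"bin_width={self.bin_width} must divide {MINUTES_PER_DAY} "
                "so that day boundaries align with bin edges"
            )
        start = pd.Timestamp(self.start_time).floor("min")
        object.__setattr__(self, "start_time", start)
        object.__setattr__(self, "bin_width", int(self.bin_width))
        counts = counts.astype(np.int64)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    # -- derived geometry ---------------------------------------------------

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def duration_min(self) -> int:
        """Total span in minutes."""
        return self.n_bins * self.bin_width

    @property
    def end_time(self) -> pd.Timestamp:
        """Right edge (exclusive) of the last bin."""
        return self.start_time + pd.Timedelta(minutes=self.duration_min)

    def bin_start(self, i: int) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(minutes=i * self.bin_width)

    def bin_midpoint(self, i: int) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(
            seconds=(i * self.bin_width + self.bin_width / 2.0) * 60
        )

    def times(self) -> pd.DatetimeIndex:
        """Left edges of all bins."""
        return pd.date_range(
            self.start_time, periods=self.n_bins, freq=f"{self.bin_width}min"
        )

    def total(self) -> int:
        return int(self.counts.sum())

    def with_counts(self, counts: np.ndarray) -> "ActivitySeries":
        return replace(self, counts=counts)


def rebin(series: ActivitySeries, new_width: int) -> ActivitySeries:
    """Aggregate a series into wider bins by summing counts.

    ``new_width`` must be a positive multiple of the current bin width and the
    series length must divide evenly into the new bins (no ragged tail).  The
    total count is conserved and ``start_time`` is unchanged.
    """
    new_width = int(new_width)
    if new_width <= 0 or new_width % series.bin_width != 0:
        raise ValueError(
            f"new_width={new_width} must be a positive multiple of the current "
            f"bin width ({series.bin_width} min)"
        )
    if new_width == series.bin_width:
        return series
    ratio = new_width // series.bin_width
    if series.n_bins % ratio != 0:
        raise ValueError(
            f"cannot rebin {series.n_bins} bins of {series.bin_width} min into "
            f"{new_width}-min bins: ragged tail of {series.n_bins % ratio} bins"
        )
    summed = series.counts.reshape(-1, ratio).sum(axis=1)
    return replace(series, bin_width=new_width, counts=summed)
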