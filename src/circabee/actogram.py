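"""Actogram matrices: day-by-day rasters of activity versus time of day.

The matrix is the analysis object; rendering to an image is a thin optional
layer (:func:`plot_actogram`).  Double-plotting places day *i* and day *i+1*
side by side on row *i* to make phase drift visible; the second half of the
last row, which has no following day, is NaN-padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import MINUTES_PER_DAY, ActivitySeries, rebin


@dataclass(frozen=True)
class ActogramMatrix:
    values: np.ndarray  # (n_days, bins_per_day) or (n_days, 2*bins_per_day)
    bin_width: int
    double_plot: bool
    start_time: pd.Timestamp
    subject_id: str

    @property
    def n_days(self) -> int:
        return self.values.shape[0]


def actogram_matrix(
    series: ActivitySeries, bin_width: int = 30, double_plot: bool = False
) -> ActogramMatrix:
    """Build a (double-plotted) actogram matrix from a series spanning at
    least one full day; a trailing partial day is dropped."""
    bins_per_day_raw = MINUTES_PER_DAY // series.bin_width
    n_days = series.n_bins // bins_per_day_raw
    if n_days < 1:
        raise ValueError("actogram requires at least one full day of data")
    trimmed = ActivitySeries(
        subject_id=series.subject_id,
        start_time=series.start_time,
        bin_width=series.bin_width,
        counts=series.counts[: n_days * bins_per_day_raw],
        modality=series.modality,
    )
    trimmed = rebin(trimmed, bin_width)
    per_day = MINUTES_PER_DAY // bin_width
    single = trimmed.counts.astype(float).reshape(n_days, per_day)
    if not double_plot:
        values = single
    else:
        values = np.full((n_days, 2 * per_day), np.nan)
        values[:, :per_day] = single
        values[:-1, per_day:] = single[1:]
    return ActogramMatrix(
        values=values,
        bin_width=bin_width,
        double_plot=double_plot,
        start_time=trimmed.start_time,
        subject_id=series.subject_id,
    )


def plot_actogram(matrix: ActogramMatrix, ax=None):
    """Render an actogram matrix as a bar raster (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.6 * matrix.n_days + 1))
    width_h = matrix.values.shape[1] * matrix.bin_width / 60.0
    hours = np.arange(matrix.values.shape[1]) * matrix.bin_width / 60.0
    vmax = np.nanmax(matrix.values) or 1.0
    for row in range(matrix.n_days):
        base = matrix.n_days - row - 1
        heights = np.nan_to_num(matrix.values[row]) / vmax * 0.9
        ax.bar(hours, heights, width=matrix.bin_width / 60.0, bottom=base,
               align="edge", color="black")
    ax.set_xlim(0, width_h)
    ax.set_ylim(0, matrix.n_days)
    ax.set_xlabel("time (h)" + (" — double-plotted" if matrix.double_plot else ""))
    ax.set_ylabel("day")
    ax.set_yticks(np.arange(matrix.n_days) + 0.5,
                  labels=[str(d) for d in range(matrix.n_days, 0, -1)])
    ax.set_title(matrix.subject_id)
    return ax
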