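"""Autocorrelation-based rhythm strength (RS) and arrhythmicity classification.

The rhythmicity statistic is the height of the circadian autocorrelation peak
divided by the 95 % white-noise confidence line 2/sqrt(N), where N is the
number of bins analysed.  A subject with RS <= 1.5 is classified arrhythmic,
the conventional cut-off for this statistic.

The autocorrelogram uses the standard biased, mean-centred, variance-normalised
estimator

    acf[k] = sum_i (y_i - ybar)(y_{i+k} - ybar) / sum_i (y_i - ybar)^2

whose lag-0 value is exactly 1 and whose values lie in [-1, 1].  The circadian
peak is the highest interior local maximum of the correlogram within a lag
window around 24 h (default 18-30 h); the lag of that peak is the period
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .series import ActivitySeries, rebin

#: analysis bin width in minutes; rhythmicity is always computed on 30-min bins
ANALYSIS_BIN_MIN = 30
#: RS at or below this value is classified arrhythmic
RS_THRESHOLD = 1.5
#: default circadian peak search window, hours of lag
SEARCH_WINDOW_HOURS = (18.0, 30.0)
#: default maximum lag of the correlogram, hours
MAX_LAG_HOURS = 48.0


class ConstantSeriesError(ValueError):
    """The series has zero variance, so the autocorrelation is undefined."""


@dataclass(frozen=True)
class RhythmicityResult:
    """Outcome of the RS computation for one subject (one lighting regime).

    ``degenerate`` is set when the input had zero variance: the ACF is
    undefined and the subject is labelled arrhythmic by convention with
    ``rs = 0``.
    """

    acf: np.ndarray
    n_bins: int
    confidence_line: float
    peak_lag_hours: float
    peak_height: float
    rs: float
    label: str  # "rhythmic" | "arrhythmic"
    estimated_period_hours: float
    degenerate: bool = False

    @property
    def is_arrhythmic(self) -> bool:
        return self.label == "arrhythmic"


def autocorrelogram(series: ActivitySeries, max_lag_hours: float = MAX_LAG_HOURS) -> np.ndarray:
    """Normalised autocorrelation of a series out to ``max_lag_hours``.

    Computed with FFT-based convolution (O(N log N)); equivalent to the direct
    sum definition above.  Requires at least twice the maximum lag of data and
    a non-constant series.
    """
    y = series.counts.astype(float)
    n = y.size
    max_lag_bins = int(max_lag_hours * 60 // series.bin_width)
    if n * series.bin_width < 2 * max_lag_hours * 60:
        raise ValueError(
            f"series spans {n * series.bin_width} min; need at least "
            f"{2 * max_lag_hours:g} h of data for a {max_lag_hours:g} h correlogram"
        )
    d = y - y.mean()
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise ConstantSeriesError(
            f"series {series.subject_id!r} is constant; autocorrelation undefined"
        )
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(d, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag_bins + 1]
    return acov / denom


def _direct_autocorrelogram(y: Sequence[float], max_lag_bins: int) -> np.ndarray:
    """O(N^2) direct-sum reference implementation (used as a cross-check)."""
    y = np.asarray(y, dtype=float)
    d = y - y.mean()
    denom = float(np.dot(d, d))
    out = np.empty(max_lag_bins + 1)
    for k in range(max_lag_bins + 1):
        s = 0.0
        for i in range(len(y) - k):
            s += d[i] * d[i + k]
        out[k] = s / denom
    return out


def rhythm_statistic(
    acf: np.ndarray,
    n_bins: int,
    bin_width_min: int = ANALYSIS_BIN_MIN,
    search_window_hours: tuple[float, float] = SEARCH_WINDOW_HOURS,
    rs_threshold: float = RS_THRESHOLD,
) -> RhythmicityResult:
    """Select the circadian peak of a correlogram and form the RS ratio.

    The peak is the highest interior local maximum within the lag window,
    falling back to the window's maximum value when no interior local maximum
    exists.  ``rs = peak_height / (2/sqrt(n_bins))``; RS <= threshold is
    labelled arrhythmic (boundary inclusive on the arrhythmic side).
    """
    acf = np.asarray(acf, dtype=float)
    lo_h, hi_h = search_window_hours
    lo = int(np.ceil(lo_h * 60 / bin_width_min))
    hi = int(np.floor(hi_h * 60 / bin_width_min))
    if lo < 1 or hi >= acf.size or lo > hi:
        raise ValueError(
            f"search window {search_window_hours} h outside computed lags "
            f"(acf has {acf.size - 1} lags of {bin_width_min} min)"
        )
    window = np.arange(lo, hi + 1)
    interior = window[(acf[window] >= acf[window - 1]) & (acf[window] >= acf[window + 1])]
    if interior.size:
        peak_lag = int(interior[np.argmax(acf[interior])])
    else:
        peak_lag = int(window[np.argmax(acf[window])])
    peak_height = float(acf[peak_lag])
    confidence = 2.0 / np.sqrt(n_bins)
    rs = peak_height / confidence
    peak_lag_hours = peak_lag * bin_width_min / 60.0
    return RhythmicityResult(
        acf=acf,
        n_bins=int(n_bins),
        confidence_line=confidence,
        peak_lag_hours=peak_lag_hours,
        peak_height=peak_height,
        rs=float(rs),
        label="arrhythmic" if rs <= rs_threshold else "rhythmic",
        estimated_period_hours=peak_lag_hours,
    )


def compute_rhythmicity(
    series: ActivitySeries,
    max_lag_hours: float = MAX_LAG_HOURS,
    search_window_hours: tuple[float, float] = SEARCH_WINDOW_HOURS,
    rs_threshold: float = RS_THRESHOLD,
    analysis_bin_min: int = ANALYSIS_BIN_MIN,
) -> RhythmicityResult:
    """End-to-end RS for one series: rebin to the analysis width, correlate,
    pick the circadian peak.

    A constant (zero-variance) series cannot be correlated; it is returned as
    arrhythmic with ``degenerate=True`` and ``rs = 0``.
    """
    if series.bin_width != analysis_bin_min:
        series = rebin(series, analysis_bin_min)
    try:
        acf = autocorrelogram(series, max_lag_hours=max_lag_hours)
    except ConstantSeriesError:
        return RhythmicityResult(
            acf=np.empty(0),
            n_bins=series.n_bins,
            confidence_line=2.0 / np.sqrt(series.n_bins),
            peak_lag_hours=float("nan"),
            peak_height=float("nan"),
            rs=0.0,
            label="arrhythmic",
            estimated_period_hours=float("nan"),
            degenerate=True,
        )
    return rhythm_statistic(
        acf,
        n_bins=series.n_bins,
        bin_width_min=analysis_bin_min,
        search_window_hours=search_window_hours,
        rs_threshold=rs_threshold,
    )


def arrhythmic_proportion(results: Iterable[RhythmicityResult]) -> tuple[float, int]:
    """Percentage of subjects labelled arrhythmic, with the group n."""
    results = list(results)
    if not results:
        raise ValueError("cannot compute a proportion of an empty collection")
    n_arr = sum(r.is_arrhythmic for r in results)
    return 100.0 * n_arr / len(results), len(results)
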