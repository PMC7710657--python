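"""Readers and writers for activity-monitor data.

Two on-disk dialects are supported:

``canonical_csv``
    Long-format CSV with a mandatory header ``subject_id,timestamp,count``;
    timestamps are ISO-8601 at minute resolution.  The simplest lossless
    interchange format.
``dam_tsv``
    The de-facto tab-separated dialect of locomotor activity monitors: one
    row per time step with columns *index, date, time, status, six reserved
    status fields, then 32 integer channel columns*.  Only rows whose status
    field is 1 (OK) are ingested.  Channel-to-subject assignment travels in a
    separate :class:`dict` (``channel_map``), since the format itself carries
    no subject names.

Both readers infer the bin width from the timestamp step and reject files
whose timestamps are not uniformly spaced, naming the first offending line.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .series import ActivitySeries, Modality

N_DAM_CHANNELS = 32
_DAM_META_COLS = 10  # index, date, time, status, 6 reserved


class Dialect(str, Enum):
    DAM_TSV = "dam_tsv"
    CANONICAL_CSV = "canonical_csv"


class MonitorFormatError(ValueError):
    """Malformed monitor file (bad structure, gap, or inconsistent step)."""


class MonitorDataError(ValueError):
    """Structurally valid file with invalid data (e.g. negative counts)."""


@dataclass(frozen=True)
class MonitorFile:
    """A monitor data file plus the information needed to interpret it."""

    path: Path
    dialect: Dialect
    channel_map: Optional[Mapping[int, str]] = None  # DAM channel -> subject_id
    modality: Modality = Modality.LOCOMOTION


def read_monitor(source: MonitorFile | str | Path, dialect: Dialect | str | None = None,
                 channel_map: Optional[Mapping[int, str]] = None,
                 modality: Modality = Modality.LOCOMOTION) -> list[ActivitySeries]:
    """Parse a monitor file into one :class:`ActivitySeries` per active channel."""
    if not isinstance(source, MonitorFile):
        if dialect is None:
            raise ValueError("dialect is required when passing a bare path")
        source = MonitorFile(Path(source), Dialect(dialect), channel_map, modality)
    path = Path(source.path)
    if not path.exists():
        raise FileNotFoundError(path)
    if source.dialect == Dialect.CANONICAL_CSV:
        return _read_canonical(path, source.modality)
    return _read_dam(path, source.channel_map, source.modality)


def _check_uniform(times: pd.DatetimeIndex, line_numbers: Sequence[int], label: str) -> int:
    """Return the constant step in minutes, or raise naming the first bad line."""
    if len(times) < 1:
        raise MonitorFormatError(f"{label}: no data rows")
    if len(times) == 1:
        return 1  # single bin: default to 1-min resolution
    steps = np.diff(times.asi8) // 60_000_000_000
    if steps[0] <= 0:
        raise MonitorFormatError(
            f"{label}: non-increasing timestamp at line {line_numbers[1]}"
        )
    bad = np.flatnonzero(steps != steps[0])
    if bad.size:
        raise MonitorFormatError(
            f"{label}: inconsistent timestamp step at line "
            f"{line_numbers[int(bad[0]) + 1]} (expected {int(steps[0])} min, "
            f"got {int(steps[bad[0]])} min)"
        )
    return int(steps[0])


def _read_canonical(path: Path, modality: Modality) -> list[ActivitySeries]:
    df = pd.read_csv(path)
    expected = ["subject_id", "timestamp", "count"]
    if list(df.columns) != expected:
        raise MonitorFormatError(
            f"{path}: expected header {','.join(expected)}, got {','.join(df.columns)}"
        )
    if df.empty:
        raise MonitorFormatError(f"{path}: no data rows")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    except (ValueError, TypeError) as exc:
        raise MonitorFormatError(f"{path}: unparseable timestamp ({exc})") from exc
    if (df["count"] < 0).any():
        line = int(df.index[df["count"] < 0][0]) + 2
        raise MonitorDataError(f"{path}: negative count at line {line}")
    out = []
    for subject, grp in df.groupby("subject_id", sort=False):
        lines = (grp.index + 2).tolist()  # +1 header, +1 one-based
        times = pd.DatetimeIndex(grp["timestamp"])
        step = _check_uniform(times, lines, f"{path} [{subject}]")
        out.append(
            ActivitySeries(
                subject_id=str(subject),
                start_time=times[0],
                bin_width=step,
                counts=grp["count"].to_numpy(),
                modality=modality,
            )
        )
    return out


def _read_dam(path: Path, channel_map: Optional[Mapping[int, str]],
              modality: Modality) -> list[ActivitySeries]:
    times, rows, lines = [], [], []
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or all(not f.strip() for f in raw):
                continue
            if len(raw) != _DAM_META_COLS + N_DAM_CHANNELS:
                raise MonitorFormatError(
                    f"{path}: line {lineno}: expected "
                    f"{_DAM_META_COLS + N_DAM_CHANNELS} tab-separated fields, got {len(raw)}"
                )
            if raw[3].strip() != "1":  # non-OK status rows are skipped
                continue
            try:
                t = pd.to_datetime(f"{raw[1]} {raw[2]}", format="%d %b %y %H:%M:%S")
                counts = [int(c) for c in raw[_DAM_META_COLS:]]
            except ValueError as exc:
                raise MonitorFormatError(f"{path}: line {lineno}: {exc}") from exc
            if any(c < 0 for c in counts):
                raise MonitorDataError(f"{path}: negative count at line {lineno}")
            times.append(t)
            rows.append(counts)
            lines.append(lineno)
    step = _check_uniform(pd.DatetimeIndex(times), lines, str(path))
    matrix = np.asarray(rows, dtype=np.int64)
    if channel_map is None:
        active = [ch for ch in range(1, N_DAM_CHANNELS + 1) if matrix[:, ch - 1].any()]
        channel_map = {ch: f"ch{ch:02d}" for ch in active}
    out = []
    for ch in sorted(channel_map):
        if not 1 <= ch <= N_DAM_CHANNELS:
            raise MonitorFormatError(f"channel {ch} outside 1..{N_DAM_CHANNELS}")
        out.append(
            ActivitySeries(
                subject_id=channel_map[ch],
                start_time=times[0],
                bin_width=step,
                counts=matrix[:, ch - 1],
                modality=modality,
            )
        )
    return out


def write_series(
    collection: Sequence[ActivitySeries],
    path: str | Path,
    dialect: Dialect | str,
) -> Optional[dict[int, str]]:
    """Write a cohort to disk; returns the channel map for the DAM dialect
    (needed to recover subject ids on re-read), ``None`` for canonical CSV.

    All series must share one bin width; the DAM dialect additionally
    requires a common start time and length (its rows span all channels) and
    at most 32 series.
    """
    collection = list(collection)
    if not collection:
        raise ValueError("cannot write an empty collection")
    widths = {s.bin_width for s in collection}
    if len(widths) != 1:
        raise ValueError(f"mixed bin widths {sorted(widths)}; rebin first")
    path = Path(path)
    if Dialect(dialect) == Dialect.CANONICAL_CSV:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["subject_id", "timestamp", "count"])
            for s in collection:
                for t, c in zip(s.times(), s.counts):
                    w.writerow([s.subject_id, t.strftime("%Y-%m-%dT%H:%M"), int(c)])
        return None
    # DAM dialect
    if len(collection) > N_DAM_CHANNELS:
        raise ValueError(f"DAM dialect holds at most {N_DAM_CHANNELS} channels")
    starts = {s.start_time for s in collection}
    lengths = {s.n_bins for s in collection}
    if len(starts) != 1 or len(lengths) != 1:
        raise ValueError("DAM dialect requires a common start time and length")
    ref = collection[0]
    matrix = np.zeros((ref.n_bins, N_DAM_CHANNELS), dtype=np.int64)
    channel_map = {}
    for ch, s in enumerate(collection, start=1):
        matrix[:, ch - 1] = s.counts
        channel_map[ch] = s.subject_id
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for i, t in enumerate(ref.times()):
            meta = [i + 1, t.strftime("%d %b %y").lstrip("0"), t.strftime("%H:%M:%S"),
                    1, 0, 0, 0, 0, 0, 0]
            w.writerow(meta + matrix[i].tolist())
    return channel_map


#: stable column order for the per-subject results table
RESULT_COLUMNS = [
    "subject_id", "group", "regime",
    "rs", "label", "estimated_period_hours", "n_bins",
    "activity_day", "activity_night",
    "sleep_total_day", "sleep_total_night",
    "sleep_bouts_day", "sleep_bouts_night",
    "mean_bout_day", "mean_bout_night",
    "excluded", "exclusion_reason",
]


def export_results_table(rows: Iterable[Mapping], path: str | Path) -> pd.DataFrame:
    """Write per-subject metric records to CSV with a stable column order and
    fixed numeric precision; missing metrics become empty fields."""
    df = pd.DataFrame(list(rows))
    extra = [c for c in df.columns if c not in RESULT_COLUMNS]
    cols = [c for c in RESULT_COLUMNS if c in df.columns] + extra
    df = df.reindex(columns=cols)
    df.to_csv(path, index=False, na_rep="", float_format="%.4f")
    return df
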