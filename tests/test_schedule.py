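"""Phase mapping, rebinning, and phase slicing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circabee import (
    LightSchedule,
    OutOfScheduleError,
    Phase,
    phase_of,
    rebin,
    slice_phase,
)

from .conftest import LIGHTS_ON, START, make_series


class TestActivitySeriesInvariants:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_series([1, -1, 2])

    def test_rejects_non_integer_counts(self):
        with pytest.raises(ValueError, match="integer"):
            make_series([1.5, 2.0])

    def test_rejects_bin_width_not_dividing_day(self):
        with pytest.raises(ValueError, match="divide"):
            make_series([1, 2], bin_width=7)

    def test_rejects_empty(self):
        with pytest.raises(ValueError, match="non-empty"):
            make_series([])

    def test_accepts_integer_valued_floats(self):
        s = make_series(np.array([1.0, 2.0]))
        assert s.counts.dtype == np.int64


class TestPhaseOf:
    def test_minute_after_lights_on_is_day(self, schedule):
        assert phase_of(START + pd.Timedelta(minutes=1), schedule) == Phase.DAY

    def test_lights_on_boundary_is_day(self, schedule):
        # half-open [lights_on, lights_off): boundary belongs to the phase it begins
        assert phase_of(START, schedule) == Phase.DAY

    def test_exact_lights_off_is_night(self, schedule):
        assert phase_of(START + pd.Timedelta(minutes=720), schedule) == Phase.NIGHT

    def test_dd_extrapolated_lights_on_plus_6h_is_subjective_day(self, schedule):
        t = START + pd.Timedelta(days=2, hours=6)  # DD day 0, 6 h after lights-on
        assert phase_of(t, schedule) == Phase.SUBJECTIVE_DAY

    def test_dd_dark_half_is_subjective_night(self, schedule):
        t = START + pd.Timedelta(days=2, hours=18)
        assert phase_of(t, schedule) == Phase.SUBJECTIVE_NIGHT

    def test_ld_days_never_map_to_subjective(self, schedule):
        for h in range(0, 48, 3):
            assert not phase_of(START + pd.Timedelta(hours=h), schedule).is_subjective

    def test_dd_days_always_map_to_subjective(self, schedule):
        for h in range(48, 96, 3):
            assert phase_of(START + pd.Timedelta(hours=h), schedule).is_subjective

    def test_out_of_window_raises(self, schedule):
        with pytest.raises(OutOfScheduleError):
            phase_of(START - pd.Timedelta(minutes=1), schedule)
        with pytest.raises(OutOfScheduleError):
            phase_of(START + pd.Timedelta(days=4), schedule)

    @given(minute=st.integers(0, 1439))
    @settings(max_examples=50, deadline=None)
    def test_periodic_with_1440_min_within_regime(self, minute):
        schedule = LightSchedule(
            entrain_days=2, dd_days=2, lights_on_clock=LIGHTS_ON, reference_start=START
        )
        t0 = START + pd.Timedelta(minutes=minute)
        assert phase_of(t0, schedule) == phase_of(t0 + pd.Timedelta(minutes=1440), schedule)
        t_dd = t0 + pd.Timedelta(days=2)
        assert phase_of(t_dd, schedule) == phase_of(t_dd + pd.Timedelta(minutes=1440), schedule)

    def test_only_twelve_twelve_supported(self):
        with pytest.raises(ValueError, match="12:12"):
            LightSchedule(entrain_days=1, dd_days=0, lights_on_clock=0,
                          reference_start=START, photoperiod=600)


class TestRebin:
    def test_sums_within_groups(self):
        s = rebin(make_series([1] * 60), 30)
        assert list(s.counts) == [30, 30]
        assert s.start_time == START

    def test_identity_width(self):
        s = make_series([3, 1, 4, 1])
        assert rebin(s, 1) is s

    def test_ragged_tail_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            rebin(make_series([1] * 59), 30)

    def test_non_multiple_width_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            rebin(make_series([1] * 60, bin_width=30), 45)

    @given(
        n_groups=st.integers(1, 48),
        ratio=st.sampled_from([2, 3, 5, 6, 10, 30]),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_conserves_total_counts(self, n_groups, ratio, data):
        counts = data.draw(
            st.lists(st.integers(0, 50), min_size=n_groups * ratio,
                     max_size=n_groups * ratio)
        )
        new_width = ratio  # 1-min bins -> ratio-min bins, all divide 1440
        if 1440 % new_width:
            return
        s = make_series(counts)
        r = rebin(s, new_width)
        assert r.total() == s.total()
        assert r.n_bins == n_groups
        assert r.duration_min == s.duration_min


class TestSlicePhase:
    def test_one_ld_day_day_slice(self, schedule):
        s = make_series(np.arange(2 * 1440) % 3)
        (sl0, sl1) = slice_phase(s, schedule, Phase.DAY)
        assert sl0.start_time == START and sl0.duration_min == 720
        assert sl1.start_time == START + pd.Timedelta(days=1)

    def test_day_plus_night_totals_partition_whole_day(self, schedule, rng):
        s = make_series(rng.integers(0, 5, 2 * 1440))
        day = sum(x.total() for x in slice_phase(s, schedule, Phase.DAY))
        night = sum(x.total() for x in slice_phase(s, schedule, Phase.NIGHT))
        assert day + night == s.total()

    def test_two_dd_days_subjective_night(self, schedule, rng):
        s = make_series(rng.integers(0, 5, 4 * 1440))
        slices = slice_phase(s, schedule, Phase.SUBJECTIVE_NIGHT)
        assert len(slices) == 2
        assert all(sl.duration_min == 720 for sl in slices)
        # brute-force per-bin check against phase_of
        for sl in slices:
            for i in range(sl.n_bins):
                assert phase_of(sl.bin_midpoint(i), schedule) == Phase.SUBJECTIVE_NIGHT

    def test_four_phase_slices_reconstitute_series(self, schedule, rng):
        s = make_series(rng.integers(0, 5, 4 * 1440))
        total = sum(
            x.total()
            for ph in Phase
            for x in slice_phase(s, schedule, ph)
        )
        assert total == s.total()

    def test_incompatible_phase_gives_empty(self, ld_schedule, rng):
        s = make_series(rng.integers(0, 5, 4 * 1440))
        assert slice_phase(s, ld_schedule, Phase.SUBJECTIVE_DAY) == []

    def test_requires_phase_boundary_alignment(self, rng):
        sched = LightSchedule(entrain_days=1, dd_days=0, lights_on_clock=300,
                              reference_start=START)
        with pytest.raises(ValueError, match="lights-on"):
            slice_phase(make_series(rng.integers(0, 5, 1440)), sched, Phase.DAY)
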