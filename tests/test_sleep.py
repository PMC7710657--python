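"""Sleep-bout detection, phase apportioning, and per-phase activity."""

import numpy as np
import pandas as pd
import pytest

from circabee import (
    ForagerParams,
    Phase,
    detect_sleep_bouts,
    phase_activity,
    simulate_forager,
    schedule_for,
    summarize_sleep,
)

from .conftest import START, make_series


def true_sleep_runs(state, threshold=5):
    """Independent oracle: runs of True in the latent sleep trace."""
    runs, n = [], 0
    for v in list(state) + [False]:
        if v:
            n += 1
        else:
            if n >= threshold:
                runs.append(n)
            n = 0
    return runs


class TestDetectSleepBouts:
    def test_five_zero_minutes_is_one_bout(self):
        bouts = detect_sleep_bouts(make_series([2, 0, 0, 0, 0, 0, 3]))
        assert len(bouts) == 1
        assert bouts[0].duration_min == 5
        assert bouts[0].start == START + pd.Timedelta(minutes=1)

    def test_run_of_four_is_no_bout(self):
        assert detect_sleep_bouts(make_series([1, 0, 0, 0, 0, 1, 1])) == []

    def test_all_zero_day_is_one_maximal_bout(self):
        bouts = detect_sleep_bouts(make_series([0] * 1440))
        assert len(bouts) == 1 and bouts[0].duration_min == 1440

    def test_wrong_bin_width_instructs_one_minute_input(self):
        with pytest.raises(ValueError, match="1-min"):
            detect_sleep_bouts(make_series([0, 0], bin_width=30))

    def test_bouts_ordered_and_non_overlapping(self, rng):
        s = make_series((rng.random(1440) < 0.5).astype(int))
        bouts = detect_sleep_bouts(s)
        for a, b in zip(bouts, bouts[1:]):
            assert a.end <= b.start

    def test_detection_is_idempotent(self, rng):
        s = make_series((rng.random(1440) < 0.5).astype(int))
        assert detect_sleep_bouts(s) == detect_sleep_bouts(s)

    def test_total_sleep_non_increasing_in_threshold(self, rng):
        s = make_series((rng.random(2880) < 0.6).astype(int))
        totals = [
            sum(b.duration_min for b in detect_sleep_bouts(s, threshold=k))
            for k in range(1, 16)
        ]
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestSummarizeSleep:
    def test_bout_inside_day_counts_only_day(self, ld_schedule):
        counts = np.ones(4 * 1440, dtype=int)
        counts[60:70] = 0  # 10-min bout 1 h after lights-on
        bouts = detect_sleep_bouts(make_series(counts), schedule=ld_schedule)
        s = summarize_sleep(bouts, ld_schedule)
        assert s.total_sleep_day == 10 and s.bouts_day == 1
        assert s.total_sleep_night == 0 and s.bouts_night == 0
        assert s.mean_bout_day == 10 and s.mean_bout_night is None

    def test_bout_straddling_lights_off_apportioned_by_minute(self, ld_schedule):
        # 20-min bout starting 10 min before lights-off: hand-enumerated,
        # episode counted at its start (day); 10 min day + 10 min night
        counts = np.ones(4 * 1440, dtype=int)
        counts[710:730] = 0
        bouts = detect_sleep_bouts(make_series(counts), schedule=ld_schedule)
        s = summarize_sleep(bouts, ld_schedule)
        assert s.bouts_day == 1 and s.bouts_night == 0
        assert s.total_sleep_day == 10 and s.total_sleep_night == 10
        assert s.mean_bout_day == 20

    def test_minutes_conserved_across_phases(self):
        params = ForagerParams(n_days_ld=3, n_days_dd=0, seed=11)
        series, _ = simulate_forager(params)
        sched = schedule_for(params)
        bouts = detect_sleep_bouts(series, schedule=sched)
        s = summarize_sleep(bouts, sched)
        assert s.total_sleep_day + s.total_sleep_night == sum(
            b.duration_min for b in bouts
        )

    def test_profile_values_within_bin_capacity(self):
        params = ForagerParams(n_days_ld=3, n_days_dd=0, seed=12,
                               sleep_onset_rate_day=0.02)
        series, _ = simulate_forager(params)
        sched = schedule_for(params)
        s = summarize_sleep(detect_sleep_bouts(series, schedule=sched), sched)
        assert s.profile_30min.shape == (48,)
        assert np.all(s.profile_30min >= 0) and np.all(s.profile_30min <= 30)
        # profile integrates to the same minutes as the phase totals
        assert s.profile_30min.sum() * s.n_days == pytest.approx(
            s.total_sleep_day + s.total_sleep_night
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_ground_truth_recovered_exactly(self, seed):
        # sleep fully suppresses counts and waking minutes always register
        # activity, so detected bouts == latent sleep runs >= threshold
        params = ForagerParams(n_days_ld=2, n_days_dd=2, seed=seed,
                               sleep_onset_rate_day=0.01,
                               sleep_onset_rate_night=0.03)
        series, truth = simulate_forager(params)
        bouts = detect_sleep_bouts(series)
        runs = true_sleep_runs(truth.sleep_state)
        assert [b.duration_min for b in bouts] == runs


class TestPhaseActivity:
    def test_constant_rate_splits_evenly(self, ld_schedule):
        s = make_series(np.ones(4 * 1440, dtype=int))
        act = phase_activity(s, ld_schedule)
        assert act.means[Phase.DAY] == 720 and act.means[Phase.NIGHT] == 720

    def test_photophase_only_activity_gives_zero_night(self, ld_schedule):
        counts = np.zeros(4 * 1440, dtype=int)
        for d in range(4):
            counts[d * 1440 : d * 1440 + 720] = 2
        act = phase_activity(make_series(counts), ld_schedule)
        assert act.means[Phase.NIGHT] == 0 and act.means[Phase.DAY] == 1440

    def test_matches_brute_force_per_bin_sum(self, schedule, rng):
        s = make_series(rng.integers(0, 6, 4 * 1440))
        act = phase_activity(s, schedule)
        brute = {ph: 0 for ph in Phase}
        for i in range(s.n_bins):
            brute[schedule.phase_of(s.bin_midpoint(i))] += int(s.counts[i])
        for ph in Phase:
            n_days = 2  # 2 LD + 2 DD full days in this fixture
            assert act.means[ph] == pytest.approx(brute[ph] / n_days)

    def test_trailing_partial_day_excluded_and_reported(self, ld_schedule, rng):
        s = make_series(rng.integers(0, 6, 2 * 1440 + 100))
        act = phase_activity(s, ld_schedule)
        assert act.n_days_ld == 2
        assert act.excluded_trailing_min == 100

    def test_no_full_day_rejected(self, ld_schedule, rng):
        with pytest.raises(ValueError, match="full"):
            phase_activity(make_series(rng.integers(0, 6, 600)), ld_schedule)
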