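"""Dedup, coverage and resampling rules against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from predeath.preprocess import (CohortMatrices, align_to_death,
                                 coverage_filter, dedup_first_per_day,
                                 resample_cohort, resample_moving_average)
from _oracles import brute_force_window_mean
from conftest import tiny_events


class TestDedup:
    def test_first_same_day_result_kept(self):
        ev = pd.DataFrame({
            "patient_id": ["a", "a"],
            "days_before_death": [3, 3],
            "parameter": ["alb", "alb"],
            "value": [3.1, 2.9],
            "timestamp": ["2019-01-01T08:00", "2019-01-01T15:00"],
        })
        out = dedup_first_per_day(ev)
        assert len(out) == 1 and out["value"].iloc[0] == 3.1

    def test_idempotent_without_duplicates(self):
        ev = tiny_events([("a", 1, "alb", 3.0), ("a", 2, "alb", 2.9)])
        pd.testing.assert_frame_equal(dedup_first_per_day(ev), ev)

    def test_untimestamped_ties_keep_input_order_with_warning(self):
        ev = tiny_events([("a", 3, "alb", 3.1), ("a", 3, "alb", 2.9)])
        with pytest.warns(UserWarning):
            out = dedup_first_per_day(ev)
        assert out["value"].tolist() == [3.1]


class TestCoverage:
    @staticmethod
    def _cohort(n_with, n_total):
        rows = [(f"p{i}", 1, "x", 1.0) for i in range(n_total)]
        rows += [(f"p{i}", 2, "y", 1.0) for i in range(n_with)]
        return tiny_events(rows)

    def test_strict_majority_kept(self):
        kept, _ = coverage_filter(self._cohort(51, 100))
        assert "y" in kept

    def test_exact_half_dropped(self):
        kept, _ = coverage_filter(self._cohort(50, 100))
        assert kept == ["x"]

    def test_zero_threshold_keeps_everything(self):
        kept, _ = coverage_filter(self._cohort(1, 100),
                                  min_patient_fraction=0.0)
        assert kept == ["x", "y"]

    def test_patients_lacking_a_retained_parameter_are_flagged(self):
        kept, excluded = coverage_filter(self._cohort(60, 100))
        assert set(kept) == {"x", "y"}
        assert len(excluded) == 40 and "p99" in excluded


class TestResampler:
    def test_two_event_window_mean(self):
        ev = tiny_events([("a", 10, "x", 2.0), ("a", 12, "x", 4.0)])
        grid = resample_moving_average(ev, window_days=5, t_max=20)
        assert grid.loc[11, "x"] == pytest.approx(3.0)

    def test_constant_series_everywhere(self):
        ev = tiny_events([("a", d, "x", 7.0) for d in range(0, 21, 2)])
        grid = resample_moving_average(ev, window_days=5, t_max=20)
        observed = grid["x"].dropna()
        assert (observed == 7.0).all()

    def test_empty_window_masked(self):
        ev = tiny_events([("a", 0, "x", 1.0), ("a", 20, "x", 2.0)])
        grid = resample_moving_average(ev, window_days=5, t_max=20)
        assert np.isnan(grid.loc[10, "x"])

    def test_window_must_be_positive(self):
        ev = tiny_events([("a", 0, "x", 1.0)])
        with pytest.raises(ValueError):
            resample_moving_average(ev, window_days=0)

    @settings(max_examples=60, deadline=None)
    @given(data=st.data(),
           align=st.sampled_from(["centered", "trailing"]),
           window=st.integers(min_value=1, max_value=7))
    def test_matches_brute_force_oracle(self, data, align, window):
        days = data.draw(st.lists(st.integers(0, 25), min_size=1,
                                  max_size=12, unique=True))
        values = data.draw(st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=len(days),
            max_size=len(days)))
        ev = tiny_events([("a", d, "x", v) for d, v in zip(days, values)])
        grid = resample_moving_average(ev, window_days=window, t_max=25,
                                       align=align)
        for t in range(26):
            expected = brute_force_window_mean(days, values, t, window,
                                               align)
            got = grid.loc[t, "x"]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(4)
        days = rng.choice(np.arange(5, 40), size=10, replace=False)
        values = rng.normal(size=10)
        ev = tiny_events([("a", int(d), "x", v)
                          for d, v in zip(days, values)])
        ev_shift = tiny_events([("a", int(d) + 5, "x", v)
                                for d, v in zip(days, values)])
        g1 = resample_moving_average(ev, window_days=5, t_max=60)
        g2 = resample_moving_average(ev_shift, window_days=5, t_max=60)
        # interior cells: translating all events by +5 translates the grid
        for t in range(5, 45):
            a, b = g1.loc[t, "x"], g2.loc[t + 5, "x"]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestDayVectors:
    def test_day_vector_round_trips_through_tidy_csv(self, tmp_path):
        ev = tiny_events([("a", d, p, float(d + i))
                          for d in (0, 3, 7) for i, p in enumerate("xy")])
        mats = resample_cohort(ev, window_days=5, t_max=10)
        path = tmp_path / "m.csv"
        mats.to_tidy().to_csv(path, index=False)
        reloaded = CohortMatrices.from_tidy(pd.read_csv(path))
        for t in (0, 5, 10):
            pd.testing.assert_series_equal(mats.day_vector("a", t),
                                           reloaded.day_vector("a", t))

    def test_fully_masked_day_is_all_missing(self):
        ev = tiny_events([("a", 0, "x", 1.0)])
        mats = resample_cohort(ev, window_days=5, t_max=20)
        assert mats.day_vector("a", 15).isna().all()
        assert not mats.day_vector("a", 1).isna().any()

    def test_day_outside_grid_rejected(self):
        ev = tiny_events([("a", 0, "x", 1.0)])
        mats = resample_cohort(ev, window_days=5, t_max=10)
        with pytest.raises(ValueError):
            mats.day_vector("a", 11)


class TestCalendarAlignment:
    def test_calendar_events_convert_to_days_before_death(self):
        ev = pd.DataFrame({
            "patient_id": ["a", "a", "a"],
            "timestamp": ["2020-01-01", "2020-01-09", "2020-01-12"],
            "parameter": ["x"] * 3,
            "value": [1.0, 2.0, 3.0],
        })
        deaths = pd.DataFrame({"patient_id": ["a"],
                               "death_date": ["2020-01-10"]})
        out = align_to_death(ev, deaths)
        # the post-death event is dropped
        assert out["days_before_death"].tolist() == [9, 1]
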