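"""Cleaning cascade: range rule, neighbour rule, beat error, resampling, diary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from workhrr import ibi_qc
from workhrr.types import DiaryInterval, HrSeries4Hz, IbiSeries

from conftest import make_series


class TestHrRangeFilter:
    @pytest.mark.parametrize(
        "ibi_ms, kept",
        [
            (2000.0, False),  # 30 bpm, below the 36 bpm floor
            (800.0, True),  # 75 bpm, mid-range
            (60000.0 / 36.0, True),  # exactly 36 bpm: rule is strict 'less than'
            (300.0, True),  # exactly 200 bpm: strict 'greater than'
            (250.0, False),  # 240 bpm
        ],
    )
    def test_boundary_semantics(self, ibi_ms, kept):
        s = make_series([800.0, ibi_ms, 800.0])
        out, report = ibi_qc.filter_hr_range(s)
        assert (ibi_ms in out.ibi_ms) == kept
        assert report.n_input == 3
        assert report.n_removed_range == (0 if kept else 1)

    def test_empty_input(self):
        out, report = ibi_qc.filter_hr_range(make_series([]))
        assert len(out) == 0 and report.n_input == 0


class TestNeighborFilter:
    def test_isolated_outlier_removed(self):
        s = make_series([800.0, 800.0, 1000.0, 800.0, 800.0])
        out, report = ibi_qc.filter_neighbor_deviation(s)
        assert report.n_removed_neighbor == 1
        assert 1000.0 not in out.ibi_ms
        assert list(out.ibi_ms) == [800.0] * 4

    def test_constant_sequence_untouched(self):
        s = make_series([900.0] * 50)
        out, _ = ibi_qc.filter_neighbor_deviation(s)
        assert len(out) == 50

    def test_gentle_ramp_untouched(self):
        # each step is 14% relative to the previous interval, under the 15% rule
        ibis = 600.0 * 1.14 ** np.arange(8)
        out, _ = ibi_qc.filter_neighbor_deviation(make_series(ibis))
        assert len(out) == 8

    def test_short_series_unchanged(self):
        s = make_series([500.0])
        out, _ = ibi_qc.filter_neighbor_deviation(s)
        assert len(out) == 1

    def test_output_is_subset_of_input(self, rng):
        ibis = rng.uniform(400.0, 1400.0, size=200)
        s = make_series(ibis)
        out, _ = ibi_qc.filter_neighbor_deviation(s)
        assert set(out.time_s) <= set(s.time_s)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=300.0, max_value=1660.0), min_size=2, max_size=40))
    def test_idempotent(self, ibis):
        s = make_series(ibis)
        once, _ = ibi_qc.filter_neighbor_deviation(s)
        twice, rep = ibi_qc.filter_neighbor_deviation(once)
        assert rep.n_removed_neighbor == 0
        assert np.array_equal(once.ibi_ms, twice.ibi_ms)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=301.0, max_value=1660.0), min_size=1, max_size=40))
    def test_range_filter_idempotent(self, ibis):
        s = make_series(ibis)
        once, _ = ibi_qc.filter_hr_range(s)
        twice, rep = ibi_qc.filter_hr_range(once)
        assert rep.n_removed_range == 0
        assert np.array_equal(once.ibi_ms, twice.ibi_ms)


class TestBeatErrorExclusion:
    def test_bad_epoch_removed(self):
        # one-minute epoch with 40/60 flagged (67%) followed by a clean epoch
        flags = [True] * 40 + [False] * 20 + [False] * 60
        s = make_series([1000.0] * 120, error_flag=flags)
        out, report = ibi_qc.exclude_by_beat_error(s)
        assert report.n_epochs_excluded == 1
        assert not out.error_flag.any()
        assert len(out) + report.n_removed_epoch_error == 120

    def test_clean_epoch_retained(self):
        s = make_series([1000.0] * 60)
        out, report = ibi_qc.exclude_by_beat_error(s)
        assert len(out) == 60 and report.n_epochs_excluded == 0

    def test_whole_measurement_invalid(self):
        flags = [True] * 55 + [False] * 45
        s = make_series([1000.0] * 100, error_flag=flags)
        out, report = ibi_qc.exclude_by_beat_error(s)
        assert report.series_invalid and not out.valid


class TestResampling:
    def test_constant_stream_exact(self):
        s = make_series([1000.0] * 100)
        hr4 = ibi_qc.resample_4hz(s)
        assert np.allclose(hr4.hr_bpm, 60.0)
        assert hr4.valid.all()

    def test_linear_midpoint(self):
        # beats anchored at HR 60 and 80 bpm, 10 s apart
        s = IbiSeries("w", 0, np.array([0.0, 10.0]), np.array([1000.0, 750.0]),
                      np.zeros(2, bool))
        hr4 = ibi_qc.resample_4hz(s, max_gap_s=15.0)
        t = hr4.time_s
        mid = np.argmin(np.abs(t - 5.0))
        assert hr4.hr_bpm[mid] == pytest.approx(70.0)

    def test_gap_masked(self):
        ibis = [1000.0] * 30 + [30000.0] + [1000.0] * 30
        s = make_series(ibis)
        hr4 = ibi_qc.resample_4hz(s, max_gap_s=5.0)
        in_gap = (hr4.time_s > 30.5) & (hr4.time_s < 59.5)
        assert not hr4.valid[in_gap].any()
        assert hr4.valid[hr4.time_s < 29.5].all()

    def test_too_few_beats_fully_masked(self):
        hr4 = ibi_qc.resample_4hz(make_series([800.0]))
        assert len(hr4) == 0

    def test_affine_hr_exact_at_grid(self, rng):
        # instantaneous HR affine in time: interpolation must reproduce it exactly
        t = np.cumsum(rng.uniform(0.6, 1.1, size=300))
        a, b = 70.0, 0.05
        hr = a + b * t
        s = IbiSeries("w", 0, t, 60000.0 / hr, np.zeros(len(t), bool))
        hr4 = ibi_qc.resample_4hz(s, max_gap_s=5.0)
        expected = a + b * hr4.time_s
        assert np.allclose(hr4.hr_bpm, expected, atol=1e-9)


class TestDiarySplit:
    def _hr(self, n=120, start=0.0):
        return HrSeries4Hz(start_s=start, hr_bpm=np.full(n, 80.0), valid=np.ones(n, bool))

    def test_interior_and_boundary(self):
        hr = self._hr(n=4 * 3600 * 17)
        diary = [DiaryInterval("w", 0, "work", 8 * 3600.0, 16 * 3600.0)]
        labels = ibi_qc.assign_periods(hr, diary)
        t = hr.time_s
        inside = np.argmin(np.abs(t - (8 * 3600.0 + 0.25)))
        assert labels[inside] == "work"
        # half-open: the first sample of the next hour is not work
        at_end = np.argmin(np.abs(t - 16 * 3600.0))
        assert t[at_end] == 16 * 3600.0 and labels[at_end] == "uncovered"

    def test_full_partition_no_uncovered(self):
        hr = self._hr(n=400)
        diary = [
            DiaryInterval("w", 0, "sleep", 0.0, 30.0),
            DiaryInterval("w", 0, "work", 30.0, 70.0),
            DiaryInterval("w", 0, "leisure", 70.0, 101.0),
        ]
        parts = ibi_qc.split_by_diary(hr, diary)
        assert not parts["uncovered"].valid.any()
        total = sum(parts[p].valid.sum() for p in ("sleep", "work", "leisure"))
        assert total == hr.valid.sum()

    def test_overlap_rejected_with_names(self):
        hr = self._hr()
        diary = [
            DiaryInterval("w", 0, "work", 0.0, 50.0),
            DiaryInterval("w", 0, "leisure", 40.0, 90.0),
        ]
        with pytest.raises(ValueError, match="overlapping.*work.*leisure"):
            ibi_qc.assign_periods(hr, diary)


def test_clean_series_counts_close():
    flags = [False] * 200
    ibis = [800.0] * 200
    ibis[50] = 2500.0  # out of range
    ibis[120] = 1100.0  # isolated outlier
    s = make_series(ibis, error_flag=flags)
    out, report = ibi_qc.clean_series(s)
    assert report.n_input == 200
    assert report.n_removed_range == 1
    assert report.n_removed_neighbor == 1
    assert report.n_retained == len(out)
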