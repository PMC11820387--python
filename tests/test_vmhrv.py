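"""pNN50 semantics, window gating, paired-discard rules, beat detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dyadsync as ds
from dyadsync.preprocess import QualityTrace, perfect_quality

from conftest import random_ibi


def _ibi(intervals_ms, t0=0.0):
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    onsets = t0 + np.concatenate([[0.0], np.cumsum(intervals_ms)[:-1]]) / 1000.0
    return ds.IbiSeries(interval_ms=intervals_ms, onset_s=onsets)


def brute_force_pnn50(intervals_ms) -> float:
    """Independent oracle: direct loop over successive differences."""
    count = hits = 0
    for a, b in zip(intervals_ms[:-1], intervals_ms[1:]):
        count += 1
        if abs(b - a) > 50.0:
            hits += 1
    return 100.0 * hits / count


class TestPnn50:
    @pytest.mark.parametrize("intervals,expected", [
        ([800, 860, 820, 825, 900], 50.0),   # diffs 60, 40, 5, 75 -> 2/4
        ([800] * 10, 0.0),
        ([800, 860] * 5, 100.0),
        ([800, 850, 900], 0.0),              # exactly 50 ms does not count
    ])
    def test_worked_examples(self, intervals, expected):
        assert ds.pnn50(_ibi(intervals)) == pytest.approx(expected)

    def test_single_interval_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            ds.pnn50(_ibi([800.0]))

    def test_cleaning_gap_not_counted(self):
        # two contiguous runs separated by a deleted beat: the cross-gap
        # difference (800 vs 900) must not enter the count
        run1 = _ibi([800, 810])
        run2 = _ibi([900, 910], t0=10.0)
        merged = ds.IbiSeries(
            interval_ms=np.concatenate([run1.interval_ms, run2.interval_ms]),
            onset_s=np.concatenate([run1.onset_s, run2.onset_s]))
        assert ds.pnn50(merged) == pytest.approx(0.0)

    def test_time_shift_invariance(self):
        a = _ibi([800, 870, 820, 900, 825])
        b = _ibi([800, 870, 820, 900, 825], t0=123.0)
        assert ds.pnn50(a) == ds.pnn50(b)

    @given(st.lists(st.floats(min_value=400, max_value=1500), min_size=2,
                    max_size=40))
    @settings(max_examples=80, deadline=None)
    def test_bounds_and_oracle_agreement(self, intervals):
        value = ds.pnn50(_ibi(intervals))
        assert 0.0 <= value <= 100.0
        assert value == pytest.approx(brute_force_pnn50(intervals))


class TestWindowedPnn50:
    def test_300s_session_yields_37_windows(self, full_quality):
        ibi = random_ibi(np.random.default_rng(0))
        tr = ds.windowed_pnn50(ibi, full_quality)
        assert len(tr) == 37

    def test_matches_per_window_brute_force(self, full_quality):
        rng = np.random.default_rng(1)
        ibi = random_ibi(rng)
        tr = ds.windowed_pnn50(ibi, full_quality)
        for i, s in enumerate(tr.window_start_s):
            sel = (ibi.onset_s >= s) & (ibi.onset_s < s + 120.0)
            expected = brute_force_pnn50(ibi.interval_ms[sel])
            assert tr.pnn50_pct[i] == pytest.approx(expected)

    def test_low_quality_windows_flagged_invalid(self):
        ibi = random_ibi(np.random.default_rng(3))
        q = perfect_quality(300.0)
        # drag frames 100..199 (50-100 s) to zero: windows overlapping that
        # span by enough frames drop below the 0.7 mean threshold
        sqi = q.sqi.copy()
        sqi[100:200] = 0.0
        q = QualityTrace(frame_start_s=q.frame_start_s, sqi=sqi,
                         duration_s=300.0)
        tr = ds.windowed_pnn50(ibi, q)
        expected_invalid = []
        for i, s in enumerate(tr.window_start_s):
            k = (q.frame_start_s >= s) & (q.frame_start_s < s + 120.0)
            expected_invalid.append(q.sqi[k].mean() < 0.7)
        assert np.array_equal(~tr.valid, np.array(expected_invalid))

    def test_session_shorter_than_window_rejected(self):
        ibi = random_ibi(np.random.default_rng(4), duration_s=100.0)
        with pytest.raises(ValueError, match="window"):
            ds.windowed_pnn50(ibi, perfect_quality(100.0))


class TestPairWindows:
    def _trace(self, valid):
        n = len(valid)
        return ds.VmhrvTrace(window_start_s=np.arange(n) * 5.0,
                             pnn50_pct=np.linspace(10, 40, n),
                             mean_sqi=np.ones(n), valid=np.array(valid),
                             n_intervals=np.full(n, 100))

    def test_intersection_and_min3_drop(self):
        pw = ds.pair_windows(self._trace([1, 1, 0, 1]),
                             self._trace([1, 0, 1, 1]))
        assert list(pw.window_start_s) == [0.0, 15.0]
        assert pw.n_windows == 2 and pw.dropped

    def test_all_valid_keeps_everything(self):
        pw = ds.pair_windows(self._trace([1] * 8), self._trace([1] * 8))
        assert pw.n_windows == 8 and not pw.dropped

    def test_symmetry(self):
        a, b = self._trace([1, 0, 1, 1, 0, 1]), self._trace([0, 1, 1, 1, 1, 1])
        pab = ds.pair_windows(a, b)
        pba = ds.pair_windows(b, a)
        assert np.array_equal(pab.window_start_s, pba.window_start_s)
        assert len(pab.viewer_pnn50) == len(pab.player_pnn50)

    def test_mismatched_grids_rejected_naming_lengths(self):
        with pytest.raises(ValueError, match="4.*3|3.*4"):
            ds.pair_windows(self._trace([1, 1, 1, 1]), self._trace([1, 1, 1]))


class TestDetectBeats:
    def test_constant_rr_beat_count(self, constant_rr_recording):
        beats = ds.detect_beats(ds.bandpass_bvp(constant_rr_recording))
        assert abs(len(beats) - 375) <= 1

    def test_all_zero_signal_gives_empty_series(self):
        rec = ds.PpgRecording(samples=np.zeros(75000), fs=250.0)
        assert len(ds.detect_beats(rec)) == 0

    def test_amplitude_scale_invariance(self, clean_recording):
        filtered = ds.bandpass_bvp(clean_recording)
        b1 = ds.detect_beats(filtered)
        b2 = ds.detect_beats(ds.PpgRecording(samples=0.01 * filtered.samples,
                                             fs=250.0))
        assert np.array_equal(b1.beat_times_s, b2.beat_times_s)

    def test_recall_precision_on_clean_fixture(self, clean_pair,
                                               clean_recording):
        ibi, _ = clean_pair
        truth = ds.BeatSeries(ibi.onset_s[ibi.onset_s < 299.5])
        detected = ds.detect_beats(ds.bandpass_bvp(clean_recording))
        recall, precision = ds.match_beats(detected, truth)
        assert recall >= 0.99 and precision >= 0.99

    def test_interval_cleaning_range(self):
        beats = ds.BeatSeries(np.array([0.0, 0.8, 1.0, 5.0, 5.8]))
        ibi = ds.beats_to_ibi(beats)
        # 200 ms and 4000 ms intervals removed, 800 ms kept
        assert np.allclose(ibi.interval_ms, [800.0, 800.0])
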