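"""Beat detection, interbeat intervals, and quality-gated windowed pNN50.

pNN50 — the percentage of successive interbeat-interval (IBI) pairs that
differ by more than 50 ms — is a time-domain index of vagally mediated heart
rate variability.  It is computed here over sliding 120-s windows stepped
every 5 s.  Each window inherits the mean signal-quality index (SQI) of the
2.5-s quality frames it contains and is discarded when that mean falls below
0.7; for dyadic analyses, any window discarded for one partner is also
discarded for the other, and a session keeping fewer than three matched
windows is dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .preprocess import PpgRecording, QualityTrace, expected_frame_count

__all__ = [
    "BeatSeries",
    "IbiSeries",
    "VmhrvTrace",
    "PairedVmhrv",
    "detect_beats",
    "beats_to_ibi",
    "pnn50",
    "windowed_pnn50",
    "pair_windows",
    "match_beats",
]

#: Window geometry for pNN50, seconds.
HRV_WIN_S = 120.0
HRV_STEP_S = 5.0

#: Mean-SQI gate below which a window is discarded.
QUALITY_THRESHOLD = 0.7

#: Minimum matched windows for a dyad session to survive.
MIN_SEGMENTS = 3

#: Plausible interbeat-interval range after cleaning, milliseconds.
IBI_MIN_MS = 250.0
IBI_MAX_MS = 3000.0

#: Refractory period for peak detection, seconds.
REFRACTORY_S = 0.3

#: Tolerance when testing whether two intervals are contiguous, seconds.
_ADJ_TOL_S = 1e-6


@dataclass
class BeatSeries:
    """Strictly increasing pulse-peak times, seconds."""

    beat_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times_s = np.asarray(self.beat_times_s, dtype=float)
        if len(self.beat_times_s) > 1 and np.any(np.diff(self.beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.beat_times_s)


@dataclass
class IbiSeries:
    """Interbeat intervals with the onset time of each interval's first beat.

    Onsets make interval adjacency explicit: after cleaning removes an
    implausible interval, the successive-difference across the gap must not
    be counted, and adjacency is recoverable as
    ``onset[i+1] == onset[i] + interval[i]/1000``.
    """

    interval_ms: np.ndarray
    onset_s: np.ndarray

    def __post_init__(self) -> None:
        self.interval_ms = np.asarray(self.interval_ms, dtype=float)
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        if self.interval_ms.shape != self.onset_s.shape:
            raise ValueError("interval_ms and onset_s must align")
        if np.any(self.interval_ms <= 0):
            raise ValueError("intervals must be positive")
        if len(self.onset_s) > 1 and np.any(np.diff(self.onset_s) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.interval_ms)

    def adjacent_pairs(self) -> np.ndarray:
        """Boolean mask over successive interval pairs that are contiguous."""
        if len(self) < 2:
            return np.zeros(max(len(self) - 1, 0), dtype=bool)
        expected = self.onset_s[:-1] + self.interval_ms[:-1] / 1000.0
        return np.abs(self.onset_s[1:] - expected) <= _ADJ_TOL_S


@dataclass
class VmhrvTrace:
    """Per-window pNN50 with the quality gate applied.

    ``valid`` is True iff the window's mean SQI meets the threshold AND the
    window holds at least two intervals (pNN50 is undefined otherwise).
    """

    window_start_s: np.ndarray
    pnn50_pct: np.ndarray
    mean_sqi: np.ndarray
    valid: np.ndarray
    n_intervals: np.ndarray
    window_len_s: float = HRV_WIN_S
    quality_threshold: float = QUALITY_THRESHOLD

    def __post_init__(self) -> None:
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        self.pnn50_pct = np.asarray(self.pnn50_pct, dtype=float)
        self.mean_sqi = np.asarray(self.mean_sqi, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.n_intervals = np.asarray(self.n_intervals, dtype=int)
        n = len(self.window_start_s)
        for arr in (self.pnn50_pct, self.mean_sqi, self.valid, self.n_intervals):
            if len(arr) != n:
                raise ValueError("all per-window arrays must align")

    def __len__(self) -> int:
        return len(self.window_start_s)


@dataclass
class PairedVmhrv:
    """Time-matched valid windows for one dyad session.

    Only windows valid for BOTH partners are kept; ``dropped`` is True when
    fewer than ``MIN_SEGMENTS`` windows survive, in which case the session
    contributes to no downstream statistic.
    """

    window_start_s: np.ndarray
    viewer_pnn50: np.ndarray
    player_pnn50: np.ndarray
    n_windows: int
    dropped: bool

    def __post_init__(self) -> None:
        if not (len(self.window_start_s) == len(self.viewer_pnn50)
                == len(self.player_pnn50) == self.n_windows):
            raise ValueError("paired vectors must have equal length n_windows")


def detect_beats(rec: PpgRecording) -> BeatSeries:
    """Systolic-peak detection on a bandpassed waveform.

    Local maxima exceeding an adaptive prominence threshold (a fixed fraction
    of the 5th-95th percentile amplitude range, hence invariant to amplitude
    scaling) with a 0.3-s refractory period.  A signal with no detectable
    peaks (e.g. all zeros) yields an empty series — downstream windows then
    simply fail the two-interval requirement.
    """
    x = rec.samples
    lo, hi = np.percentile(x, [5.0, 95.0])
    amp_range = hi - lo
    if amp_range <= 0:
        return BeatSeries(beat_times_s=np.empty(0))
    prominence = 0.3 * amp_range
    distance = max(1, int(round(REFRACTORY_S * rec.fs)))
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence)
    return BeatSeries(beat_times_s=rec.start_time_s + peaks / rec.fs)


def match_beats(detected: BeatSeries, truth: BeatSeries,
                tol_s: float = 0.05, align: bool = True
                ) -> tuple[float, float]:
    """(recall, precision) of detected beats against ground truth.

    Systolic peaks lag pulse onsets by a constant morphology-dependent
    delay, so by default the median detected-minus-true offset is removed
    before matching within ``tol_s``.
    """
    det = np.asarray(detected.beat_times_s, dtype=float)
    tru = np.asarray(truth.beat_times_s, dtype=float)
    if len(det) == 0 or len(tru) == 0:
        return 0.0, 0.0
    if align:
        k = min(len(det), len(tru))
        det = det - np.median(det[:k] - tru[:k])
    d = np.abs(det[:, None] - tru[None, :])
    recall = float((d.min(axis=0) <= tol_s).mean())
    precision = float((d.min(axis=1) <= tol_s).mean())
    return recall, precision


def beats_to_ibi(beats: BeatSeries, min_ms: float = IBI_MIN_MS,
                 max_ms: float = IBI_MAX_MS) -> IbiSeries:
    """Successive beat-to-beat intervals, with implausible intervals deleted.

    Intervals outside ``(min_ms, max_ms)`` are removed outright (no
    interpolation); the onset bookkeeping ensures successive-difference
    statistics never bridge the resulting gaps.
    """
    t = beats.beat_times_s
    if len(t) < 2:
        return IbiSeries(interval_ms=np.empty(0), onset_s=np.empty(0))
    intervals = np.diff(t) * 1000.0
    onsets = t[:-1]
    keep = (intervals > min_ms) & (intervals < max_ms)
    return IbiSeries(interval_ms=intervals[keep], onset_s=onsets[keep])


def pnn50(ibi: IbiSeries) -> float:
    """Percent of contiguous successive-interval pairs differing by > 50 ms.

    The inequality is strict: a difference of exactly 50 ms does not count.
    Pairs separated by a cleaning gap are excluded from both numerator and
    denominator.  Returns NaN when no contiguous pair exists despite >= 2
    intervals (the caller marks such windows invalid).

    Raises
    ------
    ValueError
        With fewer than 2 intervals (pNN50 undefined).
    """
    if len(ibi) < 2:
        raise ValueError("pNN50 undefined for fewer than 2 intervals")
    adj = ibi.adjacent_pairs()
    n_pairs = int(adj.sum())
    if n_pairs == 0:
        return float("nan")
    diffs = np.abs(np.diff(ibi.interval_ms))[adj]
    return 100.0 * float(np.sum(diffs > 50.0)) / n_pairs


def expected_window_count(duration_s: float, win_s: float = HRV_WIN_S,
                          step_s: float = HRV_STEP_S) -> int:
    """Number of full vmHRV windows: floor((duration - win)/step) + 1."""
    return expected_frame_count(duration_s, win_s, step_s)


def windowed_pnn50(ibi: IbiSeries, quality: QualityTrace,
                   win_s: float = HRV_WIN_S, step_s: float = HRV_STEP_S,
                   q_thresh: float = QUALITY_THRESHOLD) -> VmhrvTrace:
    """Sliding-window pNN50 gated by mean per-window signal quality.

    Windows start every ``step_s`` seconds from time 0; an interval belongs
    to the window containing its first-beat onset (half-open
    ``[start, start + win_s)``); a window's ``mean_sqi`` averages the SQI
    frames whose start time falls inside the window.  Validity requires both
    ``mean_sqi >= q_thresh`` and at least two intervals.
    """
    duration = quality.duration_s
    n_win = expected_frame_count(duration, win_s, step_s)
    if n_win < 1:
        raise ValueError(
            f"recording of {duration:.1f} s shorter than one {win_s:.0f}-s window"
        )
    starts = np.arange(n_win) * step_s

    onset = ibi.onset_s
    pnn = np.full(n_win, np.nan)
    nint = np.zeros(n_win, dtype=int)
    for i, s in enumerate(starts):
        j0, j1 = np.searchsorted(onset, [s, s + win_s])
        nint[i] = j1 - j0
        if nint[i] >= 2:
            pnn[i] = pnn50(IbiSeries(interval_ms=ibi.interval_ms[j0:j1],
                                     onset_s=onset[j0:j1]))

    fstart = quality.frame_start_s
    mean_sqi = np.zeros(n_win)
    for i, s in enumerate(starts):
        k0, k1 = np.searchsorted(fstart, [s - 1e-9, s + win_s - 1e-9])
        mean_sqi[i] = quality.sqi[k0:k1].mean() if k1 > k0 else 0.0

    valid = (mean_sqi >= q_thresh) & (nint >= 2) & np.isfinite(pnn)
    return VmhrvTrace(window_start_s=starts, pnn50_pct=pnn, mean_sqi=mean_sqi,
                      valid=valid, n_intervals=nint, window_len_s=win_s,
                      quality_threshold=q_thresh)


def pair_windows(viewer: VmhrvTrace, player: VmhrvTrace,
                 min_segments: int = MIN_SEGMENTS) -> PairedVmhrv:
    """Time-matched intersection of both partners' valid windows.

    A window discarded for one partner is discarded for the other
    (symmetric by construction); a session with fewer than ``min_segments``
    surviving windows is flagged ``dropped``.
    """
    if len(viewer) != len(player) or not np.allclose(
            viewer.window_start_s, player.window_start_s):
        raise ValueError(
            f"window grids differ: viewer has {len(viewer)} windows, "
            f"player has {len(player)}"
        )
    keep = viewer.valid & player.valid
    n = int(keep.sum())
    return PairedVmhrv(
        window_start_s=viewer.window_start_s[keep],
        viewer_pnn50=viewer.pnn50_pct[keep],
        player_pnn50=player.pnn50_pct[keep],
        n_windows=n,
        dropped=n < min_segments,
    )
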