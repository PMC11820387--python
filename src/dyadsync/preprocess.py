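"""Raw blood-volume-pulse (BVP) preprocessing and signal-quality indexing.

A photoplethysmographic pulse waveform from a healthy participant is highly
periodic, so the height of the largest off-zero peak of a short segment's
normalized autocorrelation (its correlogram) is a robust per-segment signal
quality index (SQI): motion artifacts destroy the periodicity and collapse
the autocorrelation.  The SQI is computed on overlapping 2.5-s frames every
0.5 s, after a 0.7-4.0 Hz zero-phase bandpass that isolates the cardiac band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "PpgRecording",
    "QualityTrace",
    "bandpass_bvp",
    "normalized_correlogram",
    "sliding_sqi",
]

#: Default cardiac bandpass edges, Hz.
DEFAULT_LOW_HZ = 0.7
DEFAULT_HIGH_HZ = 4.0

#: Default SQI frame geometry, seconds.
SQI_WIN_S = 2.5
SQI_STEP_S = 0.5

#: Physiologic pulse-period search range for the correlogram maximum,
#: seconds; 0.25-1.5 s spans 40-240 bpm, consistent with the bandpass.
MIN_PERIOD_S = 0.25
MAX_PERIOD_S = 1.5


@dataclass
class PpgRecording:
    """A uniformly sampled pulse waveform.

    Parameters
    ----------
    samples : ndarray
        Waveform amplitude, arbitrary units.
    fs : float
        Sampling rate, samples/s.  Must exceed 8 Hz (Nyquist above the
        4.0 Hz cardiac bandpass edge).
    start_time_s : float
        Time of the first sample, seconds from session start.
    artifact_mask : ndarray of bool, optional
        Ground-truth per-sample artifact flags (simulation only).
    """

    samples: np.ndarray
    fs: float
    start_time_s: float = 0.0
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 8.0:
            raise ValueError(f"fs must exceed 8 Hz, got {self.fs}")
        if len(self.samples) < SQI_WIN_S * self.fs:
            raise ValueError(
                f"recording too short: {len(self.samples)} samples "
                f"< one {SQI_WIN_S}-s SQI frame ({SQI_WIN_S * self.fs:.0f})"
            )
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.samples.shape:
                raise ValueError("artifact_mask must match samples in length")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(len(self.samples)) / self.fs


@dataclass
class QualityTrace:
    """Per-frame signal quality on the sliding 2.5 s / 0.5 s grid."""

    frame_start_s: np.ndarray
    sqi: np.ndarray
    frame_len_s: float = SQI_WIN_S
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.frame_start_s = np.asarray(self.frame_start_s, dtype=float)
        self.sqi = np.asarray(self.sqi, dtype=float)
        if self.frame_start_s.shape != self.sqi.shape:
            raise ValueError("frame grid and sqi must align")
        if len(self.sqi) and (self.sqi.min() < 0 or self.sqi.max() > 1):
            raise ValueError("sqi values must lie in [0, 1]")
        if self.duration_s == 0.0 and len(self.frame_start_s):
            self.duration_s = float(self.frame_start_s[-1] + self.frame_len_s)


def expected_frame_count(duration_s: float, win_s: float = SQI_WIN_S,
                         step_s: float = SQI_STEP_S) -> int:
    """Number of full frames: floor((duration - win)/step) + 1."""
    if duration_s < win_s:
        return 0
    # tiny epsilon guards float error in the division for exact-grid durations
    return int(np.floor((duration_s - win_s) / step_s + 1e-9)) + 1


def bandpass_bvp(rec: PpgRecording, low_hz: float = DEFAULT_LOW_HZ,
                 high_hz: float = DEFAULT_HIGH_HZ) -> PpgRecording:
    """Zero-phase Butterworth bandpass of the cardiac band.

    A 2nd-order Butterworth filter is applied forward-backward
    (``sosfiltfilt``), preserving beat timing; DC and slow drift are removed
    by the 0.7 Hz high-pass edge.

    Raises
    ------
    ValueError
        If the band is invalid for the sampling rate, or the recording is
        shorter than three time constants of the low edge.
    """
    if not (0 < low_hz < high_hz < rec.fs / 2):
        raise ValueError(
            f"need 0 < low < high < fs/2, got ({low_hz}, {high_hz}) at fs={rec.fs}"
        )
    min_len = int(np.ceil(3.0 / low_hz * rec.fs))
    if len(rec.samples) < min_len:
        raise ValueError(
            f"recording of {len(rec.samples)} samples is shorter than the "
            f"minimum {min_len} samples (3 time constants of {low_hz} Hz)"
        )
    sos = signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=rec.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    return PpgRecording(samples=filtered, fs=rec.fs,
                        start_time_s=rec.start_time_s,
                        artifact_mask=rec.artifact_mask)


def _corr_norms(x2_batch: np.ndarray) -> np.ndarray:
    """Per-lag normalization sqrt(front-energy * back-energy) for each row.

    For lag k the raw autocorrelation sums n - k products; dividing by the
    geometric mean of the energies of the two overlapping sub-segments makes
    the value a true correlation in [-1, 1] at every lag — a perfectly
    periodic segment then scores ~1 at its period instead of (n - k)/n.
    """
    n = x2_batch.shape[-1]
    css = np.cumsum(x2_batch, axis=-1)
    total = css[..., -1:]
    front = css[..., n - 1::-1]          # energy of x[:n-k] for k = 0..n-1
    back = np.concatenate([total, total - css[..., :-1]], axis=-1)  # x[k:]
    return np.sqrt(front * back)


def normalized_correlogram(segment: np.ndarray) -> np.ndarray:
    """Per-lag normalized autocorrelation of a mean-removed segment.

    Returns values for lags ``1 .. len(segment) - 1`` (the trivial lag-0
    value of 1 is excluded).  Each lag is normalized by the energies of the
    two overlapping sub-segments, so an exactly periodic segment scores ~1
    at its period.  A zero-variance segment returns all zeros — a flat
    signal carries no pulse, and downstream scoring treats it as quality 0
    rather than an error.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("segment must be a 1-D array of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("segment contains non-finite values")
    x = x - x.mean()
    if float(np.dot(x, x)) == 0.0:
        return np.zeros(len(x) - 1)
    n = len(x)
    nfft = next_fast_len(2 * n)
    spec = rfft(x, nfft)
    acf = irfft(spec * np.conj(spec), nfft)[:n]
    norms = _corr_norms((x * x)[None, :])[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, acf / norms, 0.0)
    return out[1:]


def sliding_sqi(rec: PpgRecording, win_s: float = SQI_WIN_S,
                step_s: float = SQI_STEP_S,
                min_period_s: float = MIN_PERIOD_S,
                max_period_s: float = MAX_PERIOD_S) -> QualityTrace:
    """Frame-wise SQI: the correlogram maximum over physiologic pulse lags.

    Frames of ``win_s`` seconds start every ``step_s`` seconds at the
    recording origin; the final partial frame is dropped.  Each frame's SQI
    is the maximum of its normalized correlogram over lags corresponding to
    pulse periods in ``[min_period_s, max_period_s]``, clipped to [0, 1];
    zero-variance frames score 0.
    """
    win_n = int(round(win_s * rec.fs))
    step_n = int(round(step_s * rec.fs))
    x = rec.samples
    if len(x) < win_n:
        raise ValueError(
            f"recording of {len(x)} samples shorter than one frame ({win_n})"
        )
    frames = np.lib.stride_tricks.sliding_window_view(x, win_n)[::step_n]
    n_frames = frames.shape[0]

    centered = frames - frames.mean(axis=1, keepdims=True)
    denom = np.einsum("ij,ij->i", centered, centered)
    nfft = next_fast_len(2 * win_n)
    spec = rfft(centered, nfft, axis=1)
    acf = irfft(spec * np.conj(spec), nfft, axis=1)[:, :win_n]
    norms = _corr_norms(centered * centered)

    lag_lo = max(1, int(round(min_period_s * rec.fs)))
    lag_hi = min(win_n - 1, int(round(max_period_s * rec.fs)))
    if lag_lo > lag_hi:
        raise ValueError("lag search range empty; check fs and period bounds")

    with np.errstate(invalid="ignore", divide="ignore"):
        ncorr = np.where(norms > 0, acf / norms, 0.0)
    peak = ncorr[:, lag_lo:lag_hi + 1].max(axis=1)
    sqi = np.where(denom > 0, peak, 0.0)
    sqi = np.clip(sqi, 0.0, 1.0)

    starts = rec.start_time_s + np.arange(n_frames) * step_s
    return QualityTrace(frame_start_s=starts, sqi=sqi, frame_len_s=win_s,
                        duration_s=rec.duration_s)


def perfect_quality(duration_s: float, win_s: float = SQI_WIN_S,
                    step_s: float = SQI_STEP_S) -> QualityTrace:
    """An all-ones QualityTrace for artifact-free (e.g. simulated-IBI) data."""
    n = expected_frame_count(duration_s, win_s, step_s)
    return QualityTrace(frame_start_s=np.arange(n) * step_s,
                        sqi=np.ones(n), frame_len_s=win_s,
                        duration_s=duration_s)
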