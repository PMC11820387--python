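"""Synthetic dyad cohorts: coupled RR-interval series, pulse waveforms with
motion artifacts, and VAS ratings with configurable group effects.

The generator emulates the acquisition regime of a two-room dyadic session:
each pair (a gameplayer and a viewer) contributes four 5-min sessions
(Baseline, ActiveEasy, ActiveHard, Passive) of 250-Hz blood-volume-pulse
waveforms, plus per-condition 0-100 visual-analogue ratings.

The physiological core is a pair of RR-interval series driven by slow
(~60-s timescale) zero-mean unit-variance modulators.  Each partner's
modulator is a mixture ``m_k = c * m_shared + (1 - c) * m_private_k`` of a
shared and a private process, so the coupling parameter ``c`` controls how
much of the slow variability the partners have in common.  The modulator
shifts the mean RR level AND scales the beat-to-beat jitter SD, so that
windowed pNN50 — a variability statistic — fluctuates slowly and coherently
between coupled partners, which is exactly the structure the downstream
synchrony estimate measures.  With ``rr_jitter_sd_ms = 0`` the series are
noise-free and fully determined by the modulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import PpgRecording
from .vmhrv import IbiSeries

__all__ = [
    "CONDITIONS",
    "SimConfig",
    "RatingEffectConfig",
    "DyadSession",
    "Cohort",
    "simulate_rr_pair",
    "render_ppg",
    "inject_artifacts",
    "simulate_ratings",
    "simulate_cohort",
]

#: Session conditions in protocol order.
CONDITIONS = ("Baseline", "ActiveEasy", "ActiveHard", "Passive")

ROLES = ("viewer", "gameplayer")

#: Minimum admissible RR interval, ms (intervals are floored just above it).
_RR_FLOOR_MS = 300.0

# Per-group jitter-SD shifts (ms) per condition, calibrated once so that the
# resulting window pNN50 medians land near the reported group medians
# (HIGH ~44/48/31/35 %, LOW ~31/19/39/39 % for ActiveEasy/ActiveHard/
# Passive/Baseline): socially-close (HIGH-like) viewers relax (higher vmHRV)
# during active viewing, distant (LOW-like) viewers tense up, and in the
# Passive condition the ordering reverses.
_DEFAULT_CONDITION_SHIFTS: dict[tuple[str, str], float] = {
    ("HIGH", "ActiveEasy"): -1.0, ("HIGH", "ActiveHard"): 3.0,
    ("HIGH", "Passive"): -12.5, ("HIGH", "Baseline"): -9.0,
    ("LOW", "ActiveEasy"): 4.0, ("LOW", "ActiveHard"): -4.0,
    ("LOW", "Passive"): 10.0, ("LOW", "Baseline"): 10.0,
}


@dataclass
class SimConfig:
    """Physiological generator settings.

    Defaults describe a 5-min, 250 samples/s session with a mean RR of
    850 ms, a ~60-s modulation timescale, and a motion-artifact load of six
    2-s events per minute.  ``group_coupling`` and ``group_jitter_sd_ms``
    give the (HIGH-like, LOW-like) per-group values used by
    :func:`simulate_cohort`; the scalar ``coupling`` / ``rr_jitter_sd_ms``
    apply when a pair is simulated outside a grouped cohort.
    """

    n_pairs: int = 24
    duration_s: float = 300.0
    fs: float = 250.0
    mean_rr_ms: float = 850.0
    rr_jitter_sd_ms: float = 40.0
    modulation_amp_ms: float = 25.0
    modulation_period_s: float = 60.0
    coupling: float = 0.5
    artifact_rate_per_min: float = 6.0
    artifact_duration_s: float = 2.0
    artifact_amplitude: float = 4.0
    seed: int = 0
    # cohort-level structure
    n_familiar: int | None = None            # default: round(13/24 * n_pairs)
    group_coupling: tuple[float, float] = (0.60, 0.42)
    group_jitter_sd_ms: tuple[float, float] = (47.0, 31.0)
    condition_jitter_shift_ms: Mapping[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.duration_s <= 120.0:
            raise ValueError("duration_s must exceed 120 s (one vmHRV window)")
        if self.fs <= 8.0:
            raise ValueError("fs must exceed 8 Hz (2x the 4 Hz bandpass edge)")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact_rate_per_min must be >= 0")
        # worst-case sd of an interval: mean-level swing + modulated jitter
        worst_sd = self.modulation_amp_ms + self.max_jitter_sd_ms()
        if self.mean_rr_ms - 4.0 * worst_sd <= 0:
            raise ValueError(
                "mean_rr_ms minus 4 sd could produce nonpositive intervals: "
                f"{self.mean_rr_ms} - 4*{worst_sd}"
            )

    def max_jitter_sd_ms(self) -> float:
        base = max(self.rr_jitter_sd_ms, *self.group_jitter_sd_ms)
        shifts = self.condition_jitter_shift_ms or _DEFAULT_CONDITION_SHIFTS
        return base + self.modulation_amp_ms + max(shifts.values(), default=0.0)


@dataclass
class RatingEffectConfig:
    """Rating generator settings (all on the 0-100 VAS scale).

    ``closeness_means`` are the (HIGH-like, LOW-like) group means;
    ``concern_shift`` is added to the HIGH-like group's empathic-concern
    mean; ``stress_by_condition`` maps each condition to mean
    (player own-stress, viewer perceived-partner-stress, viewer own-stress).
    Viewer own-stress tracks perceived stress with slope
    ``affective_slope`` plus noise, producing the vicarious (affective
    empathy) correlation.  All outputs are clipped to [0, 100].
    """

    closeness_means: tuple[float, float] = (70.0, 30.0)
    concern_shift: float = 25.0
    concern_base: float = 40.0
    stress_by_condition: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "Baseline": (5.0, 5.0, 5.0),
            "ActiveEasy": (31.0, 30.0, 25.0),
            "ActiveHard": (60.0, 55.0, 45.0),
            "Passive": (5.0, 8.0, 8.0),
        })
    rating_sd: float = 15.0
    affective_slope: float = 0.8
    seed: int = 0


@dataclass
class DyadSession:
    """One pair x one condition: a viewer and a gameplayer recording.

    Depending on the cohort's ``signal_level`` each role holds either a raw
    waveform (``ppg``) or the ground-truth interval series (``ibi``).
    """

    pair_id: int
    condition: str
    viewer_ppg: PpgRecording | None = None
    player_ppg: PpgRecording | None = None
    viewer_ibi: IbiSeries | None = None
    player_ibi: IbiSeries | None = None


@dataclass
class Cohort:
    """A simulated study: sessions, ratings, and ground-truth pair metadata."""

    sessions: dict[tuple[int, str], DyadSession]
    ratings: pd.DataFrame
    pairs: pd.DataFrame          # pair_id, familiar, group, coupling
    signal_level: str = "ppg"    # "ppg" or "ibi"
    duration_s: float = 300.0
    fs: float = 250.0


def _smooth_modulator(n: int, dt_s: float, period_s: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Moving-average-smoothed white noise, standardized to mean 0, sd 1.

    The boxcar window spans ``period_s`` seconds, giving a process whose
    autocorrelation vanishes beyond one period — the simplest smooth process
    with a controllable timescale.
    """
    w = max(2, int(round(period_s / dt_s)))
    white = rng.standard_normal(n + w - 1)
    m = np.convolve(white, np.ones(w) / w, mode="valid")
    sd = m.std()
    if sd == 0:
        return np.zeros(n)
    return (m - m.mean()) / sd


def simulate_rr_pair(config: SimConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[IbiSeries, IbiSeries]:
    """Generate one dyad's coupled RR-interval series.

    Each partner's interval sequence is
    ``RR_i = mean_rr_ms + modulation_amp_ms * m_k(t_i) + eps_i`` on the
    nominal beat grid ``t_i = i * mean_rr_ms``, where ``m_k`` mixes a shared
    and a private slow modulator by the coupling fraction, and ``eps_i`` is
    white noise whose SD is itself modulated,
    ``sd_i = max(rr_jitter_sd_ms + modulation_amp_ms * m_k(t_i), 1)``
    (zero when ``rr_jitter_sd_ms`` is zero).  Intervals are floored just
    above 300 ms; the sequences span at least ``duration_s``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = config.mean_rr_ms / 1000.0
    n = int(np.ceil(config.duration_s / dt)) + max(8, int(0.05 * config.duration_s / dt))

    m_shared = _smooth_modulator(n, dt, config.modulation_period_s, rng)
    c = config.coupling
    out = []
    for _ in range(2):
        m_priv = _smooth_modulator(n, dt, config.modulation_period_s, rng)
        m = c * m_shared + (1.0 - c) * m_priv
        rr = config.mean_rr_ms + config.modulation_amp_ms * m
        if config.rr_jitter_sd_ms > 0:
            sd = np.maximum(config.rr_jitter_sd_ms
                            + config.modulation_amp_ms * m, 1.0)
            rr = rr + rng.standard_normal(n) * sd
        rr = np.maximum(rr, _RR_FLOOR_MS + 1.0)
        beats = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
        # keep intervals until the beat grid spans the session
        last = int(np.searchsorted(beats, config.duration_s))
        last = min(max(last, 1), n)
        out.append(IbiSeries(interval_ms=rr[:last], onset_s=beats[:last]))
    return out[0], out[1]


def _pulse_template(fs: float) -> np.ndarray:
    """Asymmetric unimodal pulse: gamma-like fast rise, slower decay.

    Peak normalized to 1, ~0.1 s time-to-peak, total support 0.45 s.
    """
    t = np.arange(0.0, 0.45, 1.0 / fs)
    shape = (t / 0.05) ** 2 * np.exp(-t / 0.05)
    return shape / shape.max()


def render_ppg(ibi: IbiSeries, fs: float = 250.0,
               duration_s: float | None = None,
               noise_sd: float = 0.01,
               rng: np.random.Generator | None = None) -> PpgRecording:
    """Render a pulse waveform from an interval series.

    One pulse template is added at each cumulative beat time; the waveform
    is normalized to [-1, 1] before measurement noise (SD ``noise_sd``) is
    added.

    Raises
    ------
    ValueError
        On an empty interval series, or when ``fs`` gives fewer than 20
        samples per mean beat (template unresolvable).
    """
    if len(ibi) == 0:
        raise ValueError("cannot render an empty interval series")
    mean_rr_s = float(np.mean(ibi.interval_ms)) / 1000.0
    if fs * mean_rr_s < 20:
        raise ValueError(
            f"fs={fs} gives {fs * mean_rr_s:.1f} samples per mean beat (< 20)"
        )
    beats = np.concatenate([ibi.onset_s, [ibi.onset_s[-1] + ibi.interval_ms[-1] / 1000.0]])
    if duration_s is None:
        duration_s = float(beats[-1]) + 0.45
    n = int(round(duration_s * fs))

    template = _pulse_template(fs)
    sig = np.zeros(n + len(template))
    idx = np.round(beats * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    # vectorized scatter-add of the template at every beat index
    flat = (idx[:, None] + np.arange(len(template))[None, :]).ravel()
    np.add.at(sig, flat, np.tile(template, len(idx)))
    sig = sig[:n]

    lo, hi = sig.min(), sig.max()
    if hi > lo:
        sig = 2.0 * (sig - lo) / (hi - lo) - 1.0
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        sig = sig + rng.standard_normal(n) * noise_sd
    return PpgRecording(samples=sig, fs=fs)


def inject_artifacts(rec: PpgRecording, rate_per_min: float,
                     duration_s: float, amplitude: float,
                     seed: int | np.random.Generator = 0) -> PpgRecording:
    """Overwrite Poisson-placed epochs with high-amplitude aperiodic noise.

    Event count is Poisson with mean ``rate_per_min * T/60``; event onsets
    are uniform over the recording, epochs truncated at the end.  Affected
    samples are REPLACED (not added to), so the autocorrelation collapse the
    quality index relies on is guaranteed; the returned recording carries a
    ground-truth per-sample mask.  Rate 0 returns an identical copy with an
    empty mask.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = rec.samples.copy()
    mask = np.zeros(len(x), dtype=bool)
    total_s = rec.duration_s
    n_events = rng.poisson(rate_per_min * total_s / 60.0) if rate_per_min > 0 else 0
    starts = np.sort(rng.uniform(0.0, total_s, size=n_events))
    for s in starts:
        i0 = int(round(s * rec.fs))
        i1 = min(len(x), i0 + int(round(duration_s * rec.fs)))
        if i1 > i0:
            x[i0:i1] = amplitude * rng.standard_normal(i1 - i0)
            mask[i0:i1] = True
    return PpgRecording(samples=x, fs=rec.fs, start_time_s=rec.start_time_s,
                        artifact_mask=mask)


def simulate_ratings(config: SimConfig, ratings: RatingEffectConfig,
                     groups: Mapping[int, str],
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-pair per-condition VAS ratings with the configured group effects.

    Columns: pair_id, condition, closeness, concern, perceived_stress,
    own_stress, player_stress; every value clipped to [0, 100].
    """
    if rng is None:
        rng = np.random.default_rng(ratings.seed)
    rows = []
    hi_close, lo_close = ratings.closeness_means
    sd = ratings.rating_sd
    for pair_id in sorted(groups):
        is_high = groups[pair_id] == "HIGH"
        for cond in CONDITIONS:
            p_stress, perc_mean, own_mean = ratings.stress_by_condition[cond]
            closeness = rng.normal(hi_close if is_high else lo_close, sd)
            concern = rng.normal(
                ratings.concern_base + (ratings.concern_shift if is_high else 0.0), sd)
            perceived = rng.normal(perc_mean, sd)
            own = own_mean + ratings.affective_slope * (perceived - perc_mean) \
                + rng.normal(0.0, 0.6 * sd)
            player = rng.normal(p_stress, sd)
            rows.append({
                "pair_id": pair_id, "condition": cond,
                "closeness": float(np.clip(closeness, 0, 100)),
                "concern": float(np.clip(concern, 0, 100)),
                "perceived_stress": float(np.clip(perceived, 0, 100)),
                "own_stress": float(np.clip(own, 0, 100)),
                "player_stress": float(np.clip(player, 0, 100)),
            })
    return pd.DataFrame(rows)


def simulate_cohort(sim: SimConfig, ratings: RatingEffectConfig,
                    signal_level: str = "ppg") -> Cohort:
    """Generate a full study cohort: paired recordings for every pair x
    condition, plus the ratings table.

    Pairs are split into familiar (HIGH-like) and unfamiliar (LOW-like)
    groups — by default 13:11 of 24 — receiving the per-group coupling and
    jitter SD from ``sim``, with per-condition jitter shifts reproducing the
    active-vs-passive vmHRV pattern.  ``signal_level="ibi"`` skips waveform
    rendering and artifact injection and stores ground-truth interval
    series (used for large replicate studies).

    Raises
    ------
    ValueError
        If ``n_pairs < 2`` (a median split is undefined).
    """
    if sim.n_pairs < 2:
        raise ValueError("n_pairs must be >= 2 (median split undefined)")
    if signal_level not in ("ppg", "ibi"):
        raise ValueError("signal_level must be 'ppg' or 'ibi'")

    n_familiar = sim.n_familiar
    if n_familiar is None:
        n_familiar = int(round(sim.n_pairs * 13 / 24))
    n_familiar = min(max(n_familiar, 1), sim.n_pairs - 1)
    shifts = sim.condition_jitter_shift_ms
    if shifts is None:
        shifts = _DEFAULT_CONDITION_SHIFTS

    ss = np.random.SeedSequence(sim.seed)
    child = ss.spawn(sim.n_pairs * len(CONDITIONS) + 1)
    rating_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=ratings.seed, spawn_key=(sim.seed,)))

    sessions: dict[tuple[int, str], DyadSession] = {}
    pair_rows = []
    groups: dict[int, str] = {}
    k = 0
    for pair_id in range(sim.n_pairs):
        familiar = pair_id < n_familiar
        group = "HIGH" if familiar else "LOW"
        groups[pair_id] = group
        coupling = sim.group_coupling[0] if familiar else sim.group_coupling[1]
        jitter = sim.group_jitter_sd_ms[0] if familiar else sim.group_jitter_sd_ms[1]
        pair_rows.append({"pair_id": pair_id, "familiar": familiar,
                          "group": group, "coupling": coupling,
                          "jitter_sd_ms": jitter})
        for cond in CONDITIONS:
            rng = np.random.default_rng(child[k]); k += 1
            cfg = replace(sim, coupling=coupling,
                          rr_jitter_sd_ms=max(jitter + shifts.get((group, cond), 0.0), 1.0))
            v_ibi, p_ibi = simulate_rr_pair(cfg, rng=rng)
            sess = DyadSession(pair_id=pair_id, condition=cond)
            if signal_level == "ibi":
                sess.viewer_ibi, sess.player_ibi = v_ibi, p_ibi
            else:
                for role, ibi in (("viewer", v_ibi), ("gameplayer", p_ibi)):
                    rec = render_ppg(ibi, fs=sim.fs, duration_s=sim.duration_s,
                                     rng=rng)
                    rec = inject_artifacts(rec, sim.artifact_rate_per_min,
                                           sim.artifact_duration_s,
                                           sim.artifact_amplitude, seed=rng)
                    if role == "viewer":
                        sess.viewer_ppg = rec
                    else:
                        sess.player_ppg = rec
            sessions[(pair_id, cond)] = sess

    ratings_df = simulate_ratings(sim, ratings, groups, rng=rating_rng)
    pairs_df = pd.DataFrame(pair_rows)
    return Cohort(sessions=sessions, ratings=ratings_df, pairs=pairs_df,
                  signal_level=signal_level, duration_s=sim.duration_s,
                  fs=sim.fs)
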