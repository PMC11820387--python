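# Methods

This document records the generative model, the analysis constants, the
numerical choices, and the design decisions behind `dyadsync`, in enough
detail to re-derive every committed number.

## 1. Generative model

### 1.1 Coupled RR-interval series (`simulate.simulate_rr_pair`)

Each partner's interbeat intervals are generated on a nominal beat grid
`t_i = i · mean_rr_ms`:

```
RR_i = mean_rr_ms + modulation_amp_ms · m_k(t_i) + eps_i
```

where `m_k` is a slow modulator and `eps_i` is white noise.  The modulator
for partner `k` mixes a shared and a private component by the coupling
fraction `c`:

```
m_k = c · m_shared + (1 − c) · m_private_k
```

Each modulator is moving-average-smoothed standardized white noise with a
boxcar spanning `modulation_period_s` (default 60 s) — the simplest smooth
process with one controllable timescale.  The induced correlation between
the two partners' modulators is `c² / (c² + (1 − c)²)`: 0 at `c = 0`,
0.155 at 0.3, 0.69 at 0.6, 0.99 at 0.9.

Crucially, the modulator drives both the interval *mean* and the jitter
*standard deviation*:

```
sd_i = max(rr_jitter_sd_ms + modulation_amp_ms · m_k(t_i), 1)   [ms]
```

(and exactly zero when `rr_jitter_sd_ms = 0`).  pNN50 is a dispersion
statistic — it is blind to slow changes in the interval mean — so a
mean-only modulation would produce no pNN50 coupling at all.  Driving the
jitter SD is what lets windowed pNN50 inherit the coupling, which is the
property the whole pipeline is meant to recover.  Intervals are floored
just above 300 ms; sequences span at least the session duration.

Defaults (all in the config dataclass, all overridable): `mean_rr_ms =
850`, `rr_jitter_sd_ms = 40`, `modulation_amp_ms = 25`,
`modulation_period_s = 60`, `coupling = 0.5`, `duration_s = 300`,
`fs = 250` Hz.

### 1.2 Waveform rendering and artifacts

`render_ppg` places a pulse template `(t/τ)² · exp(−t/τ)` with `τ = 0.05 s`
(support 0.45 s, systolic peak ≈ 0.1 s after the beat onset) at every beat,
scatter-adds, normalizes to [−1, 1], and adds Gaussian sensor noise
(`noise_sd = 0.01`).  `inject_artifacts` draws Poisson motion events
(default 6 per minute, 2 s each) and replaces the affected samples with
amplitude-4 Gaussian noise, recording a boolean ground-truth mask.

### 1.3 Cohorts, groups and ratings

`simulate_cohort` builds `n_pairs` dyads × 4 conditions (`Baseline`,
`ActiveEasy`, `ActiveHard`, `Passive`).  The first `round(13/24 · n)` pairs
are "familiar" (HIGH-like) and receive group-level coupling and jitter SD
(defaults `(0.60, 0.42)` and `(47, 31)` ms); per-condition jitter shifts
reproduce the qualitative vmHRV pattern of the motivating design,
including the reversal where the LOW group's pNN50 exceeds the HIGH
group's in the Passive condition.  Ratings (0–100 visual-analogue scale)
get group means for closeness and empathic concern and per-condition
stress means; viewer own-stress tracks perceived partner stress with slope
0.8, producing the vicarious ("affective empathy") correlation.  All
ratings are clipped to [0, 100].

`signal_level="ibi"` skips waveform rendering and hands the ground-truth
interval series to the pipeline directly — used for Monte-Carlo replicate
studies where rendering and re-detecting ~350 beats per recording would
dominate the runtime without exercising anything new.

### 1.4 What the generator does and does not emulate

Emulated: slow vagal-like modulation with a controllable dyadic coupling;
heteroscedastic beat-to-beat jitter (the substrate of pNN50); realistic
pulse morphology, sensor noise, and burst motion artifacts; group
structure in both physiology and ratings.

Not emulated: respiratory sinus arrhythmia as an explicit oscillation,
baroreflex dynamics, ectopic beats, sensor drift or detachment, pulse-wave
morphology changes with vascular tone, and any causal direction of
coupling (the shared modulator is symmetric by construction).

## 2. Preprocessing

- **Bandpass** (`bandpass_bvp`): 2nd-order Butterworth, 0.7–4.0 Hz,
  applied forward–backward (`sosfiltfilt`) so beat timing is not skewed by
  filter delay.  Recordings shorter than the filter's stable minimum are
  rejected.
- **SQI** (`sliding_sqi`): frames of 2.5 s every 0.5 s (a 300-s recording
  → exactly 596 frames, `floor((300 − 2.5)/0.5) + 1`).  Per frame, the SQI
  is the maximum of the *per-lag normalized* autocorrelation over
  physiological lags (periods 0.25–1.5 s, i.e. 40–240 bpm).  The
  normalization divides the lag-`k` autocovariance by
  `sqrt(E_front(k) · E_back(k))`, the energies of the two overlapping
  segments — the biased `(n − k)/n` estimator would cap a perfectly
  periodic frame well below 1 at cardiac lags and break the 0.7 gate.
  Computation is batched: one strided window view, one FFT per frame
  block, cumulative-sum energy norms.

## 3. vmHRV and the exclusion rules

- **Beat detection** (`detect_beats`): `scipy.signal.find_peaks` with
  amplitude-relative prominence (0.3 of the 5–95 percentile span, so
  detection is invariant to amplitude scaling) and a 0.3-s refractory
  distance.  `match_beats` scores recall/precision after removing the
  constant systolic-peak-vs-onset offset (median alignment), the standard
  convention for detector evaluation.
- **IBI cleaning** (`beats_to_ibi`): intervals outside (250, 3000) ms are
  deleted; deletion breaks onset contiguity, and `pnn50` only counts
  successive-interval pairs that are contiguous in time (tolerance 1 µs),
  so cleaning gaps never fabricate large differences.
- **pNN50**: percentage of contiguous interval pairs with
  `|ΔRR| > 50 ms` (strict), `NaN` if a window has no contiguous pair,
  error below 2 intervals.
- **Windowing** (`windowed_pnn50`): 120-s windows every 5 s anchored at 0
  (300 s → exactly 37 windows).  An interval belongs to the window
  containing its first-beat onset (half-open `[start, start + 120)`); a
  window's `mean_sqi` averages the SQI frames *starting* inside it.
  Validity requires `mean_sqi ≥ 0.7` **and** ≥ 2 intervals.
- **Paired discard** (`pair_windows`): a window survives only if valid for
  *both* partners (symmetric by construction — the kept index set is the
  intersection); a session with fewer than 3 surviving matched windows is
  dropped entirely and contributes to no statistic.
- **Discard log**: every discarded role-window appears exactly once with
  exactly one reason, checked in priority order `too_few_intervals` →
  `low_sqi` → `partner_discard` → `session_drop`, so
  `kept + logged = total` holds per recording.

## 4. Synchrony and statistics

- **Synchrony** (`synchrony_r`): Pearson correlation (default) or
  Spearman of the two partners' matched pNN50 vectors.  Zero-variance
  vectors yield `r = 0` flagged `degenerate` instead of NaN.  Negative
  correlations are retained — clipping would bias group means.
- **Rank tests** (`stats`): Mann-Whitney U (statistic = smaller U
  orientation) and Wilcoxon signed-rank (zeros dropped, statistic =
  smaller rank sum), both with tie-corrected, continuity-corrected normal
  deviates.  For small samples the p-value is computed by *full
  enumeration* (MW: all `C(n, n1)` group labelings for tie-free
  `n ≤ 12`; Wilcoxon: all `2^n` sign patterns for effective `n ≤ 12`),
  giving exact two-sided p-values where the normal approximation is
  weakest.  Correlations use the scipy coefficient with a t-approximation
  p, or exact pairing enumeration for `n ≤ 8`.
- **Effect size**: `r = Z / √N`, sign preserved.  For Wilcoxon, `N` is the
  number of pairs *supplied* (before zero-difference removal), matching
  common statistical-software output; for MW, `N = n1 + n2`.
- **Multiple comparisons**: Bonferroni within each family —
  `alpha_between = 0.05/3 ≈ 0.017` for the three test conditions,
  `alpha_within = 0.05/6 ≈ 0.008` for the six condition pairs.
- **Battery** (`run_battery`): between-group tests use a *per-condition*
  median split on closeness (strictly above the median → HIGH); paired
  across-condition tests use a *stable overall* split on each viewer's
  mean closeness, because per-condition membership would make pairing
  ill-defined.  Across-condition vmHRV comparisons pair windows by
  identical window start time (`window_start_s` intersection).  Cells
  whose inputs were excluded report `insufficient data` instead of
  aborting; reports are plain JSON, floats rounded to 6 decimals, keys
  sorted — byte-deterministic for a given cohort.

## 5. Monte-Carlo experiment sizing

These sizes are the package's own choices, made from measured variances,
not tuned to any particular seed:

- **Coupling recovery** (tests and `scripts/acceptance.py`): 20 pairs per
  coupling level, 100 sessions averaged per pair.  A single 300-s session
  holds only ~5 independent 60-s modulator epochs, so a per-session
  synchrony estimate has sd ≈ 0.63 while the population-mean gap between
  `c = 0` and `c = 0.3` is only ≈ 0.06; averaging 100 sessions brings the
  level-mean standard error to ≈ 0.014 (≈ 3.6 ms per simulated session,
  ~30 s total).
- **Battery calibration**: 200 ratings-only null replicates (no concern
  effect; family-wise false-alarm rate over the three concern cells) and
  100 IBI-level effect replicates (group jitter-SD separation applied
  uniformly across conditions; all three between-group vmHRV cells must
  flag).  Measured per-test null rejection at `alpha = 0.017` is ≈ 0.015,
  implying a family-wise rate ≈ 0.044.
- **Replicate studies run at `signal_level="ibi"`** because rendering +
  re-detecting beats reproduces the ground-truth intervals to ≥ 99%
  recall/precision (verified separately) and would multiply runtime
  roughly 30×.

## 6. Limitations

- pNN50 synchrony estimated from one 300-s session is intrinsically noisy
  (few independent modulator epochs); single-session per-pair correlations
  should be interpreted only in group aggregate.
- The 120-s/5-s window grid yields heavily overlapping windows; the 37
  values per session are serially dependent, which is why all inference
  here treats windows as observations only inside rank tests that the
  battery applies identically across groups (a shared, conservative
  simplification — not a claim of independence).
- The simulator's group effects are additive and stationary within a
  session; real affective responses drift.
- Beat detection assumes a single dominant pulse per cardiac cycle; no
  dicrotic-notch handling.
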