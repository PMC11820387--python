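"""Cohort file formats and the end-to-end pipeline with discard accounting.

On disk a cohort is: one CSV per recording (``time_s,bvp``), an optional
artifact-mask CSV per recording (``start_s,end_s``), a manifest CSV
(``pair_id,role,condition,file``) and a ratings CSV
(``pair_id,condition,closeness,concern,perceived_stress,own_stress,
player_stress``).  The pipeline logs every discarded 120-s window exactly
once with exactly one reason (``low_sqi``, ``too_few_intervals``,
``partner_discard`` or ``session_drop``), making the exclusion rules
auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .preprocess import (PpgRecording, bandpass_bvp, perfect_quality,
                         sliding_sqi)
from .simulate import CONDITIONS, ROLES, Cohort, DyadSession
from .stats import RATING_COLUMNS, report_to_frame, run_battery
from .synchrony import synchrony_r
from .vmhrv import (PairedVmhrv, VmhrvTrace, beats_to_ibi, detect_beats,
                    pair_windows, windowed_pnn50)

__all__ = ["write_cohort", "read_cohort", "run_pipeline", "PipelineResult"]

log = logging.getLogger("dyadsync")


def _mask_to_intervals(mask: np.ndarray, fs: float) -> pd.DataFrame:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.astype(int), [0]])))
    starts, ends = edges[::2], edges[1::2]
    return pd.DataFrame({"start_s": starts / fs, "end_s": ends / fs})


def _intervals_to_mask(df: pd.DataFrame, n: int, fs: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for _, row in df.iterrows():
        i0 = max(0, int(round(row["start_s"] * fs)))
        i1 = min(n, int(round(row["end_s"] * fs)))
        mask[i0:i1] = True
    return mask


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write a PPG-level cohort to disk in the flat CSV layout."""
    if cohort.signal_level != "ppg":
        raise ValueError("only PPG-level cohorts have an on-disk waveform form")
    outdir = Path(outdir)
    (outdir / "recordings").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for (pair_id, cond), sess in sorted(cohort.sessions.items()):
        for role, rec in (("viewer", sess.viewer_ppg),
                          ("gameplayer", sess.player_ppg)):
            name = f"pair{pair_id:03d}_{role}_{cond}"
            path = outdir / "recordings" / f"{name}.csv"
            t = rec.times_s
            # default float formatting is repr-round-trippable; a fixed
            # format would quantize the waveform on re-read
            pd.DataFrame({"time_s": t, "bvp": rec.samples}).to_csv(
                path, index=False)
            if rec.artifact_mask is not None:
                _mask_to_intervals(rec.artifact_mask, rec.fs).to_csv(
                    outdir / "recordings" / f"{name}_artifacts.csv",
                    index=False, float_format="%.6f")
            manifest_rows.append({"pair_id": pair_id, "role": role,
                                  "condition": cond,
                                  "file": f"recordings/{name}.csv"})
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    cohort.ratings.to_csv(outdir / "ratings.csv", index=False,
                          float_format="%.6f")
    if cohort.pairs is not None:
        cohort.pairs.to_csv(outdir / "pairs.csv", index=False)
    return outdir


def read_cohort(manifest_path: str | Path,
                ratings_path: str | Path) -> Cohort:
    """Read and validate a cohort from its manifest and ratings CSVs.

    Sessions referencing missing files, and pairs missing a role or a
    condition, are excluded with a logged warning; non-monotone timestamps
    and out-of-range ratings raise with the offending row number.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    ratings = pd.read_csv(ratings_path)

    for i, row in ratings.iterrows():
        for col in RATING_COLUMNS:
            v = row[col]
            if not 0.0 <= v <= 100.0:
                raise ValueError(
                    f"ratings row {i}: {col}={v} outside the VAS range [0, 100]")

    recordings: dict[tuple[int, str, str], PpgRecording] = {}
    fs_seen = None
    for i, row in manifest.iterrows():
        path = base / row["file"]
        if not path.exists():
            log.warning("manifest row %d: missing file %s; session excluded",
                        i, path)
            continue
        df = pd.read_csv(path, float_precision="round_trip")
        t = df["time_s"].values
        dt = np.diff(t)
        if len(dt) and (dt.min() <= 0):
            raise ValueError(
                f"manifest row {i} ({path.name}): non-monotone timestamps")
        fs = 1.0 / float(np.median(dt))
        fs_seen = fs
        mask = None
        mask_path = path.with_name(path.stem + "_artifacts.csv")
        if mask_path.exists():
            mask = _intervals_to_mask(pd.read_csv(mask_path), len(df), fs)
        recordings[(int(row["pair_id"]), row["role"], row["condition"])] = \
            PpgRecording(samples=df["bvp"].values, fs=round(fs, 6),
                         start_time_s=float(t[0]), artifact_mask=mask)

    sessions: dict[tuple[int, str], DyadSession] = {}
    pair_ids = sorted({int(p) for p, _, _ in recordings})
    kept_pairs = []
    duration = 300.0
    for pair_id in pair_ids:
        complete = all((pair_id, role, cond) in recordings
                       for role in ROLES for cond in CONDITIONS)
        if not complete:
            log.warning("pair %d missing a role or condition; pair excluded",
                        pair_id)
            continue
        kept_pairs.append(pair_id)
        for cond in CONDITIONS:
            v = recordings[(pair_id, "viewer", cond)]
            p = recordings[(pair_id, "gameplayer", cond)]
            duration = v.duration_s
            sessions[(pair_id, cond)] = DyadSession(
                pair_id=pair_id, condition=cond, viewer_ppg=v, player_ppg=p)

    ratings = ratings[ratings["pair_id"].isin(kept_pairs)].reset_index(drop=True)
    return Cohort(sessions=sessions, ratings=ratings,
                  pairs=pd.DataFrame({"pair_id": kept_pairs}),
                  signal_level="ppg", duration_s=duration,
                  fs=fs_seen or 250.0)


@dataclass
class PipelineResult:
    traces: dict
    quality: dict
    paired: dict
    synchrony: list
    report: dict
    discard_log: pd.DataFrame
    config: PipelineConfig


def _session_traces(sess: DyadSession, cohort: Cohort,
                    cfg: PipelineConfig) -> dict[str, VmhrvTrace]:
    """Per-role vmHRV traces for one session, via the level-appropriate path."""
    out = {}
    for role in ROLES:
        if cohort.signal_level == "ppg":
            rec = sess.viewer_ppg if role == "viewer" else sess.player_ppg
            filtered = bandpass_bvp(rec, cfg.bandpass.low_hz,
                                    cfg.bandpass.high_hz)
            quality = sliding_sqi(filtered, cfg.sqi.win_s, cfg.sqi.step_s)
            ibi = beats_to_ibi(detect_beats(filtered))
        else:
            ibi = sess.viewer_ibi if role == "viewer" else sess.player_ibi
            quality = perfect_quality(cohort.duration_s, cfg.sqi.win_s,
                                      cfg.sqi.step_s)
        out[role] = windowed_pnn50(ibi, quality, cfg.hrv.win_s,
                                   cfg.hrv.step_s, cfg.sqi.threshold)
    return out


def _log_windows(rows: list, pair_id: int, cond: str, traces: dict,
                 paired: PairedVmhrv) -> None:
    """Append one row per discarded role-window with its single reason."""
    kept_starts = set(np.round(paired.window_start_s, 6))
    roles = list(traces)
    for role in roles:
        own = traces[role]
        other = traces[roles[1] if role == roles[0] else roles[0]]
        for i, start in enumerate(own.window_start_s):
            if not own.valid[i]:
                reason = ("too_few_intervals" if own.n_intervals[i] < 2
                          or not np.isfinite(own.pnn50_pct[i]) else "low_sqi")
            elif not other.valid[i]:
                reason = "partner_discard"
            elif paired.dropped:
                reason = "session_drop"
            else:
                continue
            rows.append({"pair_id": pair_id, "condition": cond, "role": role,
                         "window_start_s": float(start), "reason": reason})


def run_pipeline(config: PipelineConfig, cohort: Cohort,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run quality gating, windowed pNN50, synchrony, and the stats battery.

    When ``outdir`` is given, writes per-session vmHRV CSVs, a synchrony
    CSV, the battery report (JSON + CSV) and the discard log.

    Raises
    ------
    RuntimeError
        If every session was dropped (summarizing the discard log).
    """
    config.validate()
    traces: dict = {}
    quality: dict = {}
    paired: dict = {}
    discard_rows: list = []
    for (pair_id, cond), sess in sorted(cohort.sessions.items()):
        per_role = _session_traces(sess, cohort, config)
        for role, tr in per_role.items():
            traces[(pair_id, cond, role)] = tr
        pw = pair_windows(per_role["viewer"], per_role["gameplayer"],
                          config.hrv.min_segments)
        # the paired vector with session-drop applied downstream
        paired[(pair_id, cond)] = pw
        _log_windows(discard_rows, pair_id, cond, per_role, pw)

    discard_log = pd.DataFrame(
        discard_rows, columns=["pair_id", "condition", "role",
                               "window_start_s", "reason"])

    usable = [k for k, v in paired.items() if not v.dropped]
    if not usable:
        summary = discard_log["reason"].value_counts().to_dict()
        raise RuntimeError(
            f"zero usable sessions after quality gating; discards: {summary}")

    synchrony = [synchrony_r(paired[k], method=config.synchrony.method,
                             pair_id=k[0], condition=k[1])
                 for k in sorted(usable)]

    report = run_battery(cohort.ratings, paired,
                         alpha_between=config.stats.alpha_between,
                         alpha_within=config.stats.alpha_within,
                         synchrony_method=config.synchrony.method)

    result = PipelineResult(traces=traces, quality=quality, paired=paired,
                            synchrony=synchrony, report=report,
                            discard_log=discard_log, config=config)
    if outdir is not None:
        write_results(result, outdir)
    return result


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def write_results(result: PipelineResult, outdir: str | Path) -> Path:
    """Write vmHRV traces, synchrony, report and discard log under outdir."""
    outdir = Path(outdir)
    (outdir / "vmhrv").mkdir(parents=True, exist_ok=True)
    for (pair_id, cond, role), tr in sorted(result.traces.items()):
        pd.DataFrame({
            "window_start_s": tr.window_start_s,
            "pnn50_pct": tr.pnn50_pct,
            "mean_sqi": tr.mean_sqi,
            "valid": tr.valid.astype(int),
            "n_intervals": tr.n_intervals,
        }).to_csv(outdir / "vmhrv" / f"pair{pair_id:03d}_{role}_{cond}.csv",
                  index=False, float_format="%.6f")

    pd.DataFrame([{
        "pair_id": s.pair_id, "condition": s.condition, "r": round(s.r, 6),
        "method": s.method, "n_windows": s.n_windows,
        "degenerate": s.degenerate,
    } for s in result.synchrony]).to_csv(outdir / "synchrony.csv", index=False)

    (outdir / "report.json").write_text(
        json.dumps(result.report, indent=2, sort_keys=True,
                   default=_json_default) + "\n")
    report_to_frame(result.report).to_csv(outdir / "report.csv", index=False)
    result.discard_log.to_csv(outdir / "discard_log.csv", index=False,
                              float_format="%.6f")
    return outdir
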