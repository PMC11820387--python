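#!/usr/bin/env python
"""Run the full pipeline on the simulated cohort and keep the key tables.

Reads ``scratch/cohort`` (produced by ``01_simulate_cohort.py``), runs
quality gating, windowed pNN50, per-pair synchrony and the statistics
battery.  Bulky per-recording outputs stay in ``scratch/analysis``; the
report, synchrony table and a discard summary are copied to ``results/``.

Run from the repository root::

    python analysis/02_quality_and_vmhrv.py
"""

import shutil
from pathlib import Path

import pandas as pd

from dyadsync.config import PipelineConfig
from dyadsync.io import read_cohort, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    if not (cohort_dir / "manifest.csv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    cohort = read_cohort(cohort_dir / "manifest.csv",
                         cohort_dir / "ratings.csv")

    outdir = ROOT / "scratch" / "analysis"
    result = run_pipeline(PipelineConfig(), cohort, outdir=outdir)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for name in ("report.json", "report.csv", "synchrony.csv"):
        shutil.copy(outdir / name, results / name)

    log = result.discard_log
    summary = (log.groupby(["condition", "reason"]).size()
               .rename("n_windows").reset_index())
    summary.to_csv(results / "discard_summary.csv", index=False)

    n_dropped = sum(v.dropped for v in result.paired.values())
    print(f"sessions: {len(result.paired)} total, {n_dropped} dropped")
    print(f"windows discarded: {len(log)} "
          f"({dict(log['reason'].value_counts())})")
    sync = pd.read_csv(results / "synchrony.csv")
    print("mean synchrony r by condition:")
    print(sync.groupby("condition")["r"].mean().round(3).to_string())
    print(f"tables in {results}, full traces in {outdir}")


if __name__ == "__main__":
    main()
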