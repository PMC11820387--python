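#!/usr/bin/env python
"""Generate the default 24-pair study cohort and write it to scratch/.

The raw waveform CSVs are bulky (75k samples per recording), so they live
under ``scratch/cohort`` — every later stage reads them from there.

Run from the repository root::

    python analysis/01_simulate_cohort.py [--seed 0]
"""

import argparse
from pathlib import Path

import dyadsync as ds
from dyadsync.io import write_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    sim = ds.SimConfig(seed=args.seed)              # 24 pairs, study defaults
    ratings = ds.RatingEffectConfig(seed=args.seed)
    cohort = ds.simulate_cohort(sim, ratings, signal_level="ppg")

    outdir = ROOT / "scratch" / "cohort"
    write_cohort(cohort, outdir)
    print(f"wrote {len(cohort.sessions)} sessions ({sim.n_pairs} pairs, "
          f"{sim.duration_s:.0f} s at {sim.fs:.0f} Hz) to {outdir}")


if __name__ == "__main__":
    main()
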