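#!/usr/bin/env python
"""The central in-silico experiment: which gaits are fastest where?

Runs the desk-scale optimization study (20 particles x 60 iterations x 10
seeds per condition) across all five conditions: upward, downward and
sideways climbing with 200% adhesion, ground walking with adhesion, and
ground walking without adhesion.  Expected outcome, mirroring the full-scale
study: wall conditions are dominated by high-TCS tripod-class winners,
whereas ground-without-adhesion winners are low-TCS bipod-family gaits.

Writes results/study/study.csv (tidy, one row per experiment), per-run
fitness histories under results/study/runs/, and a condition-level summary.

    python analysis/03_optimize_gaits.py [--seed 0] [--conditions wall_up,ground]
"""

import argparse
from pathlib import Path

from hexagait.pipeline import CONDITION_NAMES, ExperimentManifest, run_study

OUT = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument(
        "--conditions",
        default=",".join(CONDITION_NAMES),
        help="comma-separated subset of the five study conditions",
    )
    args = parser.parse_args()
    conditions = tuple(args.conditions.split(","))
    manifest = ExperimentManifest.desk(
        base_seed=args.seed, conditions=conditions, out_dir=str(OUT)
    )
    df = run_study(manifest, progress=True)
    summary = (
        df.groupby("condition")
        .agg(
            median_tcs=("tcs", "median"),
            median_speed=("speed", "median"),
            median_stance=("mean_stance_count", "median"),
            median_stability=("stability_pct", "median"),
            tripod_class=("class", lambda c: (c.str.startswith("tripod")).sum()),
            bipod_or_unclear=("class", lambda c: (~c.str.startswith("tripod")).sum()),
        )
        .round(3)
    )
    summary.to_csv(OUT / "summary.csv")
    print(summary.to_string())
    print(f"\nwrote {OUT / 'study.csv'} and {OUT / 'summary.csv'}")


if __name__ == "__main__":
    main()
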