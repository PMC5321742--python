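#!/usr/bin/env python
"""Map the tripod and bipod gaits onto a two-link hexapod robot leg.

Samples the model's prescribed leg-tip trajectories, solves the two-link
inverse kinematics per sample (selecting the knee-backward branch), and
exports the joint-angle time series a robot controller would consume.  The
phase relations between legs — the gait itself — survive the mapping
unchanged, which is what lets a morphologically different robot walk both
gaits.  Writes results/robot/<gait>_angles.csv.
"""

from pathlib import Path

import numpy as np

from hexagait.gaits import BIPOD_B, TRIPOD_A
from hexagait.robot import TwoLinkLeg, map_gait_to_robot

OUT = Path(__file__).resolve().parents[1] / "results" / "robot"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    leg = TwoLinkLeg(promotion_bias=5.0)
    for name, gait in (("tripod-A", TRIPOD_A), ("bipod-B", BIPOD_B)):
        df = map_gait_to_robot(gait, leg, samples_per_cycle=100)
        path = OUT / f"{name}_angles.csv"
        df.to_csv(path, index=False)
        lam = df["lambda_deg"]
        sig = df["sigma_deg"]
        print(
            f"{name}: {len(df)} samples, lambda in [{lam.min():.1f}, {lam.max():.1f}] deg, "
            f"sigma in [{sig.min():.1f}, {sig.max():.1f}] deg -> {path}"
        )
        # sanity: in tripod-A, L1 and R2 share phase 0 -> identical traces
        if name == "tripod-A":
            by_leg = {k: g["sigma_deg"].to_numpy() for k, g in df.groupby("leg")}
            assert np.allclose(by_leg["L1"], by_leg["R2"])


if __name__ == "__main__":
    main()
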