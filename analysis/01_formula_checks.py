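#!/usr/bin/env python
"""Desk checks of the closed-form physics used throughout the model.

Evaluates the drag, friction, adhesion, Froude-scaling and leg-tip-speed
formulas at the model's parameters and writes results/formulas.json.  The
point of the exercise: drag on a fly-scale walker is three orders of
magnitude below sliding friction, which justifies leaving aerodynamics out
of the locomotion loop.
"""

import json
from pathlib import Path

from hexagait.simulator import (
    adhesion_force,
    drag_force,
    froude_scaled_frequency,
    leg_tip_speed,
    sliding_friction_estimate,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    v_tip = leg_tip_speed(20.0, 0.0005)
    leg_drag = drag_force(1.225, 1.05, 5e-8, v_tip)
    body_drag = drag_force(1.225, 1.05, 0.0025**2, 0.02)
    friction = sliding_friction_estimate(0.1, 1.42e-7, 9.81)
    results = {
        "leg_tip_speed_m_per_s": v_tip,
        "single_leg_drag_N": leg_drag,
        "whole_body_drag_N": body_drag,
        "sliding_friction_single_leg_N": friction,
        "friction_to_leg_drag_ratio": friction / leg_drag,
        "adhesion_100pct_N": adhesion_force(100, 8.5e-7),
        "adhesion_200pct_N": adhesion_force(200, 8.5e-7),
        "froude_frequency_25mm_Hz": froude_scaled_frequency(20.0, 2.5e-3, 25e-3),
        "froude_frequency_250mm_Hz": froude_scaled_frequency(20.0, 2.5e-3, 250e-3),
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "formulas.json").write_text(json.dumps(results, indent=2))
    print(f"leg tip speed           {v_tip:.4f} m/s")
    print(f"single-leg drag         {leg_drag:.3e} N")
    print(f"whole-body drag         {body_drag:.3e} N")
    print(f"single-leg friction     {friction:.3e} N "
          f"({friction / leg_drag:.0f}x the leg drag -> drag is negligible)")
    print(f"Froude-scaled strides   25 mm: {results['froude_frequency_25mm_Hz']:.2f} Hz, "
          f"250 mm: {results['froude_frequency_250mm_Hz']:.2f} Hz")
    print(f"wrote {OUT / 'formulas.json'}")


if __name__ == "__main__":
    main()
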