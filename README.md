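# hexagait

**Why do fast-running insects keep three legs on the ground?** Most running
vertebrates minimize ground contact at speed, yet nearly every fast insect —
flies, ants, cockroaches — uses the statically stable tripod gait, in which
the support triangles {L1, R2, L3} and {R1, L2, R3} alternate. One
long-standing hypothesis is that the tripod gait is not the fastest possible
coordination but the one that lets a climbing insect traverse vertical
terrain with adhesive feet without peeling off.

`hexagait` is a package for testing that hypothesis in silico. It provides:

* a **quasi-static locomotion template** of a fly-scale hexapod (2.5 mm,
  0.85 mg, 20 Hz strides): prescribed periodic foot trajectories whose only
  free parameters are the relative leg phases, a Coulomb friction pyramid
  (per-axis bound μ·F_n), per-contact adhesion expressed as a percentage of
  the single-foot inverted-suspension force, and a peel rule that makes the
  model fall from vertical surfaces when its contacts cannot statically hold
  the body;
* **particle swarm optimization** (constricted PSO: w = 0.729,
  c₁ = c₂ = 1.49, per-dimension velocity cap 0.4) over the periodic 5-D
  phase space (L1 anchored at 0°), with forward velocity over 0.5 s as
  fitness and pre-fall distance credited to keep the landscape smooth;
* **footfall-diagram metrics**: tripod coordination strength
  (TCS = t₂/t₁ over a three-stride window, counting frames whose stance set
  is *exactly* a tripod triangle), atypical bipod-like coordination (co-swing
  of L1+R3, R1+L3 or L2+R2), stance counts, duty factors, support-polygon
  static stability, cost of transport COT = E/(m·g·d), and the tilt-test
  friction coefficient μₛ = tan θ;
* a **two-link robot leg mapping** (closed-form planar IK with feasible
  branch selection) for exporting any discovered gait to a hexapod robot;
* a **synthetic fly-videography generator** (500 fps stance traces with
  onset jitter, slips and dropouts) so every metric's recovery can be
  quantified without recordings.

## Worked example

```python
from hexagait import TRIPOD_A, BIPOD_B, SimulationCondition, simulate
from hexagait.analysis import cost_of_transport, static_stability_fraction

ground = SimulationCondition("ground", adhesion_level=0.0)
wall = SimulationCondition("wall_up", adhesion_level=200.0)

for name, gait in [("tripod-A", TRIPOD_A), ("bipod-B", BIPOD_B)]:
    g, w = simulate(gait, ground), simulate(gait, wall)
    print(name, f"ground {g.mean_speed:.3f} m/s, COT {cost_of_transport(g):.3f},"
          f" stability {static_stability_fraction(g):.0f}%,"
          f" wall fell={w.fell}")
```

prints

```
tripod-A ground 0.040 m/s, COT 0.050, stability 80%, wall fell=False
bipod-B ground 0.050 m/s, COT 0.040, stability 20%, wall fell=True
```

The bipod gait — front legs synchronized with the opposite rear leg and the
two middle legs moving together, three power strokes per cycle — is 25%
faster and cheaper per distance on flat ground because it never pauses
between power strokes, but with only two feet down it peels off a vertical
wall within a few hundredths of a second, while the tripod climbs
indefinitely.

The full in-silico experiment lives in `analysis/` as numbered drivers:

| script | what it does |
| --- | --- |
| `01_formula_checks.py` | closed-form physics (drag vs friction, Froude scaling) |
| `02_simulate_baseline_gaits.py` | tripod vs bipod under each condition |
| `03_optimize_gaits.py` | swarm optimization across all five conditions |
| `04_fly_emulation.py` | noisy synthetic fly trials and metric recovery |
| `05_robot_mapping.py` | joint-angle export for a two-link hexapod robot |

Running `03_optimize_gaits.py` reproduces the central result at desk scale
(10 swarms of 20 particles × 60 iterations per condition): all three
vertical-climbing conditions yield tripod-class winners with median TCS ≈
0.5, while ground locomotion without adhesion yields low-TCS (median ≈ 0)
bipod-family winners. There is also a `hexagait` CLI (`simulate`,
`optimize`, `study`, `analyze`, `synth`, `map-robot`, `render`, `classify`)
wrapping the same library calls.

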