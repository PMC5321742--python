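# Methods

## The model in one paragraph

A gait of a six-legged walker is encoded as five relative phases: each leg
repeats an identical motion cycle at a fixed stride frequency, and only the
timing of the cycles differs between gaits (the left front leg L1 anchors
the encoding at 0°). `hexagait` asks which phase vectors make a fly-scale
model fastest under different mechanical circumstances — climbing a vertical
surface with adhesive feet versus running on flat ground with or without
adhesion — by coupling a deterministic quasi-static locomotion template to a
stochastic swarm optimizer, and then scoring every winner with
footfall-based coordination metrics.

## Quasi-static locomotion template

The template deliberately replaces articulated rigid-body dynamics with the
smallest mechanical model that preserves the phenomena under study: contact
scheduling, friction-limited propulsion, adhesion-dependent grip, and
falling from vertical surfaces.

**Prescribed foot trajectories.** Each foot follows a fixed periodic
trajectory in the body frame: for a fraction κ of the cycle (default 0.4) it
is at surface level sweeping backward through `sweep_length` s = 1 mm
(power stroke), otherwise it returns forward along a smooth arc of
0.5 mm clearance. The sweep speed is s·f/κ = 0.05 m/s at the default
f = 20 Hz. κ < 0.5 is essential: it gives the classic tripod gait its
characteristic pauses between power strokes (two support windows of 0.4
cycle leave 2 × 0.05 cycle with no feet down), which is exactly why the
bipod family — three staggered support pairs covering the whole cycle — is
faster on the ground. κ > 1/3 lets three-group gaits achieve continuous
coverage. Because contact timing is prescribed, realized duty factor equals
κ for any gait that does not fall; emergent duty-factor variation across
optimized gaits is a full-dynamics phenomenon this template does not
reproduce (the stance-count contrasts between gait classes are carried by
the ideal-diagram metrics instead).

**Contact resolution.** Per time step (Δt = 1 ms, 50 steps per cycle; an
error is raised beyond a quarter cycle), the |C| contacting feet share the
normal gravity load equally, plus a constant adhesion force per foot.
Following the suspension definition, a 100% adhesion level equals one body
weight per contact (the force letting a single foot hold the inverted body);
experiments use 200%. A friction pyramid bounds the tangential force per
contact at μ_pyramid·F_n with μ_pyramid = 4 — an upper bound for sticking,
not a classical sliding coefficient. Tangential demand per contact is the
in-plane gravity share plus a per-stance-leg drag term μ·m_leg·g with
μ = 0.1 and m_leg = 1.42 × 10⁻⁷ kg (the sliding-friction estimate; this is
the only place the two friction coefficients meet, and they serve different
purposes). If demand fits within the pyramid the contacts stick and the
body advances at the sweep speed; otherwise the advance is scaled by the
available/demanded force ratio.

**Falling.** On the ground the model never falls. On walls two accumulators
govern failure. (1) *Airborne*: consecutive time without any load-bearing
contact (no contact, or zero normal force because adhesion is absent);
beyond τ_air = 10 ms the model is deemed detached. While unsupported on a
wall the body back-slides at |g_heading|/γ_slip (γ_slip = 200 s⁻¹ →
≈ 4.9 cm/s). (2) *Peel*: whenever the contact set cannot statically hold
the body — fewer than three contacts, a degenerate (collinear) support
polygon, or a projected centre of mass that is not at least 0.1 mm interior
to the support hull — a peel angle grows at rate m·g_tan·h/J_peel
(≈ 20 s⁻¹ at defaults: m = 0.85 mg, h = 1 mm COM standoff,
J_peel = 4.2 × 10⁻¹⁰ N m s) and decays at the same rate while the support
is sound; crossing θ_peel = 0.3 is a fall. The thresholds are calibrated so
that the ideal tripod (5 ms support gaps, sound triangles otherwise) climbs
indefinitely while any permanently two-legged coordination peels off within
a few hundredths of a second.

The COM-support term in the peel rule is a deliberate design choice: with a
bare "three non-collinear contacts" criterion, unbalanced triples such as
{L1, R1, L2} hold a wall exactly as well as a tripod triangle, and
optimization on the wall would not single out tripod coordination. Requiring
the COM strictly inside the hull encodes the torque argument directly. A
side effect worth knowing: the alternative tripod-B triples ({L1, L2, R3} /
{R1, R2, L3}) place the COM exactly on the L1–R3 hull edge, so under the
strict-interior margin they fail on walls — upward climbing in this template
uniquely favours the classic tripod, which is the sharper version of the
claim, at the cost of not reproducing tripod-B's appearance during downward
and sideways climbing.

Foot home positions (mirror-symmetric, middle feet slightly wider:
front/rear ±1.25 mm fore-aft, ±0.75 mm lateral; middle ±0.85 mm lateral)
make both tripod triangles contain the COM with ≈ 0.5 mm margin. The
support-pattern verdict uses home positions (not the ±0.5 mm sweep offsets),
which lets all 64 contact patterns be precomputed per model.

**Energy.** The ledger integrates tangential contact force × sweep speed.
Because total stance time per cycle (6κ leg-cycles) is gait-independent,
ground energy is nearly equal across gaits and cost of transport
COT = E/(m·g·d) is dominated by distance: the bipod's full coverage gives it
both higher speed and lower COT (0.040 vs 0.050 at defaults), without
energy ever being optimized for.

Two implementations of the stepping loop exist: a scalar reference
(`step`) and a vectorized `simulate` (clipped-cumsum identity for the peel
accumulator, run-length encoding for the airborne timer). Tests assert they
produce identical trajectories; everything downstream uses the vectorized
path. Simulation is fully deterministic.

**Closed-form formulas.** The P-controller servo law
(sign(p_t−p_c)·min(P|p_t−p_c|, ν_d)), drag ½ρc_D·A·v², Froude frequency
scaling f√(L/L_target) and the leg-tip speed 2πfL are exposed as standalone
functions. Drag is evaluated only to confirm it is negligible (three orders
of magnitude below sliding friction at fly scale); it is not part of the
locomotion loop. The servo law does not drive the quasi-static template.

## Swarm optimization

Canonical constricted PSO (inertia 0.729, cognitive = social = 1.49,
global-best topology) over [0,1)⁵ with two periodicity adaptations: the
attraction terms use the signed shortest circular displacement, and
positions wrap modulo 1. Velocities are clamped per dimension at 0.4 of the
parameter space (the cap could alternatively be read as a bound on the
velocity norm; per-dimension is used here and exposed in config). Fitness
is forward distance over 0.5 s divided by 0.5 s, with pre-fall distance
credited (never negative). The all-time best is reported, not the
final-iteration best; best-so-far fitness is non-decreasing by
construction and reproducible from the seed.

Two profiles: the full-scale study (50 particles × 150 iterations × 15
experiments per condition) and a desk profile (20 × 60 × 10) used by the
automated checks; the desk profile reproduces the ordinal conclusions in a
few seconds per condition. Experiment seeds derive from a base seed via
SHA-256 so every cell of the study is independent and reproducible.

## Gait classes and classification

Ideal phase vectors: tripod-A (0, 180, 180, 0, 0, 180); tripod-B
(0, 180, 0, 180, 180, 0) from its verbal definition (front+middle of one
side with the opposite rear leg); bipod-A (0, 240, 120, 120, 240, 0) and
bipod-B (0, 120, 240, 240, 120, 0), the two stepping orders of the pairs
(L1,R3), (R1,L3), (L2,R2) at 0/120/240°. The C variants ship as
provisional copies of their A variants (no published vectors to pin them
to) and the whole table is YAML-overridable. No left/right mirror
equivalence is applied: anchoring L1 at 0° breaks mirror symmetry on
purpose.

The classification error m between a candidate and an ideal vector is the
sum over six legs of minimal circular phase differences in degrees (any
monotone aggregate — mean, RMS — induces the same ranking; the sum keeps
m per-leg additive). Classification is primarily by this metric, with two
qualifications mirroring how gaits are actually judged: when the two best
classes are within 30° of each other the tie is resolved by
footfall-signature similarity (fraction of frames whose stance set occurs
in the class's idealized diagram), and a best error above 360° returns
"unclear". Provisional entries lose exact ties to their non-provisional
twins.

## Footfall metrics

TCS follows the three-stride protocol exactly: the window runs from an R1
stance onset to the last R1 swing frame three cycles later, and a frame
counts only if the stance set *equals* {R1, L2, R3} or {L1, R2, L3} — a
superset does not count. Bipod-like coordination is the fraction of the
same window in which L1+R3, R1+L3 or L2+R2 are simultaneously in swing
(frame-wise co-swing; an onset-aligned variant was considered and rejected
because co-swing is the only reading computable from stance traces alone).
Simulated diagrams anchor the window at the first R1 onset after the first
full cycle, since there is no touch-evoked start. Stance counts and duty
factors average over five cycles after omitting the first (steady state);
static stability is the percentage of frames in cycles 2–10 whose COM
projection lies inside (or on) the convex hull of the stance feet, with
fewer than three or collinear contacts counting as unstable by convention.
Note that with κ = 0.4 the simulated ideal tripod is statically stable 80%
of the time (the two 5 ms zero-contact gaps per cycle account for the
remaining 20%) — a duty-0.5 rendering would give ~100%.

## Synthetic data

The generator renders the ideal diagram of a named class at 500 fps /
20 Hz strides (25 frames per cycle) and perturbs it with annotation-style
noise: every bout boundary shifts by a rounded Gaussian (default SD 1.5
frames in the moderate profile), stance bouts acquire 1–3-frame spurious
swings with probability 0.1 (slips), swing bouts acquire stance blips
likewise. These magnitudes are declared assumptions — no quantitative noise
characterization of manual 500 fps annotation exists to calibrate against.
The generator emulates stance *timing* noise only: no kinematic noise, no
body-speed covariation, no inter-animal variability, and the
blocked-adhesion fly condition is emulated simply as "generate a
bipod-class trial", with no biomechanics of polymer-coated pulvilli.
Passing recovery tests therefore show that the metrics are robust to
annotation noise, not that they would survive every pathology of real
recordings. Tilt-table data are Gaussian angles (default SD 2°) around
arctan μₛ; the recovery estimate is tan of the mean angle.

## Robot mapping

Both the four-segment model leg and the two-segment robot leg use a
straight-down zero-angle convention (all joints at 0 → tip at (0, −Σl);
positive angles rotate distal segments forward). Forward kinematics is the
cumulative-angle sine/cosine sum; the two-link inverse kinematics is the
closed-form law-of-cosines pair, every solution verified by forward
substitution to 10⁻⁹ length units, with an explicit unreachable error
carrying the reach annulus [|e−f|, e+f]. Branch selection filters by joint
limits and prefers the knee-backward branch (configurable); a promotion
bias widens the robot's promotion range. Robot segment lengths default to
e = f = 1 placeholders (config values). The model tip path is taken from
the template's prescribed foot trajectory and scaled to 80% of the robot's
reach; since the mapping is per-leg and time-invariant, relative leg phases
— the gait — are preserved exactly. The physical robot experiment itself
(tracking, latex feet, speed measurement) is out of scope; the mapping
output is an exported joint-angle CSV.

## Numerical choices and degenerate inputs

* Cycle positions map float wrap jitter (values within 10⁻⁹ below 1) to 0,
  and stance tests use a 10⁻⁹ guard below duty/κ, so exact rational phase
  boundaries (e.g. duty 1/3 at 99 frames per cycle) land on the intended
  side.
* Fall-threshold comparisons carry a 10⁻⁹ absolute tolerance so the scalar
  and vectorized integrators cross on the same frame.
* PSO position wrap maps a result of exactly 1.0 (float modulo of a tiny
  negative) back to 0.
* Zero-distance runs make COT raise rather than return infinity;
  diagrams too short or too mangled for a metric's windowing raise
  `InsufficientDataError` (the fly-trial classifier maps that to
  "unclear", and the study table records NaN).
* Degenerate support polygons (< 3 or collinear contacts) are unstable by
  convention everywhere.

## Known limitations

The template is quasi-static: no inertia, no spring–mass dynamics, no
joint compliance, no yaw or turning, no aerodynamics in the loop, and
prescribed (not emergent) duty factors. Fall behaviour is a calibrated
two-accumulator abstraction, not contact mechanics; downward and sideways
climbing inherit the upward peel rule, so condition-specific failure modes
(e.g. toppling forward on descent) are not distinguished, and tripod-B
does not survive walls under the strict COM-interior margin. Desk-scale
optimization (20 × 60 × 10 seeds) reproduces ordinal conclusions, not the
full-scale study's numerical distributions.
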