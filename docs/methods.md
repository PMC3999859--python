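# Methods

This note documents the models behind the virtual plant, the control
semantics, the defaults that matter, and what the desk-scale tests do and do
not demonstrate about real hardware.

## Simulated time

All sequencing runs against a purely virtual clock (`SimClock`): time
advances only when the engine steps it, so multi-hour campaigns execute in
seconds of wall time and nothing ever sleeps. The default tick is 1
simulated second, mirroring the once-per-second sensor interrogation cadence
of the physical rig; scenario runners use 2–10 s ticks where the dynamics
allow (the stability guard below bounds the step). The `--accel` CLI flag is
accepted for interface symmetry with hardware deployments but has no effect
on simulated runs.

## Column model: tanks in series with a water budget

The packed bed is a cascade of *N* ideal stirred tanks (default *N* = 20)
of total void volume *V*. Each step transfers a slug *Q·dt* downstream by
explicit upwind update; the scheme is exactly mass-conserving and requires
*Q·dt < V/N* (enforced, error otherwise). Tanks-in-series was chosen over an
axial-dispersion PDE because it reproduces the two observable features the
control logic cares about — a first temporal moment of exactly *V/Q*
independent of *N*, and a front width of order one column volume at
*N* ≈ 20 — with unconditionally stable, trivially testable numerics.
`mean_residence_time` *measures* the moment from a simulated tracer impulse
rather than returning *V/Q*, so the identity is a check, not an assumption.

Hydration chemistry is idealised as instantaneous whenever water is
available, because at the operating point (100 °C, 20 min residence) the
real transformation is quantitative; the rate limitation worth modelling is
water availability alone. Each tank holds free (fluid-phase) water plus a
share of the catalyst's bound-water reserve W₀ (default 1.08 mmol for the
2.5 g bed, scaling linearly with bed mass: 2.16 mmol for 5 g). Reaction
consumes free water first, then bound water; excess free water replenishes
the bound reserve up to capacity. On a dry feed this yields sustained
quantitative conversion for W₀/(C_N·Q) — 180 min at 0.06 M and
0.1 mL min⁻¹ — followed by collapse over about one column volume.
Temperatures below 100 °C scale the per-step reaction extent by a
configurable factor (default 0.5); this is a qualitative knob, not a kinetic
model. The "duration of sustained conversion" reported by the acceptance
script is the plateau width between the outlet signal's 50% rise and 50%
fall crossings, which excludes the startup elution lag (~one column volume)
from the quoted figure.

## Pressure, faults, alerts

Pressure is nominal (default 8 bar) unless a scheduled fault is active.
Defaults — low alarm 2 bar, high alarm 15 bar, bubble reading 0.5 bar,
over-pressure reading 18 bar — are conventions of this simulator, exposed in
config, since sensible site-specific values belong to the installation. A
`bubble_loss` fault suspends column inflow and persists until an explicit
`re_prime` action (scheduled in the fault file or called live); the engine
never auto-recovers, matching the reality that a bubbled pump needs manual
intervention. Overlapping faults on one device are rejected. Alerts carry
{severity, device, parameter, text, timestamp} and are deduplicated per
fault onset.

## Control semantics

Monitor rules are evaluated every tick in registration order. Predicates are
strict (`above` means >); no hysteresis is applied by default. Immediate
rules gate collection the same tick their predicate changes; delayed rules,
after their predicate recovers, block for a resume delay — the symbolic
`one_column_volume` resolves to 60·V/Q seconds at the configured flow. The
engine guarantees (resume − recovery) ≥ delay exactly in simulated time.
Valve switches take routing effect on the following step, so each tick's
effluent is routed by the position in force when the tick began. The
absorbance collect threshold defaults to 50% of the full-conversion plateau
signal. Temperature stability uses a ±2 °C band by default; the band width
is config because "stable" for a heater is an installation choice. Event
logs are JSON-lines with fixed field order: identical program, plant and
seed reproduce the log byte for byte, which the tests assert.

## Reservoir coupling and the two-step state machine

The reservoir integrates (inflow − outflow)·dt, clamps to [0, capacity], and
emits crossing events (high, low, overflow risk, empty). The two-step
runner's thresholds default to: step 2 starts once the level first reaches
10 mL, step 1 stops at capacity (50 mL) and restarts at the 2 mL low mark,
step 2 pauses below 2 mL. Restart-at-low rather than restart-at-zero is
deliberate: the withdrawal pump's inlet cannot reach the last couple of
millilitres of a pear-shaped vessel, so the low mark *is* empty up to
holdup. With 0.2 mL min⁻¹ in and 0.1 mL min⁻¹ out this gives a 48 mL swing
filled at 0.1 mL min⁻¹ net and drained at 0.1 mL min⁻¹ — a 16.0 h cycle,
measured from the event log between successive step-1 restarts. State
invariants (step 2 only after its start level was reached once; step 1 never
on at a full reservoir; finished implies low level and step 1 off) are
asserted on every tick of every run and reported as violations, not
exceptions, so the CLI can exit non-zero on them.

## Hydrogenation response surface and factorial machinery

The paper-scale hydrogenation unit exposes three factors — temperature on a
10 °C grid (levels 40/100), hydrogen mode as a two-level categorical
(20 bar / full, coded ±1 with no attempt at a bar scale), and flow
(0.1/0.2 mL min⁻¹). Responses are linear in coded factors. Default
coefficients (conversion: intercept 0.72, hydrogen +0.18, temperature +0.05,
flow −0.03; tetrahydro-intermediate fraction: intercept 0.08, temperature
−0.035, flow +0.025, hydrogen −0.01; byproduct 0.02) encode the
qualitative structure of the real reaction — hydrogen mode dominates
conversion, hot-and-slow removes the partially reduced intermediate — and
live in config because only that ordering, not magnitudes, is established.
Simulated NMR integral rows are derived from the fractions
(I1 = product, I2 = residual substrate, I4 = intermediate, Ix = byproduct)
and the four responses are computed from integrals exactly as for measured
tables: conversion = 1 − I2/ΣI, yield = I1/ΣI, impurity ratios relative to
I1+I2. These formulas are this package's stated convention for making the
four quantities precise.

Designs are full 2^k with r replicates, randomised by a seeded permutation,
with sample ports assigned cyclically over the multi-position valve (9
ports: 16 runs → batches of 9 and 7). Effects are contrast differences
(equal to twice the orthogonal least-squares coefficients, tested against
that oracle); with r ≥ 2 the pure-error variance pooled over cells gives
SE(effect) = √(4s²/n) and a |t| ratio, with |t| > 2 as the conventional
importance flag (r = 2 on 2³ leaves 8 pure-error df). Each campaign run
holds its settings for 3 cartridge volumes before sampling, standing in for
the 30–60 min stabilisation of the real unit.

## Level sensing

Detection is green excess max(G−R, 0) → strict threshold (default 60 of
255) → connected components (8-connectivity, minimum area 20 px to reject
specks) → largest region's centroid height from the image bottom, with area
ties broken topmost-then-leftmost and centroids rounded half-up. Pixel
height maps to volume by piecewise-linear interpolation of a monotone
calibration table, clamped at the ends; a two-point table is the linear
fallback, more points accommodate a pear-shaped vessel. The synthetic scene
generator renders a grey bench, darker vessel, liquid fill, a green float
ellipse at the commanded level, optional red/blue clutter rectangles and
seeded salt noise; it emits the true centroid alongside the frame. Because
clutter is never green and salt is white (G−R = 0), the pipeline's colour
stage removes distractors almost deterministically — the cluttered-accuracy
test (≥ 90% of 50 frames within the float radius) therefore exercises the
plumbing, not a hard segmentation problem. Real frames add lighting
gradients, reflections and colour bleed that the generator does not model;
passing these tests shows algorithmic correctness, not camera robustness.

## Problem sizes and determinism

Scenario tests run at 2–10 s ticks over 2–40 simulated hours (the two-step
cycle measurement spans ~32 h of simulated time in about a second of wall
time). All randomness — run-order permutations, analyzer and integral
noise, clutter placement — flows through numpy `default_rng` seeded from the
caller; defaults turn noise off so exact assertions hold.

## Known limitations

No real kinetics, heat transfer, solvent effects or pump pulsation; the
hydrogenation surface is a stand-in with invented magnitudes; faults are
limited to the pressure channel; the vision module assumes a fixed camera
and a visible green float; no hardware drivers or wire protocols are
included — the device layer is the seam where they would attach.
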