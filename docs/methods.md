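# Methods

This note documents the model behind `resusbench`, the defaults it ships
with, and the choices made where the design was genuinely open. Everything
quantitative stated here is computed by the test suite or the example
scripts; nothing is asserted that the code does not reproduce.

## Plant

### Vessel geometry

The plant's pressure–volume relationship is encoded as the geometry of an
open hydrostatic reservoir. Port pressure equals the fluid column height
divided by the hydrostatic constant `h` (13.595 mm of water per mmHg, water
near 4 °C; configurable for other working fluids). Given a compliance curve
`MAP(V)` in mmHg per mL, `design_vessel_from_curve` substitutes `z = P·h`,
inverts the curve to `V(P)`, and assigns the local radius
`r(z) = sqrt((1/π)·dV/dz)`. The construction requires `dMAP/dV > 0`
throughout the valid range and rejects curves with plateaus, naming the
offending pressure.

Shipped curves:

* **whole blood** — linear, slope chosen so the vessel is a right cylinder
  of equivalent radius 27 mm (compliance π·27²·h ≈ 31.14 mL/mmHg), valid
  0–90 mmHg;
* **crystalloid** — parabolic, `MAP(V) = 0.034·V − (34/9×10⁶)·V²`, which
  passes 68 mmHg at 3000 mL with monotonically decreasing stiffness
  (vertex 76.5 mmHg at 4500 mL), valid 0–74 mmHg so that an infusate
  switch near the 68 mmHg target has capacity headroom.

The swine regressions these emulate are not published as coefficients, and
the printed crystalloid radius formula is typographically ambiguous in the
source text, so both curves are configuration inputs rather than constants;
the defaults above are this package's documented choice (volumes on a
bench scale consistent with a ~2300 mL whole-system deficit at 40 mmHg).

Volume integrals use a composite trapezoid rule on a fixed 0.1 mm height
grid. Both directions of the P↔V map interpolate the same grid, which makes
them exact inverses of each other (round-trip error < 1e-5 mmHg is a tested
invariant; for the cylinder the trapezoid rule is analytically exact).
Subject variability multiplies the equivalent radius, scaling volumes by
the square of the factor.

### Dynamics and waveform

Volume is integrated with explicit Euler at 0.1 s from the infusion and
outflow pump rates, clamped to `[0, capacity]` with starvation/overflow
flags (the physical reservoir runs dry or spills; it does not go negative).
The arterial waveform is the hydrostatic pressure plus a static elevation
offset, plus a 15 mmHg additive step when the vasopressor resistance branch
is engaged, plus a zero-mean raised-cosine ejection pulse (120 beats/min,
default 10 mmHg peak-to-trough, ejection 30% of the beat, synthesised at
100 Hz). The pulse shape is unspecified in the source protocol and is a
free choice here; because it is zero-mean by construction, the sensed MAP
is independent of it. The vasopressor is modelled as an additive pressure
step rather than a resistance×flow product because loop flow is constant
in the simulator; magnitude and duration are configurable.

The monitor MAP is the arithmetic mean of the raw waveform over a trailing
5 s window. Inside the scenario engine the window averages the
non-pulsatile pressure at the 0.1 s plant step: with the default timing
(0.5 s beat, 5 s window = 10 whole beats, samples aligned to beat starts)
the pulse contributes exactly zero to the window mean, so this equals
averaging the raw waveform while costing ten times fewer samples. The
general `sensed_map` operation on arbitrary raw samples exists for external
traces and is tested independently.

## Outflow engine

Hemorrhage is `Q_H = MAP × HF × (1 + u)` with `u` uniform on ±5%, redrawn
once per 1 s outflow update from a single seeded generator; urine is a
fixed 5 mL/min at MAP ≥ 50 mmHg and zero below; total outflow is clamped to
the pump range (default 0–600 mL/min). HF bookkeeping, evaluated on the
sensed MAP each second:

* **coagulation** — `HF ← HF·exp(−c·dt)` while 30 < MAP ≤ 70 mmHg, with
  `c` = 0.05/min for whole blood and 0.02/min for crystalloid. The decay
  form is not specified in the source protocol ("gradually reduced"); an
  exponential was chosen as the natural memoryless decay and both rates are
  configuration values. The infusate dependence (faster clotting with whole
  blood) is the required property.
* **low-pressure shutoff** — below 30 mmHg the *effective* HF is zero but
  the stored value is retained, so bleeding resumes if pressure recovers.
* **over-pressure penalty** — above 70 mmHg HF grows at 0.05/min
  ("clots dislodged"); 2 mmHg above that threshold the clot reset
  additionally restores HF to at least its scenario-initial value and zeroes
  the decay clock. The two thresholds come from different parts of the
  source description and both are configurable; the restore behaviour can
  be disabled.
* **events** — `massive_hemorrhage` overrides the effective HF with
  255/68 ≈ 3.75 mL/min/mmHg (a 255 mL/min bleed at target pressure,
  comparable to femoral artery flow) until released; `ramp_to_cap` grows HF
  linearly at 0.2/min toward an explicit cap with coagulation disabled,
  modelling trauma-induced coagulopathy. The TIC ramp rate is deliberately
  faster than the over-pressure penalty: it must traverse its range within
  a 30 min scenario.

Severity initialisations are expressed as bleed rate at 68 mmHg: high
120 mL/min (HF = 120/68), low 60 mL/min.

## Controller

The reference decision table maps the error `target − sensed MAP` through
six bands to a fraction of the 500 mL/min pump maximum:

| error (mmHg) | ≥25 | [15,25) | [10,15) | [5,10) | [2,5) | [0.5,2) | <0.5 |
|---|---|---|---|---|---|---|---|
| fraction | 1.00 | 0.60 | 0.45 | 0.35 | 0.30 | 0.20 | 0 |

The published source for this controller family does not print its numeric
bands, so the shipped table is this package's own tuning, chosen from the
loop gains: with ≈31 mL/mmHg whole-blood compliance, the near-target
trickle (100 mL/min) must exceed the residual clotted bleed plus urine for
the controller to close the last mmHg to the 99%-of-target termination
threshold, while the [2,5) band (150 mL/min) held stale for 120 s is what
carries the slow controller past the 70 mmHg over-pressure threshold. The
table is fully overridable in configuration, and validation enforces six
bands, strictly decreasing bounds, and non-increasing fractions. Output is
recomputed at multiples of the sampling period (first update at t = 0) and
held in between; the controller input is always the 5 s windowed MAP
regardless of period.

## Scenarios

Four chained challenges at a 68 mmHg target, run in succession with state
carry-over (an optional mode re-initialises a 40 mmHg baseline between
scenarios):

1. initial hypovolemia at 40 mmHg (≈2300 mL whole-system deficit ledger),
   clotting bleed, whole blood;
2. massive re-bleed, then whole-blood resuscitation;
3. as 2 plus a 15 mmHg vasopressor step applied with the re-bleed and
   removed after 10 min;
4. infusate switched to crystalloid at equal pressure, a rapid loss
   followed by the non-clotting escalating bleed, hard 30 min cap.

The massive event releases when sensed MAP falls to 40 mmHg *or* after
5 min, whichever comes first (both single-criterion modes are available).
The pure pressure-release rule cannot stand alone: an active controller
holds MAP near 55 mmHg during the event, so the release would never fire.
On release HF returns to its scenario initialisation with the coagulation
clock restarted. Scenarios 1–3 terminate 15 min after sensed MAP first
reaches 99% of target — samples taken while the massive event is still
active do not count, since carry-over means every scenario opens at the
previous scenario's stabilised pressure — with a 60 min safety cap.
Scenario 4's HF cap is a required, deliberately un-defaulted choice; the
examples use 10 mL/min/mmHg for high severity (the bleed outgrows the
pump maximum near 50 mmHg, so resuscitation must fail) and 0.9 for low
(a sustained mild bleed the controller can beat).

Loop cadences: plant 0.1 s, outflow/record 1 s, controller at its sampling
period. All randomness flows from one `numpy` generator seeded per run;
identical seeds give byte-identical records (a tested invariant).

## Metrics

All metrics operate on the sampled MAP series with times converted to
minutes. Medians over even counts take the midpoint of the central pair.
Divergence implements the closed-form least-squares slope of |PE| against
time ×60 (%/h) and is cross-checked in the tests against an independent
`polyfit` oracle to 1e-9. Areas use right-endpoint sums
`Σ (P_i − P_T)·Δt_i / P_T`, reported as magnitudes; the signed difference
`area_above − area_below` equals `Σ PE_i·Δt_i/100` exactly (tested).
Effectiveness weights samples by their interval, so irregular traces are
handled. Steady state is estimated as the mean of the final 10% of samples
with onset the earliest sample after which the trace stays within ±5% of
that value; `found` is false when even the final sample violates the band.
Overshoot is reported both relative (% of steady state) and absolute
(mmHg). Wobble is reported for the full scope and, when a steady state
exists, restricted to the post-onset segment. The rise area truncates the
below-target area at the first sample ≥ 90% of *target* (rise time uses
90% of *steady state*), and is emitted for the first scenario of a
sequence, whose starting point is uniform across configurations.

## What the simulator does and does not show

The generator's defaults emulate the bench protocol: scaled-down volumes,
water as working fluid, pressure-proportional bleeding with multiplicative
noise, and idealised pumps with instant rate changes. Passing tests
demonstrate the logic and the controller-ranking machinery, not clinical
fidelity: there is no pressure-wave propagation, tubing compliance,
viscosity, hematocrit/dilution effect on bleeding, or sensor artifact, and
the vasopressor is a static pressure step. One emergent property worth
knowing: because hemorrhage is proportional to MAP and the controller is
banded, a failing resuscitation settles into a quasi-equilibrium (bleed ≈
infusion) rather than free-falling, so the steady-state detector can
report a "steady" value far from target at the end of a diverging
scenario; the divergence metric (positive slope of |PE|) is the reliable
indicator of that failure mode.

## Numerical choices

Height grid 0.1 mm; plant step 0.1 s; waveform 100 Hz; outflow/record 1 s;
P↔V inversion by shared-grid interpolation (exact round trip); root finding
is avoided entirely. Clamps are applied with logged flags rather than
errors wherever the physical rig would saturate. Termination comparisons
use a 1e-9 s guard against float drift in time accumulation.
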