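# resusbench

A software benchtop for developing and scoring **closed-loop hemorrhage
resuscitation controllers**. Automated goal-directed fluid therapy needs a
place to fail safely: testing an infusion controller against live animals is
slow and costly, and purely numerical patient models skip the plumbing that
breaks real devices. `resusbench` reproduces, in software, a pulsatile
flow-loop testbed whose pressure–volume response is set by physical
reservoir geometry, and drives it through standardized hemorrhage scenarios
while scoring the controller with twelve performance metrics.

## The model

**Plant.** System volume lives in a hydrostatic vessel whose shape encodes a
target compliance curve. For an open vessel, port pressure is the height of
the fluid column (13.595 mm H₂O per mmHg for water), so a MAP-vs-volume
regression `MAP(V)` can be built as geometry: substitute `z = P·h`, invert
to `V(z)`, and set the local radius `r(z) = sqrt((1/π)·dV/dz)`. A linear
whole-blood response yields a right cylinder (the default has equivalent
radius 27 mm); a parabolic crystalloid response yields a widening funnel.
Subject variability rescales the equivalent radius; switching infusates
swaps vessels at equal pressure. A zero-mean raised-cosine pulse (120 bpm,
2 mL stroke) rides on the hydrostatic pressure, and the monitor MAP is the
5 s trailing mean of the raw waveform.

**Outflow.** Hemorrhage is `Q_H = MAP × HF`, where the hemorrhage factor
`HF` (mL/min per mmHg) decays exponentially with an infusate-dependent
coagulation rate, is zeroed below 30 mmHg, escalates whenever the controller
drives MAP above 70 mmHg (clots dislodged; a full clot reset 2 mmHg higher),
and is perturbed by ±5% uniform noise. Urine adds a basal 5 mL/min at
MAP ≥ 50 mmHg. Scripted events model tourniquet failure (a 255 mL/min bleed
at 68 mmHg) and trauma-induced coagulopathy (a non-clotting, escalating
bleed).

**Controller.** The reference controller is a six-step decision table: the
error `MAP_T − MAP` (target 68 mmHg) selects a fraction of the pump maximum
(500 mL/min), recomputed every sampling period (5 s or 120 s) with
zero-order hold. Any object with a `rate(t, sensed_map)` method can be
plugged in instead.

**Scenarios.** Four chained challenges: (1) resuscitation from 40 mmHg with
a clotting bleed; (2) a massive re-bleed; (3) the re-bleed plus a 15 mmHg
vasopressor step withdrawn after 10 min; (4) crystalloid resuscitation
against a non-clotting, escalating bleed, capped at 30 min. Scenarios 1–3
end 15 min after MAP first holds 99% of target.

**Metrics.** Per scenario and whole-run: the Varvel statistics of the
percentage performance error `PE_i = (P_i − P_T)/P_T × 100` — MDPE (bias),
MDAPE (accuracy), wobble, and divergence (the least-squares slope of |PE|
vs time, in %/h) — plus relative overshoot, effectiveness (% of time within
±5 mmHg of target), rise time to 90% of steady state, volume efficiency
(infused/lost), average infusion rate, and the target-normalised areas
above/below the setpoint (over-/under-resuscitation burden, in minutes),
with a rise-area variant for the first scenario.

## Worked example

```bash
python examples/run_scenarios.py
```

```
--- 5 s sampling period ---
scenario 1: 23.9 min, target reached, over-pressure   0 s
scenario 2: 28.3 min, target reached, over-pressure   0 s
scenario 3: 30.8 min, target reached, over-pressure   0 s
scenario 4: 30.0 min, target NOT reached, over-pressure   0 s
whole run: MDPE -2.7%  MDAPE 3.1%  wobble 2.1%  effectiveness 60%  volume efficiency 0.98
--- 120 s sampling period ---
scenario 1: 17.9 min, target reached, over-pressure   0 s
scenario 2: 23.9 min, target reached, over-pressure   0 s
scenario 3: 24.3 min, target reached, over-pressure  51 s
scenario 4: 30.0 min, target NOT reached, over-pressure   0 s
whole run: MDPE -5.4%  MDAPE 5.7%  wobble 4.9%  effectiveness 57%  volume efficiency 0.96
```

At the slow 120 s sampling period the stale zero-order hold overshoots the
70 mmHg over-pressure threshold (51 s above it in scenario 3 here; at low
bleed severity this recurs in every whole-blood scenario), triggering
re-bleed penalties the 5 s controller avoids entirely — the
sampling-period trade-off the platform exists to expose. Scenario 4's
escalating non-clotting bleed eventually outgrows the 500 mL/min pump:
neither configuration reaches target and MAP diverges from the setpoint.

Other entry points: `examples/design_vessels.py` (curve → geometry),
`examples/infusate_switchover.py` (whole blood budget, then crystalloid),
`examples/score_recorded_trace.py` (metrics on an external CSV), and the
`resusbench` CLI (`run`, `metrics`, `design-vessel`, `demo` subcommands).

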