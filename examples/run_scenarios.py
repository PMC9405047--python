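"""Run the four chained hemorrhage scenarios and score the controller.

The high-bleed protocol is run twice with the shipped decision-table
controller: once at a 5 s sampling period and once at 120 s.  The slow
controller overshoots past the 70 mmHg over-pressure threshold and triggers
re-bleed penalties; the fast one does not.  Scenario 4 (non-clotting,
escalating hemorrhage resuscitated with crystalloid) overwhelms both.
"""

from resusbench import (
    ControllerConfig,
    default_sequence,
    reports_for_records,
    run_sequence,
)

specs = default_sequence("high", hf_ramp_cap=10.0)

for period in (5.0, 120.0):
    records = run_sequence(
        specs, ControllerConfig(sampling_period=period), seed=1
    )
    print(f"--- {period:.0f} s sampling period ---")
    for rec in records:
        m = rec.meta
        status = "reached" if m["target_reached"] else "NOT reached"
        print(
            f"scenario {m['scenario_id']}: {m['duration_s'] / 60:4.1f} min, "
            f"target {status}, over-pressure {m['overpressure_seconds']:3d} s"
        )
    whole = reports_for_records(records)[-1]
    print(
        f"whole run: MDPE {whole.mdpe_pct:+.1f}%  MDAPE {whole.mdape_pct:.1f}%  "
        f"wobble {whole.wobble_pct:.1f}%  effectiveness {whole.effectiveness_pct:.0f}%  "
        f"volume efficiency {whole.volume_efficiency:.2f}"
    )

# MDPE (median performance error) is the controller's bias relative to the
# 68 mmHg target; effectiveness is the share of time spent within +/-5 mmHg
# of it; volume efficiency is infused volume per unit volume lost.
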