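"""Resource-limited resuscitation: a fixed whole-blood budget, then crystalloid.

Starting from 40 mmHg, a scripted volume of whole blood is infused; the
crystalloid vessel is then pre-filled to the same pressure and the infusion
continues until the 68 mmHg target.  The pressure trace is linear during
the whole-blood leg and parabolic afterwards, with no jump at the switch.
"""

from resusbench import (
    PlantState,
    design_vessel_from_curve,
    pressure_at_volume,
    simulate_constant_infusion,
    switch_infusate,
    volume_at_pressure,
    whole_blood_curve,
    crystalloid_curve,
)

wb = design_vessel_from_curve(whole_blood_curve())
crys = design_vessel_from_curve(crystalloid_curve())

for wb_budget in (300.0, 600.0, 800.0):
    v0 = volume_at_pressure(wb, 40.0)
    state = PlantState(active_profile=wb, contained_volume=v0 + wb_budget)
    p_switch = pressure_at_volume(wb, state.contained_volume)
    state = switch_infusate(state, crys)
    p_after = pressure_at_volume(crys, state.contained_volume)
    trace = simulate_constant_infusion(crys, 500.0, p_switch, 68.0)
    print(f"WB {wb_budget:.0f} mL: switch at {p_switch:.2f} mmHg "
          f"(continuity error {abs(p_after - p_switch):.1e} mmHg), "
          f"then {trace['infused_volume_mL'].iloc[-1]:.0f} mL crystalloid to 68 mmHg")

# The smaller the whole-blood budget, the lower the switch pressure and the
# more crystalloid is needed — and crystalloid needs progressively more
# volume per mmHg as pressure rises.
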