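"""Design both vessels from their compliance curves and characterise them.

A linear whole-blood MAP-vs-volume response yields a right cylinder; the
parabolic crystalloid response yields a funnel with curved walls.  The
characterisation protocol fills each vessel at a constant 500 mL/min and
records the pressure, reproducing the compliance curve it was designed from.
"""

import numpy as np

from resusbench import (
    design_vessel_from_curve,
    simulate_constant_infusion,
    volume_at_pressure,
    whole_blood_curve,
    crystalloid_curve,
)

for name, curve in [("whole blood", whole_blood_curve()),
                    ("crystalloid", crystalloid_curve())]:
    profile = design_vessel_from_curve(curve)
    r_port = float(profile.radius_fn(0.0))
    r_top = float(profile.radius_fn(profile.height_max))
    print(f"{name}: radius {r_port:.1f} mm at port -> {r_top:.1f} mm at top, "
          f"height {profile.height_max:.0f} mm, capacity {profile.capacity_ml:.0f} mL")

    trace = simulate_constant_infusion(profile, 500.0, 1.0, 68.0)
    v0 = volume_at_pressure(profile, 1.0)
    expected = np.asarray(curve.pressure(v0 + trace["infused_volume_mL"].to_numpy()))
    dev = float(np.max(np.abs(trace["pressure_mmHg"].to_numpy() - expected)))
    print(f"  fill 1->68 mmHg: {trace['infused_volume_mL'].iloc[-1]:.0f} mL infused; "
          f"max deviation from the design curve {dev:.2e} mmHg")

# A constant radius top-to-bottom means constant compliance (linear response);
# the widening crystalloid funnel means each extra mmHg costs more fluid.
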