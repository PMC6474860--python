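"""Five-hour hydration study over eight simulated replicate eyes.

Each eye is a jittered copy of the default cornea; every hour it swells a
little more (6% thickness gain after hour 1, plateauing near 13%).  The
summary tabulates per-hour means, percent changes versus the fresh state,
and exact Wilcoxon signed-rank p-values for the paired comparison.
"""

import octinflate as oi
from octinflate.geometry import GeometrySeries
from octinflate.mechanics import MechanicsConfig
from octinflate.pipeline import hysteresis_by_hour, modulus_at

hours = (0.0, 1.0, 2.0, 3.0, 4.0)
results = []
for eye in oi.replicate_params(n=8, rel_noise=0.03, seed=42):
    states = oi.simulate_geometry(oi.PressureSchedule.hydration_series(hours), eye)
    curves, moduli = oi.build_curves(
        GeometrySeries.from_truth(states), MechanicsConfig(cap_base_mm=eye.B)
    )
    hyst = hysteresis_by_hour(curves)
    for h in hours:
        T0 = next(s.T_um for s in states if s.hour == h and s.P == 0.0 and s.phase == "loading")
        results.append(
            oi.EyeMechanics(h, T0, modulus_at(moduli, 15.0, hour=h),
                            hyst[h].area_kpa, hyst[h].area_mmhg)
        )

table = oi.hydration_summary(results).to_frame()
cols = ["hour", "thickness0_um", "thickness0_um_pct_change", "thickness0_um_p"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print(
    "\nZero-pressure thickness swells ~6% in the first hour and saturates "
    "near 13% by hour 4; with all 8 eyes swelling, the exact paired Wilcoxon "
    "p-value sits at its n=8 floor of 2/256 = 0.0078."
)
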