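"""Render one speckled B-scan and recover its geometry by segmentation.

Renders the 15 mmHg loading state (bright anterior surface, epithelium
band, posterior surface at optical depth n*T), detects both boundaries,
divides the optical gap by the group index 1.389, and compares the
measured thickness/radius with the generator's ground truth.
"""

import octinflate as oi
from octinflate.segmentation import correct_refraction, detect_surfaces

schedule = oi.PressureSchedule((oi.PressureStep(15.0, "loading"),))
state = oi.simulate_geometry(schedule)[0]
scan = oi.render_bscan(state, oi.OpticsConfig(seed=42))  # speckle sigma 0.3

optical = detect_surfaces(scan)
physical = correct_refraction(optical, scan.n_group)

T = oi.apex_thickness(physical)
R = oi.fit_radius(physical)
frac = (optical.quality == "detected").mean()

print(f"B-scan: {scan.n_rows} x {scan.n_cols} px, {frac:.0%} of columns detected directly")
print(f"measured thickness  T = {T:8.2f} um   (truth {state.T_um:8.2f} um)")
print(f"measured radius     R = {R:8.3f} mm   (truth {state.R_mm:8.3f} mm)")
print(
    "\nThe central-3-mm mean thickness lands within a couple of micrometres "
    "of truth despite 30% multiplicative speckle, because boundary errors "
    "average out over ~300 A-lines."
)
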