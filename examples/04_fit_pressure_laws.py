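"""Fit the empirical pressure laws to a simulated loading series.

Recovers the shifted power-law thickness T = a - b*P^c, the linear radius
R = r0 + slope*P, and the saturating-exponential apex displacement from
noiseless simulated data, demonstrating exact parameter recovery.
"""

import numpy as np

import octinflate as oi

states = oi.simulate_geometry(oi.PressureSchedule.loading_only())
P = np.array([s.P for s in states])

tf = oi.fit_thickness_power(P, [s.T_um for s in states])
print(f"thickness:    T(P) = {tf.a:.1f} - {tf.b:.1f} * P^{tf.c:.3f}   (rss {tf.rss:.2e})")

mask = P >= 2.0
rf = oi.fit_radius_linear(P[mask], np.array([s.R_mm for s in states])[mask])
print(f"radius:       R(P) = {rf.intercept:.3f} {rf.slope:+.3f} * P      (rss {rf.rss:.2e})")

df = oi.fit_displacement_exponential(P, [s.D_um for s in states])
print(f"displacement: D(P) = {df.Dmax:.1f} * (1 - exp(-P/{df.Pc:.1f}))")

print(
    "\nAll three fits are deterministic profiled least squares; on noiseless "
    "model data they return the generating coefficients to solver tolerance, "
    "so any residual on measured data reflects the measurement itself."
)
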