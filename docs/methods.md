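# Methods

This note documents the models implemented in `octinflate`, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the numerical choices that matter.

## Physical setting

A freshly excised porcine cornea (epithelium intact, with a scleral ring)
is clamped at the limbus in an artificial anterior chamber; a saline column applies
hydraulic pressure (0–60 mmHg, in the order 0, 2, 5, 10, …, 60 and back)
to the posterior surface while an LF-OCT images a central cross-section
at every step. The sclera is treated as rigid and the limbus as fixed, so
all deformation is corneal.

## Thin-walled-sphere mechanics

Because the corneal thickness T (~1 mm) is small against the radius of
curvature R (~8.4 mm), the cornea is modelled as a thin spherical shell.
At internal pressure P the circumferential (hoop) stress is

    σ = P · R / (2 T)        [kPa; 1 mmHg = 0.1333224 kPa]

with R the anterior apex radius and T the central-3-mm mean thickness.
Deformation is tracked volumetrically through the parabolic cap of fluid
under the cornea, of base width B = 5.25 mm (fixed by the chamber) and
apical height H, with V = (π/2)·H·B². The strain is the fractional
volume change relative to the 2 mmHg **loading** state,

    ε = (V − V₀) / V₀ ,

a sign convention chosen so that inflation gives positive strain and the
tangent modulus of a stiffening shell,

    E_c = 3 (1 − ν) σ / ε ,      ν = 0.40,

comes out positive. (The same quantity is sometimes written with the
opposite sign, (V₀ − V)/V₀; only the sign differs, not the magnitude.)
The 2 mmHg reference is used because a cornea first exhibits its proper
curvature, and a stable apex position, at about that pressure; states
below the reference are excluded from the stress–strain curves, and no
modulus point is emitted at the reference itself (ε = 0 there).

The cap height is bookkept as

    H = H₂ + ΔD/1000 + (T₂ − T)/1000      [mm]

i.e. the posterior apex rises by the anterior apex rise ΔD plus the
apical thinning T₂ − T. H₂, the cap height at 2 mmHg, is an instrument-
measured quantity in a real experiment; the generator defaults it to
3.0 mm (a typical corneal sagittal height) and it is configurable
everywhere. H₂ only enters as the normaliser of ε, so it scales all
moduli by a common factor.

Hysteresis is the area enclosed between the loading and unloading
stress–strain curves: both are interpolated linearly onto a uniform
512-point grid over the **intersection** of their strain ranges (no
extrapolation) and the trapezoidal integral of |σ_load − σ_unload| is
taken. The area lives naturally in kPa (strain is dimensionless); the
mmHg figure is the same area divided by 0.1333224.

## Forward model (synthetic data)

The generator's constitutive laws and their default coefficients are the
empirical pressure relations of the measured system:

| quantity | law | defaults |
|---|---|---|
| thickness | T(P) = s(hour)·(a − b·Pᶜ) | a = 1085.5 µm, b = 57.3, c = 0.265 |
| radius | R(P) = r₀ − r₁·P (shared between phases) | r₀ = 8.448 mm, r₁ = 0.005 mm/mmHg |
| displacement | D(P) = Dmax·(1 − e^(−P/Pc)) | Pc = 12 mmHg; Dmax = 143/(e^(−2/12) − e^(−60/12)) ≈ 170.3 µm |
| swelling | s(h) = s∞ − (s∞ − 1)·e^(−rh), r fixed by s(1) | s(1) = 1.06; s∞ ≈ 1.1506 so s(4) = 1222.47/1081 |

Notes on the open choices:

* **Displacement.** The measurements show a saturating, below-20-mmHg-
  dominated rise of the apex; a saturating exponential with Pc = 12 mmHg
  reproduces that shape. Dmax defaults to the value that makes
  D(60) − D(2) exactly 143 µm, the measured maximum apex displacement.
* **Unloading.** No unloading constitutive law is measurable from the
  printed relations, so unloading evaluates thickness and displacement at
  an effective pressure P·(1 + λ); λ = 0 closes the loop exactly, larger
  λ opens it. Radius is shared between phases (the measured loading and
  unloading radii are statistically indistinguishable, p = 0.945).
* **Loop-area capacity.** The loop area grows with λ only up to λ ≈ 3.5
  (≈ 0.52 kPa with H₂ = 3 mm); beyond that the unloading strain range
  slides past the loading one and the enclosed overlap shrinks. The
  measured fresh-cornea loop (1.4 kPa ≈ 10.5 mmHg) cannot be enclosed by
  a quasi-static pressure lag in this geometry — the physical loop
  reflects viscoelastic stress relaxation that this kinematic generator
  deliberately does not model. The default λ ≈ 0.656 is fixed by the
  package's own bisection calibration to a 0.3 kPa loop;
  `calibrate_hysteresis` reaches any target up to the capacity bound and
  raises a calibration error (with the achieved range) beyond it.
* **Swelling.** Hydration is a multiplicative factor on the whole
  thickness law: 1 at hour 0, 1.06 at hour 1 (the measured ~6 % gain),
  saturating so that the hour-4 factor matches the ratio of the measured
  4-hour maximum (1222.47 µm) to the measured fresh zero-pressure
  thickness (1081 µm). `plateau_for_thickness` instead pins the
  generator's own hour-4 zero-pressure thickness to an exact target.
  The generator emulates swelling only — it has no hydration-stiffening
  law, so cross-hour modulus/hysteresis trends in simulation follow from
  geometry alone and are not meant to match measured hydration
  stiffening.
* **Replicate eyes** jitter (a, Dmax, swelling excess) multiplicatively
  with 3 % relative noise by default, emulating between-eye variability
  at the scale of the reported standard deviations.

### Rendering

Image formation is geometric, not wave-optical. The anterior surface is
a circular arc of radius R with its apex at depth `z_apex_ref − D`
(600 µm datum); the epithelium/stroma interface sits at optical depth
n·100 µm below it (a fixed, purely cosmetic band that segmentation must
tolerate but does not trace) and the posterior surface at optical depth
n·T, n = 1.389, so that refraction correction is genuinely exercised.
Interfaces are reflectivity steps (air 0.03, epithelium 0.60, stroma
0.35, aqueous 0.05 — free choices; no noise/reflectivity model is
published for the source system) blurred axially by a Gaussian PSF of
FWHM 3.5 µm, with multiplicative gamma speckle (unit mean, scale 0.3 by
default). Pixel defaults are 2.0 µm/px axial (in air) and 10 µm/px
lateral over a 1700 × 800 grid (8 mm field), so the PSF and the central
3 mm window are both well sampled. All randomness flows from one integer
seed; stacks spawn per-step seeds deterministically.

Because interfaces are rendered as PSF-blurred steps, the axial intensity
gradient peaks exactly at the interface; gradient-peak detection is
therefore unbiased, and the sub-pixel parabolic refinement brings the
noiseless round-trip error well under the 2.2 µm repeatability the
hardware achieves.

## Segmentation

Fully automated, column-wise: after Gaussian pre-smoothing (2 px axial,
2 px lateral — speckle is uncorrelated across A-lines while the surfaces
vary slowly), the anterior boundary is the first axial local maximum of
the gradient magnitude above median + 4·MAD of that column, and the
posterior boundary is the last. Traces are median-filtered over 11
columns (raw detections are kept at the trace edges, where replicate
padding would bias the median on the sloped arc), and columns whose
residual from a Savitzky–Golay local quadratic baseline exceeds 3 robust
standard deviations (1.4826·MAD, floored at a quarter pixel so noiseless
traces are not mass-flagged) are replaced by the baseline value and
flagged `interpolated`. Fewer than 50 % detected columns is an error, as
is a posterior trace above the anterior one.

Refraction correction divides the optical anterior-to-posterior gap by
n; lateral ray bending at the anterior surface is ignored (near-normal
incidence at the apex), which is an approximation valid for the central
window. Thickness is measured axially, not surface-normal: at the apex
the difference is second order.

The apex depth used for displacement is taken from the circle fit over
the central chord rather than the raw per-column minimum; pooling ~300
columns makes it robust to speckle at the sub-micrometre level.

## Fitting

The two nonlinear laws each have exactly one nonlinear parameter, so both
are solved by profiling: for fixed c (or Pc) the remaining parameters are
linear and solved in closed form, and the profiled RSS is minimised by
bounded deterministic scalar search (c ∈ (0.05, 1) to keep b and c
identifiable on 14-point schedules; Pc ∈ (0.01, 500) mmHg). There is no
random initialisation; noiseless model data is recovered to solver
tolerance. Degenerate inputs return flagged results (constant thickness
→ b = 0, exponent unidentifiable; zero displacement → Dmax = 0). The
measured displacement series is referenced to the 2 mmHg state, so the
pipeline fits the exponential with its pressure origin shifted to the
reference (dD vs P − 2), under which the shifted series is an exact
member of the same family.

## Statistics

Paired hour-vs-hour-0 comparisons across n = 8 replicate eyes use the
exact Wilcoxon signed-rank test: zero differences dropped, midranks for
ties, and the null distribution of the positive-rank sum enumerated over
all 2ⁿ sign assignments (n ≤ 20). The two-sided p-value is twice the
smaller tail, capped at 1; for n = 8 with a consistent shift it bottoms
out at 2/256 = 0.0078125.

## What passing tests do and do not show

The generator is anchored to the measured empirical relations, so
round-trip tests demonstrate that the segmentation + geometry + mechanics
chain recovers known ground truth through realistic image formation
(speckle, PSF blur, optical-path stretching) — they do not validate the
constitutive laws themselves against new tissue, and real corneas add
effects the phantom omits: regionally varying thickness, non-circular
anterior profiles, lateral refraction, scanner distortions, true
viscoelastic (rate-dependent) unloading, and hydration stiffening.

## Problem sizes and numerical choices

Default analysis runs use 27-step cycles of 1700 × 800 px scans; tests
and the reproduction script use the same image geometry with 14–27 scan
stacks and finish in well under a minute per stack. Calibrations
(`calibrate_to_modulus`, `calibrate_hysteresis`) are monotone bisection
with geometric bracket expansion, to 0.01 % relative for the modulus; the
modulus pipeline evaluates only the 2 and 15 mmHg states during
calibration, since E(15) depends on nothing else — full-cycle imaging
runs reproduce the calibrated value identically. Loop integration uses
512 grid points (doubling changes smooth-loop areas by < 0.1 %); on
piecewise-linear loops whose breakpoints lie on the grid the trapezoidal
area equals the exact shoelace polygon area to 1e−9 relative. Circle
fits are algebraic (Kåsa) least squares — exact on noiseless arcs,
adequate for 3 mm chords of ~8.4 mm circles at the noise levels used.
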