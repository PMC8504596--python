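# Methods

`imbect` implements the planning-and-verification chain for
intensity-modulated bolus electron conformal therapy (IM-BECT): conformal
bolus design, derivation of an intensity-reduction-factor (IRF) map,
segmentation of that map into a hexagonal pattern of tungsten island
blocks, pencil-beam dose computation in the presence of the modulator, and
planar dose-difference / distance-to-agreement (DTA) quality assurance.
This note records the models, the parameters that matter, and the choices
made where the design was genuinely open.

## Geometry

All geometry lives in the beam-eye coordinate system: the virtual electron
point source at `z = 0`, beam along +z, isocenter at `z = 100` cm, the
collimating insert (which carries the modulator) at `z = 93.5` cm.  Points
project between planes by similar triangles, `x(z) = x(z0)·z/z0`.  The
planning lattice is a grid of *fan lines* — rays through regularly spaced
points of the isocenter plane (default spacing 0.2 cm) — each carrying a
pencil weight: 1 inside the aperture, 0 outside, multiplied by the IRF
after intensity modulation.

## Beam model

A beam is summarised by `R100 = 0.6·R90`, `R90`, `Rp = 0.5·E` (cm, E in
MeV) and an analytic percent-depth-dose: parabolic buildup from the surface
dose (default 85%) to 100% at `R100`, a monotone cosine-power falloff
pinned exactly through `(R90, 90%)`, and a constant bremsstrahlung tail
(default 3% of given dose) beyond `Rp`.  The curve is the central-axis dose
of the reference field at the nominal SSD, so central-axis divergence is
already inside it.  The study beam is 16 MeV with `R90 = 5.0` cm.

When the passive modulator (a 1.27 cm machinable-foam insert, ρ = 0.096
g/cm³, holding the pins) is in the beam, two rigid corrections apply: the
depth-dose shifts 0.1 cm shallower (foam energy loss) and the initial
angular spread σθ increases by 50% (foam scatter).  The corrections
compose: applying them twice models two foam slabs.

**Initial angular spread.** The unmodulated σθ of a specific accelerator is
commissioning data the package cannot know; the default is **0.03 rad**,
giving an in-air penumbra σ of ≈0.2 cm at 100 cm SSD — typical of a
collimated clinical electron beam.  Override it in the beam config block
when commissioning data exist.

## Fluence transport and the island-block model

Pencils spread in air by a Gaussian of width `σθ·(z − 93.5)`.  Under the
perfect-collimation assumption every electron incident on a pin's top face
is removed, and nothing scatters in from the pin sides; each circular pin
of diameter `d` is therefore modelled as a *negative* square pencil of
equal area (side `d·√π/2`) transported to the surface with the
modulator-corrected spread (1.5×σθ) and subtracted from the open-field
fluence.  Squares are rasterised with exact fractional pixel coverage, so
the integrated deficit equals the projected block area regardless of pixel
size; sums of overlapping shadows are clamped at zero.  The x-ray
background is *not* attenuated by the pins.

On a hexagonal lattice of pitch `r` the far-field IRF of a uniform pattern
is the unblocked cell fraction,

    IRF(d) = 1 − π d² / (2√3 r²),    d(IRF) = r·√((2√3/π)(1 − IRF)),

the closed forms used for segmentation.  The manufactured catalog (eight
diameters, 0.158–0.473 cm at r = 0.6 cm) is carried as data together with
the vendor-quoted IRF percentages for validation.

## Dose engine

Dose is the sum of an electron component and an x-ray background.  The
electron component is a single-pass pencil-beam calculation: per z-slice,
each surface-fluence column contributes `φ·(PDD(d_eff) − DX(d_eff))`
spread laterally by a Gaussian whose width is that *column's* accumulated
multiple-Coulomb-scattering σ at its radiological depth `d_eff` (density
line integral plus bolus water-equivalent thickness).  Because each column
scatters with its own σ, lateral gradients of bolus thickness redistribute
fluence — thick regions spray electrons into thin ones — reproducing the
hot/cold-spot phenomenology that motivates intensity modulation.  The
x-ray background ramps linearly from zero at the surface to the tail level
at `Rp` and follows the open-field (block-free) fluence.

The Fermi–Eyges accumulation is `σ²(d) = k·∫₀^d (d−t)²/E(t)² dt` with
`E(t) = E0(1 − t/Rp)`.  The constant `k` is calibrated so that
`σ(R90/2) = 0.45 cm` by default — representative of measured r.m.s. pencil
spreads for a 16 MeV beam (≈1.4 cm by `R90`) — and the calibration value is
exposed as a beam parameter (`sigma_mcs_half_r90`).

**Normalisation.** Doses are percent of *given dose*: the central-axis
maximum in water for the effective field (the minimum-area rectangle
circumscribing the aperture).  Since the tabulated PDD already contains
the lateral-equilibrium loss of the reference field, each slice is
renormalised by the analytic equilibrium factor of the effective field
(`erf(w/2√2σ)·erf(h/2√2σ)`), so an open field in water reproduces the PDD
on axis exactly.  Output-factor variation beyond this equilibrium factor is
not modelled.

**Numerical choices.** Spatially varying σ is handled by splitting each
source pixel linearly between two bracketing σ levels (8 intervals per
slice) and blurring each level once — exact for uniform σ, second-order
accurate otherwise.  Radiological depth inside the grid uses vertical
columns (small-angle approximation); the standalone `effective_depth`
operation integrates along the true diverging ray.  Dose grids default to
0.2 cm; planar QA grids to 0.1 cm pixels.

## Bolus design operators

The bolus (machinable wax, relative electron density 0.92 by default —
configurable; thickness converts to water-equivalent by multiplying by the
density) is designed by an operator sequence:

* **Create(percent, margin)** — per fan line inside the PTV projection
  eroded laterally by the margin: `t = (R_percent − WED_distal)/ρ_bolus`,
  floored at 0.  "Physical depth" is interpreted as water-equivalent depth
  converted to bolus material by the density ratio.
* **Isodose Shift(margin)** — after a dose calculation,
  `t += (z90 − z_distalPTV)/ρ_bolus` per eligible line, using the deepest
  downstream 90% crossing; lines with no crossing are left unchanged and
  counted.
* **Smooth(exp_mult, radius_mult)** — normalised radial kernel
  `exp(−exp_mult·(ρ/R)²)` truncated at `ρ = R`, `R = radius_mult·1.5 cm`,
  renormalised at footprint edges (a uniform bolus is a fixed point).
* **Specified Shift(δ)** — uniform thickness change, floored at 0.
* **Truncate** — zeroes the bolus outside the projected aperture plus a
  1.0 cm retention margin; the margin is chosen so in-field dose changes
  by <0.5% (the removed region carries essentially no fluence).
* **Height Extension** — ineligible fan lines inherit the nearest eligible
  line's value (Euclidean distance in the isocenter plane).

Sequences are driven from config using this vocabulary; dose is recomputed
whenever an operator needs it and once at the end.

## Intensity modulation

For each fan line whose ray stays ≥0.5 cm (configurable) inside the PTV
edge, the maximum dose along the ray inside the PTV maps to an IRF:
1 below 100%; `100/Dmax` between 100% and 125%; 0.8 above.  The upper
threshold is the reciprocal of the minimum IRF (0.8⁻¹ = 125%), the unique
value making the ratio meet the clamp continuously; min/max IRF limits are
user-configurable with 0.8/1.0 as study defaults.  Lines outside the
margin inherit the nearest eligible IRF (the height-extension rule).  The
map multiplies the pencil weights; the sequence may then reoptimise the
bolus (isodose shift + smooth + specified shift).

## Segmentation

Pins sit on a pointy-row hexagonal lattice (rows parallel to x, pitch
0.6 cm, row offset r/2, row pitch r·√3/2, on-axis site included) covering
the aperture projection at 93.5 cm.  The initial pattern samples the
objective IRF at each site (projected to the isocenter plane), computes
the continuous diameter and snaps to the nearest catalog entry; a pin is
omitted when the continuous diameter is closer to 0 than to the smallest
catalog pin (d < 0.079 cm), and ties break toward the smaller pin.

The refinement loop compares the fluence the pattern achieves at the
clinical-QA reference plane (2.0 cm depth in water at 100 cm SSD; each
pin's smoothed deficit is an analytic product of error functions, so
updates are incremental) against the objective at each site, in row-major
order; sites off by more than the tolerance (default 0.03) step one
catalog position in the correcting direction, adding or removing pins at
the ends of the ladder.  The loop stops when a sweep changes nothing,
everything is within tolerance, a pattern state repeats (the best pattern
by maximum absolute error is returned), or the iteration cap is reached.
For objectives between catalog steps this dithers neighbouring diameters
so the local mean matches the objective.

## Quality assurance and plan metrics

Planar comparison uses the calculated grid as reference.  The dose
difference is measured minus calculated (bilinear resampling if grids
differ); DTA is the distance to the nearest location where the bilinearly
interpolated calculated distribution (4× upsampled, subpixel) equals the
measured value, capped at 1.0 cm.  A point passes at `|Δ| ≤ 3%` *or*
`DTA ≤ 0.3 cm`; only points with calculated dose ≥10% are evaluated.  The
threshold is percent-of-maximum by default, switchable to
percent-of-given-dose (the two readings of the inclusion rule).  Reports
include a dose-difference histogram with the <80% subset flagged
separately.  A combined gamma index is available as an optional mode.

Plans are scored on the PTV DVH: `D_90-10 = D10 − D90` (the span covering
the central 80% of volume) and the maximum dose; two plans are compared
after scaling one so the PTV V95 values match (bisection, 0.1 pp where the
discrete voxel distribution allows).

## Synthetic fixtures and what they show

The water tank reproduces the clinical-QA geometry.  The *wavy slab* is a
flat-entrance water phantom whose PTV distal surface is sinusoidal
(default amplitude 0.5 cm, period 8 cm, mean depth 3 cm, half-width 3 cm
inside a 10×10 cm field).  The defaults were chosen once so that the
conformal bolus the sequence designs produces a mild PTV hot spot
(≈105%) and an IRF band of ≈0.95–1.00 — the regime reported for
chest-wall-class cases — while remaining conformable by the single-pass
engine.  Shorter surface periods (≲4 cm) are *not* conformable here: the
engine deposits each column's full accumulated spread in one pass, so
bolus structure finer than the scatter length blurs away.  (A
redefinition-style algorithm would do better; that is exactly the
limitation the single-pass choice accepts.)  Passing tests therefore
demonstrate the chain's internal consistency on smooth geometries, not
performance on steep real anatomies, CT heterogeneity, or oblique
incidence.

## Known limitations

* Single-pass pencil beam: no phase-space redefinition, no pin-side
  scatter or bremsstrahlung perturbation (perfect collimation), no skin or
  internal collimation.
* Output factors beyond the effective-field equilibrium renormalisation
  are not modelled; the x-ray background is a declared ramped-tail
  stand-in, not an empirical model.
* Column bookkeeping inside dose grids is vertical (small-angle); only
  `effective_depth` traces true diverging rays.
* Axis-aligned rectangular fields are a degenerate alignment for the
  hexagonal lattice: the site count deviates from the packing-density
  estimate `area/((√3/2)r²)` by a few percent there, while generically
  oriented fields agree within 2%.
* The pin hole depth exceeding the pin length (recessed pins) is
  irrelevant under perfect collimation and is not modelled.
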