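# Methods

`hamdose` models a high-dose-rate intraoperative radiotherapy (HDR-IORT)
treatment delivered with a Harrison–Anderson–Mick (HAM) applicator: a flexible
silicone flap with embedded parallel catheters through which an Ir-192 source
is stepped. Treatment plans are optimized on an idealized template — flat
applicator, infinite water, TG-43 dose formalism — while real treatments
involve non-water applicator materials, little or no backscatter material
above the applicator, and an applicator bent onto the target surface. The
package quantifies, in relative dose, how much each of those departures
perturbs the delivered dose.

## Coordinates and units

All lengths are cm, energies keV, densities g/cm³. `x` is lateral (across
catheters), `z` longitudinal (along catheters), `y` depth, positive toward
the patient. The source plane (the plane of the dwell positions) is `y = 0`;
the patient-side flap surface is `y = +0.5` and the upstream surface
`y = -0.3` for the default 0.8-cm flap. The prescription region is the
1 cm × 1 cm column of voxels at 1.0 cm depth about the central axis; its mean
dose defines 100%.

## The treatment template (synthetic-input generator)

`ApplicatorSpec` defaults describe the 6-catheter, 8-cm applicator: catheter
spacing 1.0 cm, dwell step 0.5 cm, giving 17 dwells in each of 6 catheters
(102 total), flap 0.8 cm thick with the source plane 0.5 cm from the
patient-side surface. Catheter radii are not standardized in the open
literature; defaults are 1.0 mm outer radius (HDPE wall) with a 0.7-mm air
lumen, sized to pass the 0.89-mm-diameter source capsule, and both are
configurable. The flap extends 0.5 cm beyond the dwell array on each side.

Dwell times are optimized for uniform relative dose at prescription points
placed 1.0 cm below each dwell. The solver is nonnegative least squares on
the quadratic uniform-dose objective, then averaged over the template's two
mirror symmetries (the objective is convex and mirror-invariant, so the
average of optimal images is optimal; this pins the symmetry of the times to
machine precision). A seeded simulated-annealing polish is available behind a
flag for parity with annealing-based clinical optimizers; the default is the
deterministic path. Relative dose maps are invariant under a common rescaling
of dwell times (histories are allocated proportionally), so times are
reported with the longest dwell at 1 and the prescription normalization is
carried by a single reference constant computed after optimization.

## Monte Carlo engine

Photon-only transport with Woodcock (delta) tracking against a global
majorant cross-section; materials are resolved analytically at tentative
collision points (flap slab, catheter tubes and lumens, phantom boundary,
bent-surface projection). Interactions:

- **Compton** scattering on free electrons with exact Klein–Nishina sampling
  (rejection on the scatter fraction `x = E'/E`); the incoherent coefficient
  is the analytic Klein–Nishina cross-section times the medium's electron
  density.
- **Photoelectric absorption** is the residual of the tabulated total mass
  attenuation coefficient after subtracting the Klein–Nishina part. Because
  the shipped tables include coherent scattering, that residual also absorbs
  the small coherent component when the Rayleigh channel is off — a
  deliberate, conservative approximation of order the coherent fraction
  (≲1% of interactions above 150 keV).
- **Rayleigh** (optional, default off): a shipped water coherent-fraction
  curve applied to all low-Z media, with form-factor-free Thomson angular
  sampling. A documented, crude channel; switching it on moves the
  prescription dose by well under 1%.

No electrons are transported: dose to water is scored as collisional KERMA
with a track-length estimator. Every traversal of length `l` through a scored
voxel at energy `E` and weight `w` contributes
`w · E · l · (μ_en/ρ)_water(E) / V_voxel`, dose-to-water convention regardless
of the local medium. Histories terminate below 10 keV (the table floor; the
spectrum carries no lines below 60 keV) or on leaving the 100-cm world cube.
Scoring on flat grids uses exact voxel traversal (Amanatides–Woo); polar
characterization scoring splits each flight at every radial shell crossing
(the radius along a segment is quadratic in the path parameter), making the
radial assignment exact; deformed-grid scoring sub-steps each flight inside
the mapped region and projects substep midpoints onto the bent surface.

**Source model.** The microSelectron-v3-like source is a configurable
simplification: a 3.5-mm × 0.65-mm-diameter iridium cylinder in a steel
capsule (0.85 mm outer diameter, 5 mm long) with a 0.7-mm steel drive cable.
Decay photons start uniformly in the active cylinder with isotropic
directions and energies from the shipped Ir-192 line table (gammas and K
x-rays above 60 keV, ~2.2 photons per decay; betas are irrelevant to the
KERMA estimator). Capsule and cable act through *first-flight attenuation*:
at emission, analytic ray chords through the core, shell, and
polyline-of-cylinders cable multiply the history weight by `exp(-Σ μᵢ lᵢ)`,
and metal is excluded from the transport geometry. Photons scattered inside
the metal are thereby neglected (small solid angle), and the metal no longer
inflates the Woodcock majorant. Because the TG-43 dataset is characterized
with the same treatment, the approximation is self-consistent across every
comparison the package reports. For longitudinally bent applicators the cable
follows the (extended) bent catheter proximal to the active dwell, which is
how a curved cable comes to intercept the radiation field.

**Randomness and uncertainty.** A counter-based splitmix64 stream is seeded
per history, so runs are bit-reproducible and paired runs (water vs
materials, infinite vs semi-infinite) share identical decay samples: paired
differences are common-random-number estimates with collapsed variance.
Histories are split into batches (default 50) and all standard errors derive
from the spread of batch means.

**Cross-section data.** Per-element mass attenuation tables (total, with
coherent) and the water mass energy-absorption table are shipped as CSV,
transcribed from the standard NIST compilations on a 10–1500 keV grid and
combined by the elemental mixture rule; media are water, dry air, silicone
(C₂H₆OSi, 1.09 g/cm³), HDPE (C₂H₄, 0.97 g/cm³), steel (approximated as iron,
8.0 g/cm³) and iridium (22.42 g/cm³). The iridium column is synthesized by
photoelectric Z^4.5 scaling from lead with the K-edge relocated to 76.1 keV
plus the Klein–Nishina part; it only drives source self-attenuation, which
cancels between characterization and the study runs.

## TG-43 engine

A single centered source in the water cube is scored on a polar grid
(28 geometric radial shells, 0.2–12.5 cm; polar nodes every 5°). Radial nodes
sit at the 1/r²-weighted effective radius of each shell, removing finite-bin
bias against the point evaluations of the analytic engine. The radial dose
function `g_L(r)` and anisotropy function `F(r, θ)` follow from the
line-source geometry factor `G_L(r, θ) = β/(L·r·sin θ)` (axial limit handled
analytically); relative dose is `G_L/G_L(r₀, 90°) · g_L · F`, unity at
(1 cm, 90°). Interpolation is log-linear in `r` for `g_L` and bilinear in
(log r, θ) for `F`; beyond-table radii clamp to the nearest node with a
logged warning. The radial table extends to 12.5 cm so the far corners of the
±7-cm longitudinal plane interpolate rather than extrapolate. The
characterization also records the MC dose per history at the reference point,
which converts MC maps into TG-43 units so every study is normalized by the
same TG-43 prescription dose. TG-43 maps are evaluated as 4³-subsample voxel
averages to be comparable with the MC voxel-mean estimator.

## Bending model

Curvature follows the parabola `depth = -a·u²` (bending away from the
patient) with `a ∈ {0.09, 0.25, 0.54}` /cm, the range reported for clinical
conformation; the radius of curvature of the osculating circle at the apex is
`R = 1/(2a)`, i.e. 5.56, 2.0 and 0.93 cm respectively (the conformation
literature quotes approximately 5.4, 2.8 and 0.9 cm; the package follows the
osculating-circle definition and records the discrepancy rather than
reconciling it). Embedded lengths are treated as inextensible at the
mid-source-plane: flat in-plane coordinates become arc lengths along the bent
surface, inverted with a closed-form arc-length function and Newton
iteration. For longitudinal bending the source axis becomes the local
tangent; for lateral bending axes stay longitudinal. Nearest-point projection
onto the parabola (needed for material lookup and deformed scoring) solves
the stationarity cubic in closed form and picks the nearest root inside the
caustic.

The scoring grid is deformed with the applicator: flat-frame voxel
`(u, v, d)` maps to `P(u) + d·n̂(u)` with the transverse coordinate
unchanged, so bent-applicator maps are voxel-by-voxel comparable with flat
maps, mimicking a target that conforms to the applicator surface. Scored
contributions carry the local volume Jacobian `1 + d·κ(u)`. Fold-over voxels
(`1 + d·κ ≤ 0`, possible only upstream beyond the radius of curvature) are
excluded and counted. The semi-infinite boundary for bent applicators is
air wherever the signed normal distance to the *extended* bent surface is
below −0.3 cm; this fills the external gap between the upturned wings and
everything above it, and also turns the region upstream of the extended
parabola beyond the flap edge into air — far from the scored region.

## Study design and normalization

All studies reuse one characterized dataset, one flat-optimized plan
(never re-optimized — matching uncorrected clinical practice), and one
reference normalization: the TG-43 mean dose over the prescription column.
The validation study compares the water-only MC map against the TG-43 map on
the two central planes (each normalized to its own prescription mean, as the
underlying treatment-planning comparison does); the material/backscatter
study runs the 2×2 grid {all-water, full materials} × {infinite,
semi-infinite} as common-random-number pairs; the bending study runs
a × orientation × phantom with full materials on the deformed prescription
grid, reporting dose loss = 100% − prescription dose.

## Problem sizes

Desk-scale defaults, chosen as the package's working point: 1.5×10⁷ histories
for characterization (node standard errors ≲0.2% in the treatment region),
2×10⁷ for the validation planes and for each flat prescription-region run
(prescription-mean standard error ≈0.2%), and 6×10⁶ per bent configuration
(≈0.45%). The full-fidelity budget of the underlying treatment studies
(9.0018×10⁸ histories, 0.1-cm full-plane grids) is available through
configuration and reproduces the figure-grade maps, at hours of single-CPU
run time.

A caution on the validation statistic: the maximum relative deviation over
all plane voxels above a 5%-of-reference dose floor is an extreme-value
statistic. At desk-scale budgets the per-voxel standard error ranges from
≈1.8% (prescription level) to ≈3.3% (voxels at the floor) on 0.2-cm grids, so
the observed maximum is dominated by MC noise — about 3–3.5 times the local
standard error, i.e. 6–9% — rather than by real model disagreement. The
deterministic residual between the engines (interpolation plus superposition
error) is bounded instead by the agreement in well-resolved regions and by
construction of the dataset; driving the noise term itself below ~1.5%
requires on the order of 10⁹ histories, which is the full-fidelity regime.
The reported comparison therefore carries its standard error at the argmax,
and both the floored and unfloored maxima are recorded.

## What the generator emulates, and what it does not

The synthetic inputs reproduce the published treatment's structure: the
applicator geometry, the dwell lattice, uniform-dose optimization, the
phantom dichotomy, and the parabolic curvature family with its clinical
parameter range. They do not emulate: measured (CT-derived) target surfaces;
inter-applicator manufacturing variation beyond configurable densities;
partial backscatter (wet packing) between the two phantom extremes; or the
proprietary internals of the clinical optimizer and the exact capsule
drawing. Passing tests therefore demonstrate internal consistency of the
pipeline and fidelity of the implemented physics at the stated budgets — not
agreement with any individual patient geometry.

## Known limitations

- Free-electron Compton (no binding/Doppler), coherent scattering folded
  into absorption by default, and transcribed (not machine-read) attenuation
  tables put a ~1% scale of systematic uncertainty on scatter-sensitive
  quantities; the backscatter deficit is the most exposed (its scatter
  component is the quantity itself).
- First-flight metal treatment neglects capsule/cable scatter
  (self-consistent across all comparisons, but a real difference from a full
  metal-transport model).
- KERMA equals dose only under charged-particle equilibrium; within ~1 mm of
  the air lumens and the semi-infinite boundary this is an approximation, as
  it is in the track-length formulation generally.
- The steel composition is pure iron; the iridium attenuation column is
  synthesized (see above).
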