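# Methods

## The phantom model

The ArcCHECK-MR is modeled as five concentric, prismatic density layers on a
blank ("pseudo") CT stack, mirroring how a TPS applies bulk
relative-electron-density (RED) overrides to contoured structures:

| structure | outer radius (mm) | RED   | physical content                    |
|-----------|-------------------|-------|-------------------------------------|
| Outer     | 133.0             | 1.130 | outer PMMA shell                    |
| Complex   | 110.0             | 1.200 | PCBs + low-density wrap (tunable)   |
| Detectors | 103.4             | 1.000 | diode band, treated water-equivalent|
| Inner     | 100.0             | 1.130 | inner PMMA shell                    |
| Insert    | 75.0              | 1.130 | PMMA cavity/multi-plug insert       |

plus six QA-platform objects at RED 1.350 and background 0.  The pseudo-CT is
121 slices of 512 × 512 pixels, 0.97658 mm pixels and 2 mm slices, all pixels
zero; the in-plane corner at −(512−1)/2 × 0.97658 = −249.51619 mm centers the
isocenter in the volume, and slices span −120…+120 mm so the axial center is
also the isocenter (the slice-position tag of the central slice is 0).  Rings
span the full slice stack (configurable); densities come from the ordered
structure → RED table where later (inner) entries win, and a voxel center on
a shared boundary belongs to the inner structure.  Ring voxelization uses the
exact disk r ≤ radius (sign-symmetric in floating point); platform polygons
use point-in-polygon tests at voxel centers.  No partial-volume weighting is
applied — results are grid-deterministic, as with TPS bulk overrides.

## Detector helix and chart conventions

21 turns of 66 diodes at exact 360/66° angular spacing on radius 104 mm,
offset half a spacing from the anterior/posterior poles; within a turn the
axial coordinate advances linearly by the 10 mm pitch per revolution, and the
21 turns stack from −105 to +105 mm.  The unfolded chart uses the vendor's
nominal 10 mm circumferential spacing: arc = ±5 … ±325 mm (positive toward
machine left), axial = the turn's nominal plane (multiples of 10 mm).  The
~3.45 mm closure mismatch between nominal and true circumference is absorbed
at the posterior seam.  The within-turn stacking direction is chosen so the
four diodes physically nearest the posterior beam-exit axis carry the chart
coordinates (325, 10), (325, 0), (−325, 0), (−325, −10); the opposite
handedness would mirror the axial signs.  Handedness and stacking direction
are configuration (`DetectorArraySpec`), since the vendor does not publish
them.

## Dose sampling and comparison

Dose grids are sampled trilinearly (grids are ~2 mm, diode geometry sub-mm).
Plug doses use a sphere mean of radius 2.5 mm over a fixed 256-point
quasi-uniform ball; the point set is antipodally symmetric, so any linear
dose field averages exactly to its central value, and no RNG is involved.

Gamma analysis searches the evaluated (calculated) map around each reference
(measured-like) point on a lattice of step DTA/10 within radius 3 × DTA,
interpolating linearly; gamma values are capped at 3.  DTA analysis passes a
point when its own-location dose difference is within tolerance or the
interpolated evaluated values within DTA bracket the reference dose.  The
low-dose threshold is applied to reference doses relative to the global
normalization dose (the maximum reference dose unless supplied) in both local
and global modes; the vendor's exact threshold semantics are not public, so
this is configurable.  These choices make local per-point gamma ≥ global
gamma whenever the reference dose does not exceed the normalization dose,
hence local pass rates ≤ global pass rates.

## The synthetic engine

The bundled engine is a transparent stand-in for the commercial Monte Carlo
TPS, not a transport calculation:

    D(p) = MU · output · (SAD/|p−s|)² · B(d_eff(p)) · F(p′)

- `d_eff` integrates RED along the source→point segment by midpoint marching
  at a fixed step (default 0.5 mm, clamped to half the smallest voxel
  dimension so no layer can be skipped; ≤0.2 % depth error on 300 mm paths).
- `B` is a linear build-up ramp from the surface fraction (default 0.3) to 1
  at `buildup_depth` (default 15 mm), then exp(−μ_w · (d − d_b)).  The
  nonzero surface term makes a zero-density volume degenerate exactly to
  inverse square.
- `F` is the divergent rectangular aperture (FX × FY at the isocenter plane,
  maximum 57.4 × 22.0 cm²), optionally evaluated at a point shifted by
  `lateral_shift` along the crossline direction — a single-scalar mimic of
  the magnetic crossline shift, default 0.  It is not an electron-transport
  model.
- `μ_w = 3.620e-3` per mm water-equivalent is a calibration constant, solved
  once from EEDR = G · exp(−μ_w · (d_exit − d_entrance)) with the traced
  depths of the default 5-layer phantom (33.3 and 267.1 we-mm) and the
  geometric factor G = 0.7482, so the default phantom's EEDR lands near the
  experimentally observed 0.3207.  It is not a claim about the 7 FFF
  spectrum.
- Machine geometry: SAD 1435 mm; the isocentric setup puts the source 1302 mm
  from the 133 mm outer surface at gantry 0.  Gantry angles are reported in
  [0°, 360°) with 0° = beam from anterior; the attenuation series runs from
  180° in the measurement order, normalized to the gantry-0 output.

### EEDR sensitivity and tuning

EEDR(RED_Complex) is strictly decreasing: raising the Complex RED only adds
water-equivalent depth between the entrance and exit sampling diodes.  In
this engine the sensitivity is weak (~2e-3 EEDR per unit RED): both sampling
diodes sit at radius 104 mm *inside* the Complex shell (103.4–110 mm), so
most of the front-shell crossing cancels between the entrance and exit paths,
leaving only the ~1 mm path-length asymmetry.  The much larger sensitivity
seen on real hardware comes from magnetic-field and scatter physics outside
this engine's scope.  Tuning still converges sharply because the engine is
deterministic and the curve strictly monotone: `tune_red` verifies
monotonicity at the RED bounds, rejects targets outside the attainable EEDR
interval (reporting it), bisects until the EEDR tolerance or a 0.001 RED
bracket is reached, and returns the RED rounded to 0.001.

### A geometric subtlety of the inverse-square limit

With attenuation off, the exit/entrance ratio of on-axis points at ∓104 mm is
exactly ((1435−104)/(1435+104))² = (1331/1539)² ≈ 0.74796.  The physical
sampling diodes sit half an angular spacing (2.727°) off the poles, at
|y| = 103.88 mm and |x| = 4.95 mm, so the diode-sampled zero-attenuation EEDR
is slightly larger, ≈ 0.74824.  Both values are pinned by tests.

## Problem sizes used in tests

The test and acceptance computations run the engine on coarse grids chosen
for the quantity at hand: a 2 mm slab grid over the phantom cross-section and
|z| ≤ 20 mm for EEDR/tuning work (the six sampling diodes all lie within
|z| ≤ 5.1 mm), a 4 mm wide-field slab for the platform attenuation series,
and analytic or down-scaled grids elsewhere.  These sizes were chosen as the
coarsest that keep rasterization/interpolation effects comfortably below the
asserted tolerances; the full 512 × 512 × 121 build is exercised where it is
cheap (blank CT, structure generation, probe-level voxelization).

## What the synthetic data does and does not show

The generator family here (analytic RED volumes, the ray-trace engine,
synthetic dose profiles) exercises the *geometry, bookkeeping and analysis
machinery*: chart unfolding, EEDR arithmetic, calibration extraction, DICOM
round trips, gamma/DTA behaviour, tuning convergence.  Passing tests do not
demonstrate agreement with measured MR-linac dose distributions: the engine
has no electron return effect, no beam spectrum, no detector angular
response, and the platform outlines are a synthetic fixture (three rectangles
per side, placed to reproduce the reported attenuation sectors around
110–135° and 225–250°).  Published measured passing-rate tables are therefore
out of scope and not asserted anywhere.

## Known limitations

- Structures are prismatic (one cross-section per structure); real platform
  hardware varies along z.
- The vendor's proprietary corrections (angular dependence, field-size and
  energy corrections, out-of-beam corrections) are not modeled; measured-like
  data enters only through the same CSV/chart schema as calculated data.
- RT Plan objects, DICOM networking and private tags are out of scope.
- `eedr_relative_difference` returns the plain arithmetic value
  100 · (calc − meas)/meas; e.g. EEDRs of 0.3229 vs 0.3207 give 0.69 %, even
  where rounded figures near 1 % circulate for that comparison.
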