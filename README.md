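# arccheck-qa

A toolkit for building and exercising a **virtual ArcCHECK-MR phantom** for
patient-specific QA on a 1.5 T MR-linac.

The ArcCHECK-MR is a cylindrical diode-array phantom: 1386 SunPoint diodes on
a 104 mm-radius helix (21 turns of 66 diodes, 22 PCBs × 3 per turn), read out
on an "unfolded" 2D chart of circumferential (arc) and axial coordinates.  In
a 1.5 T transverse magnetic field the electron return effect makes the
device's internal density layout matter: treating it as one homogeneous
cylinder mispredicts the exit dose.  This package models the phantom as five
concentric density layers plus the QA-platform support objects and provides
everything needed to build, serialize, and analyze that model:

- **geometry** — the exact detector helix, its unfolded chart coordinates,
  the five ring structures (radii 133.0 / 110.0 / 103.4 / 100.0 / 75.0 mm),
  the 25-point MultiPlug grid, and the 174-angle gantry measurement series;
- **phantom_builder** — the 121-slice blank pseudo-CT (512×512 pixels at
  0.97658 mm, 2 mm slices, corner at −249.51619 mm), ring/platform contours,
  and voxelized relative-electron-density (RED) volumes
  (5-layer REDs 1.130 / 1.200 / 1.000 / 1.130 / 1.130, platform 1.350);
- **dicom_io** — standard DICOM CT series, RT Structure Set and RT Dose
  reading/writing in one consistent patient frame;
- **dose_sampling** — trilinear diode/plug sampling (optionally a 0.25 cm
  sphere mean), chart unfolding, normalization modes and the calibration-dose
  extraction;
- **qa_metrics** — the exit/entrance dose ratio (EEDR), MU rescaling, and
  local/global DTA and gamma-index analysis with a low-dose threshold;
- **synth_engine** — a deterministic ray-trace dose engine (inverse square ×
  radiological-depth attenuation × divergent field aperture) standing in for
  the commercial TPS, plus the iterative RED tuning loop.

## The core calibration metric

For a gantry-0° beam the EEDR is

```
EEDR = mean dose of the 4 exit-side diodes / mean dose of the 2 entrance-side diodes
```

where, on the vendor chart, the entrance diodes sit at (−5, 0) and (5, 0) and
the exit diodes at (325, 10), (325, 0), (−325, 0), (−325, −10) — the diodes
nearest the beam axis on either side (none sits exactly on it, because of the
helical winding).  Matching the calculated EEDR to the measured one by tuning
the RED of the "Complex" (PCB) layer, with the PMMA layers pinned at 1.130,
is what makes the 5-layer phantom transferable between units.  A point's
gamma index against criteria (ΔD %, DTA mm) is
`min over p of sqrt((|p − p_i|/DTA)² + ((E(p) − D_i)/ΔD_tol)²)`, with ΔD_tol
taken from the global normalization dose or the point's own dose
(local mode); a point passes at gamma ≤ 1.

## Worked example

```python
import arccheck_qa as aq
from arccheck_qa.grids import Grid3D

grid = Grid3D.centered((280.0, 280.0, 40.0), (2.0, 2.0, 2.0))
rings = aq.default_rings()
structures = aq.build_structures(rings, grid=grid)
table = aq.default_red_table(rings)
array = aq.build_detector_array()
beam = aq.BeamSpec()            # 10 x 10 cm^2, gantry 0, 200 MU
config = aq.EngineConfig()

volume = aq.voxelize_red(structures, table, grid)
doses = aq.detector_doses(volume, beam, config, array)
result = aq.compute_eedr(doses, array)
print(f"5-layer EEDR:       {result.eedr:.4f}")
print(f"entrance mean (Gy): {result.entrance_mean:.4f}")
print(f"exit mean (Gy):     {result.exit_mean:.4f}")
print(f"calibration dose:   {aq.calibration_dose(doses, array):.4f} Gy")

def factory(red):
    return aq.voxelize_red(structures, table.with_override("Complex", red), grid)

# a 'measured-like' unit whose PCB band behaves like RED 1.170
measured_eedr = aq.compute_eedr(
    aq.detector_doses(factory(1.170), beam, config, array), array).eedr
print(f"measured-like EEDR: {measured_eedr:.4f}")

spec = aq.TuneSpec(layer="Complex", bounds=(1.130, 1.250),
                   target_eedr=measured_eedr, tol=1e-6)
tuned = aq.tune_red(factory, beam, config, spec, array)
print(f"tuned Complex RED:  {tuned.red:.3f}  ({tuned.n_evaluations} engine runs)")
```

prints

```
5-layer EEDR:       0.3209
entrance mean (Gy): 2.1756
exit mean (Gy):     0.6981
calibration dose:   2.1756 Gy
measured-like EEDR: 0.3210
tuned Complex RED:  1.170  (9 engine runs)
```

The default engine attenuation is calibrated so the 5-layer phantom's EEDR
lands near the experimentally observed 0.32; the calibration dose is the mean
dose of the two entrance diodes for the reference 10 × 10 cm², 200 MU beam;
and the tuning loop recovers the RED that generated a target EEDR by
bisection on the monotone EEDR(RED) curve.

A command-line interface mirrors the library:

```
arccheck geometry --dump            # detector table (index, angles, chart, xyz)
arccheck build-phantom --mode 5layer --out phantom/
arccheck simulate --gantry 0 --field 10x10 --mu 200 --out dose.dcm
arccheck sample-dose --dose dose.dcm --out detectors.csv
arccheck gamma --ref measured.csv --eval calc.csv --dose-tol 2 --dta 2 --th 10 --mode local
arccheck tune-red --target-eedr 0.3207 --bounds 1.130:1.250
arccheck gantry-series --step 2 --exclude 8:18
```

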