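# aneufem

Wall-stress and rupture-risk evaluation for fusiform abdominal aortic
aneurysms, built as a fully synthetic, reproducible pipeline:

1. **synthetic_anatomy** — parametric aneurysm geometries (Gaussian
   radial bulge on a tube of revolution), triangulated lumen surfaces,
   and noisy voxel phantoms standing in for contrast CT volumes.
2. **reconstruct** — threshold segmentation, largest-component cleanup,
   marching-cubes surface extraction and Taubin (shrink-compensated)
   smoothing. Optional: synthetic runs can feed generated surfaces to
   the mesher directly.
3. **wall_mesher** — extrudes the lumen surface outward along vertex
   normals into a conforming tetrahedral wall mesh (prisms split with
   an index-ordered diagonal rule) with tagged inlet/outlet node sets
   and lumen faces.
4. **fem_solver** — linear isotropic elastostatics on constant-strain
   tets; incremental lumen-pressure loading (50 → 77 mmHg in 10 steps
   by default), inlet/outlet fully fixed; direct sparse factorisation
   with a CG fallback. Internally SI; mm and mmHg only at the I/O
   boundary (133.322 Pa/mmHg).
5. **postproc** — element stress/strain, von Mises stress, deviatoric
   equivalent strain, displacement maxima, and per-case records
   including the systolic-diameter bookkeeping
   `Dsys = Ddias + max displacement`.
6. **rupture_risk** — pressure–strain modulus
   `Ppsm = Ddias (Psys − Pdias) / (Dsys − Ddias)` (kPa) mapped to a
   rupture probability by the one-parameter saturating curve
   `risk = 1 − exp(−k · Ppsm)`, with `k` recovered by least squares
   from the packaged 12-case calibration table (not hard-coded; the
   fit residual is stored and asserted).
7. **cli** — stage orchestration with YAML/JSON config, manifests and
   a single seed.

Default material: E = 0.7 MPa, ν = 0.45, ρ = 1095 kg/m³. Default wall:
2 mm, two element layers, ~1 mm in-plane sizing.

## CLI

```sh
aneufem all  --out run_dir --seed 0        # full synthetic pipeline
aneufem risk --out risk_dir                # packaged calibration table -> report
aneufem synth --config my.yaml             # individual stages: synth |
                                           # reconstruct | mesh | solve | post | risk
```

Each run writes stage outputs (STL / NIfTI / VTU / CSV / JSON), a
`manifest.json` (config hash, seed, versions, timings) and a summary.
Reruns with identical config and seed are byte-identical. Exit codes:
2 = validation error, 3 = numerical failure.

## Validation highlights

- Patch test: constant-strain fields reproduced to 1e-10.
- Thick-walled-cylinder (Lamé) inner hoop stress within 2% (ν = 0.3)
  and monotonically convergent within 5% at ν = 0.45
  (`aneufem.validation`).
- Global equilibrium and step-proportionality to 1e-8.
- Phantom → surface pipeline recovers lumen volume within 3% and max
  diameter within 2% at 1 mm voxels, 10% noise.
- Risk curve reproduces all 12 calibration rows within 0.01 percentage
  points; leave-one-out predictions within 0.05 pp.

## Notes and caveats

- The linear small-strain model is retained even where computed strains
  reach tens of percent; this mirrors the reference workflow and is a
  documented simplification, not a claim of kinematic validity.
- The equivalent-strain definition (von Mises deviatoric form) and the
  risk-curve functional form are engineering choices recovered from the
  calibration data; both are flagged in reports.
- Per-patient stress/strain values from the source cohort are not
  reproducible here (the patient imaging is not public); property-based
  validation and a qualitative stress corridor substitute.
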