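# outflowfe

Inverse finite-element estimation of time-dependent (viscoelastic) shear
moduli of the aqueous outflow tissues — trabecular meshwork (TM),
juxtacanalicular tissue (JCT) and Schlemm's canal (SC) inner wall — from
pressurization-driven boundary motion, with Hughes-Liu viscoelastic beam
elements standing in for collagen fibrils.

The package contains the full pipeline at desk scale:

- `outflowfe.synth` — synthetic stand-ins for the unpublished inputs:
  OCT-like cross-section geometry, forward-simulated boundary trajectories
  with known ground truth, uniaxial specimen stress-strain curves,
  TM-displacement-vs-IOP curves and SC-lumen point clouds.
- `outflowfe.meshing` — boundary smoothing (cubic smoothing spline),
  extrusion to a 10-µm hexahedral slab, TM/JCT/SC-wall layer partition,
  beam control-point distribution (4 µm planar × 2.5 µm through-thickness
  lattice), element quality, critical time step, SC-lumen circle fitting.
- `outflowfe.material` — single-term shear relaxation
  `G(t) = G∞ + (G0 − G∞)·exp(−βt)` with deviatoric hereditary integral
  under an incrementally objective (Jaumann) rotation and elastic bulk.
- `outflowfe.beams` — degenerated-solid (Hughes-Liu) 2-noded beam: section
  ("fiber") vectors with second-order rotational update, co-rotational
  local frame, 6×18 B-matrix, zero transverse normal stress by
  condensation, penalty beam-in-solid coupling.
- `outflowfe.solver` — explicit quasi-static solver (central difference,
  stiffness-proportional mass scaling, mass damping), fully integrated
  hexahedra with mean-dilatation volumetric treatment, follower pressure,
  floating-displacement boundary conditions, displacement probes.
- `outflowfe.fitting` — bounded Nelder-Mead (sigmoid-mapped bounds,
  log-space moduli) for the three calibration stages and the
  perturbed-restart uniqueness audit.
- `outflowfe.stats` — one-way ANOVA, Scheffé post hoc, fold-change report.
- `outflowfe.tables` — the four fitted-parameter tables shipped as CSV
  fixtures.

## CLI

One entry point with subcommands:

```bash
outflowfe synth scene --seed 1 --out scene.yaml
outflowfe synth trajectory --scene scene.yaml --out traj.csv
outflowfe synth specimen --condition healthy --out curve.csv
outflowfe synth lumen --radius 63 --jitter 2 --out lumen.csv
outflowfe mesh --scene scene.yaml --edge 4.0 --out mesh.vtk
outflowfe fit specimen --target curve.csv --out fit.json
outflowfe fit complex --scene scene.yaml --target traj.csv --out fit.json
outflowfe report --out report/
```

## Units

Internally mm – MPa – N – s (consistent explicit-dynamics set); geometric
inputs are micrometres and pressures mmHg, converted at the package
boundary (1 mmHg = 1.33322e-4 MPa).
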