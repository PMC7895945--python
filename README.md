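# nucleomorph

Correlative morphometry toolkit linking MRI-derived gray-matter-volume (GMV)
change to cellular metrics measured in longitudinal 3D two-photon image stacks
of fluorescently labeled cell nuclei.

The package covers the full analysis chain:

- **`nucleomorph.synthetic`** — ground-truth phantom generation: hard-core
  inhomogeneous-Poisson nucleus fields with layered density and a
  two-component (glia/neuron) lognormal volume mixture, longitudinal presets
  (tissue shrinkage, cell loss/gain, nucleus-volume scaling, fiducial
  re-localization noise), rendering into 16-bit stacks with depth attenuation,
  vessel shadows, laser blankouts and additive noise, plus MRI-like
  baseline/follow-up phantom pairs with known deformation fields.
- **`nucleomorph.segmentation`** — 3D nucleus detection: foreground
  probability (computed stand-in or imported HDF5/TIFF), per-plane seed
  detection with a prominence criterion linked across z, seeded 3D watershed,
  the 1500/18,000-voxel size filters with local re-segmentation of merged
  objects at a lowered threshold, and centroid/volume extraction.
- **`nucleomorph.metrics`** — per-stack cellular metrics: counts (whole stack
  and 175-µm depth bins), 3D nearest-neighbor distances, nucleus-volume
  statistics with four size categories (750-µm³ bins up to 3000 µm³ plus
  overflow), relative change versus baseline, and correlation-table assembly.
- **`nucleomorph.hull`** — physical tissue volume from fiducial landmarks via
  3D Delaunay triangulation and convex-hull volume (cross-checked against the
  direct facet-based volume), layer-confined volumes by tetrahedron centroid,
  and percent-of-baseline change series on the completeness-filtered
  common landmark set.
- **`nucleomorph.mri`** — 2D affine registration from vessel fiducials,
  rasterization of stack footprints into 3-plane MRI masks, per-voxel
  Jacobian-determinant fields from displacement fields, mask-restricted GMV
  change with slicewise profiles, and fast-spin-echo PSF arithmetic.
- **`nucleomorph.qc`** — exclusion criteria: SNR (signal-ROI mean over
  background-ROI sd) with a paired 10% stability rule over ≥3 regions, a
  count-scaled z-density-profile difference score (threshold 500 cells), and
  laser-blankout plane detection.
- **`nucleomorph.stats`** — random-intercept linear mixed models (REML) with
  Wald-t fixed-effect tests, marginal R², variance inflation factors,
  pairwise timepoint contrasts with Holm correction, one-sample
  change-versus-baseline tests (t / Wilcoxon / auto), and repeated-measures
  ANOVA with Tukey post-hoc.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property-based tests for the
conservation/invariance contracts, and `tests/test_acceptance.py` with one
test per acceptance criterion (analytic oracles, Monte-Carlo cross-checks and
parameter-recovery simulations on synthetic ground truth).

## Command-line interface

All stages are exposed through one `nucleomorph` entry point:

```bash
nucleomorph simulate  --config sim.yaml --seed 1 --out data/        # synthetic dataset
nucleomorph segment   --stack stack.tif [--prob prob.h5] --config seg.yaml --out seg/
nucleomorph metrics   --nuclei seg/nuclei.csv --out metrics.csv
nucleomorph hull      --fiducials fiducials.csv --baseline 0 --out hull.csv
nucleomorph register  --pairs pairs.csv --mri mri.nii --surface-plane 2 --out mask.nii
nucleomorph gmv       --field disp.nii --mask mask.nii --out gmv.csv
nucleomorph qc        --nuclei-t t.csv --nuclei-ref ref.csv --rois rois.yaml --out qc.csv
nucleomorph correlate --table long.csv --response gmv_pct --fixed hull_pct --out model.json
```

Stacks are multi-page 16-bit TIFF (z-major), label volumes 32-bit TIFF,
probability maps HDF5, MRI volumes / masks / displacement fields NIfTI
(displacement as 4D, last axis = z,y,x components in µm), and all tables CSV.

## Conventions

- Arrays are `(z, y, x)`; z increases with cortical depth, z = 0 at the
  tissue surface; voxel centers sit at `(index + 0.5) × voxel_size`.
- Nucleus tables carry `animal_id, position_id, timepoint, nucleus_id,
  x_um, y_um, z_um, volume_voxels, volume_um3`.
- Depth bins are half-open `[a, b)` with the last bin closed; size categories
  are left-closed with volumes above the last edge counted as overflow.
- Percent-of-baseline values are `100 × value / baseline`.
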