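# perivasc

Analysis pipeline for perivascular spaces (PVS) in high-resolution 3D
contrast-enhanced MR volumes: tubeness-based segmentation, connectivity of
the perivascular network to the ventricles, minimum-clearance-distance
(MCD) maps of the parenchyma, and a closed-form model of oscillatory
solute dispersion in perivascular channels.

## The problem

Perivascular spaces are thin fluid sheaths around cerebral blood vessels
that exchange solutes with the cerebrospinal fluid (CSF) and are thought
to be a major route for clearing metabolic waste (e.g. amyloid-beta) from
brain tissue.  In ex vivo rodent brains imaged at very high field after
intraventricular infusion of a gadolinium-labelled albumin tracer, the
PVS appear as bright tubes of near-voxel width (40 um).  This package
implements the quantitative chain from such images to transport
estimates, and ships a synthetic phantom generator with exact ground
truth so every stage is testable without access to the original MRI
data.

The stages:

1. **Phantom generation** (`perivasc.phantom`) — brain-shaped volumes
   with a bright ventricle, bright tubes of known centerline and radius,
   a smooth bias field and Gaussian noise, plus matched "naive"
   (no-tracer) controls.
2. **Projections** (`perivasc.projections`) — partial and shifting
   maximum intensity projections (pMIP/spMIP) through 30-voxel slabs.
3. **Tubeness segmentation** (`perivasc.tubeness`) — per-voxel tubeness
   `sqrt(lam2*lam3)` of the Hessian of the Gaussian-smoothed intensity
   (eigenvalues sorted `lam1 >= lam2 >= lam3`, score zero unless both
   `lam2, lam3 < 0`), thresholded at the 95th-percentile tubeness of the
   naive controls, with a separate (higher) threshold for the brain
   surface.  Exposed both as functions and as the scikit-learn-style
   estimator `PVSSegmenter` (`fit` on controls, `predict` on a contrast
   volume).
4. **Network analysis** (`perivasc.network`) — dilate the ventricle mask
   by 3 voxels, region-grow 100 iterations into the PVS mask to extract
   the periventricular-connected subnetwork; estimate segment lengths by
   a seeded layered grow summing consecutive layer-centroid distances.
5. **Clearance** (`perivasc.clearance`) — Euclidean distance transform
   from parenchyma to the nearest CSF compartment (ventricles + brain
   surface, optionally + PVS), diffusive and advective time scales
   `tau_d = L^2/D*`, `tau_a = L/u`, and geometric corrections for
   voxel-averaging and fixation shrinkage.
6. **Dispersion** (`perivasc.dispersion`) — oscillatory Taylor
   dispersion in a semi-infinite channel, `dC/dt = kD d2C/dx2`, with the
   self-similar front solution `alpha = 1 - erf(x / sqrt(4kDt))` and its
   inverses for front position, velocity and traversal time.

## Worked example

Front kinematics from the command line — the time for the
half-concentration (alpha = 0.5) albumin front (D = 83 um²/s) to travel
1 mm along a perivascular channel with 70% dispersive enhancement
(k = 1.7):

```sh
$ perivasc dispersion --D 83 --k 1.7 --alpha 0.5 --distance 1000
alpha=0.5 front traverses 1000 um in 2.16 h
```

Two hours for one millimetre: oscillatory dispersion alone is far too
slow to explain tracer filling of multi-millimetre perivascular segments
within a 40-minute infusion, whereas bulk advection at the observed
18.7 um/s covers 4 mm in 3.57 min.

The full phantom pipeline:

```python
from perivasc.phantom import demo_spec
from perivasc.pipeline import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(phantom=demo_spec(7), seed=7))
print(manifest["segmentation_dice"])                      # 0.786
print(manifest["clearance"]["without_pvs"]["mean_mm"])    # 0.193
print(manifest["clearance"]["with_pvs"]["mean_mm"])       # 0.069
print(manifest["clearance"]["fold_reduction_tau_d"])      # 7.72
```

On this 56³ demonstration phantom the naive-calibrated segmentation
recovers the seeded tubes with Dice 0.79 against ground truth, and
counting the segmented PVS as CSF cuts the mean clearance distance from
0.193 mm to 0.069 mm — a 7.7-fold drop in the diffusive clearance time
scale (the square of the distance ratio).  The same quadratic scaling
applied at tissue scale (0.784 mm to 0.169 mm) gives the >21-fold
reduction computed by `perivasc.clearance.diffusive_time`.

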