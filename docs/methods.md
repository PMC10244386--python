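# Methods

This note documents the models, conventions and numerical choices behind
`perivasc`, and what the synthetic phantoms do and do not establish about
real data.

## Coordinate and unit conventions

Volumes are axis-aligned voxel lattices; voxel `(i, j, k)` has its center
at `((i+0.5)sx, (j+0.5)sy, (k+0.5)sz)` in mm.  Lengths are mm inside
distance maps and phantom geometry, um in the dispersion model and the
correction arithmetic; diffusivities are um²/s; times are seconds
internally with min/h formatting at the reporting layer.  All masks that
enter one operation must share shape and spacing; mismatches raise
`GeometryError`.

## Synthetic phantoms

A phantom is a piecewise-constant intensity model: background, an
ellipsoidal "brain" at `parenchyma_level`, a ventricle compartment
(union of ellipsoids/boxes, clipped to the brain) at `csf_level`, and
tubes at `tube_level`, where a voxel belongs to a tube iff its center
lies within the tube radius of the centerline polyline (minimum
point-to-segment distance; this rule is brute-force checkable and is the
ground truth).  The volume is then multiplied by a smooth bias field
`1 + a·cos(pi x/Lx)cos(pi y/Ly)cos(pi z/Lz)` emulating B1 inhomogeneity
(default amplitude 5%) and perturbed by additive Gaussian noise.  The
matching naive control has identical geometry, bias and noise but no
enhancement anywhere.  Generation is fully deterministic given the seed.

Default spacing is 0.04 mm isotropic and the default grid is the
acquisition matrix scale (500×400×300); analyses and tests run on the
56³ `demo_spec` phantom (2.24 mm cube, spherical brain of radius 1 mm,
central ventricle of radius 0.22 mm, 16 radial tubes of radius 0.15 mm
spanning ventricle to surface, contrast 4:1 over parenchyma,
contrast-to-noise 10).  These sizes keep every stage — including the
per-voxel eigen-decomposition — at a few seconds per volume.

Noise is additive Gaussian rather than Rician: the emulated images are
high-SNR magnitude images where the two are nearly indistinguishable,
and a Gaussian keeps the percentile calibration analytically
predictable.  The phantoms deliberately do *not* model vascular tree
topology, MR signal equations, partial-volume blur at acquisition, or
motion; consequences are listed under Limitations.

## Tubeness and segmentation

The intensity volume is smoothed with a Gaussian of physical scale
`sigma` (default 0.04 mm = one voxel, matching the width of the thinnest
structures of interest), the 3×3 Hessian is formed per voxel, its
eigenvalues are sorted descending (`lam1 >= lam2 >= lam3`), and the
score is `sqrt(lam2·lam3)` where both are negative, else zero.  Bright
tubes give `lam1 ~ 0` and `lam2 ~ lam3 << 0`; dark tubes, blobs and
saddles score zero or low.  The zero rule also guarantees the score is
real-valued everywhere.

Two Hessian discretizations are provided:

* `central` (default): smooth, then compact central stencils —
  `[1,-2,1]/h²` on the diagonal and successive `[-1,0,1]/2h` differences
  for mixed terms, each scaled by the physical spacing.  On a Gaussian
  ridge of smoothed scale `s` the diagonal stencil reads
  `2(1-exp(-h²/2s²))/h²` times the amplitude rather than `1/s²`; the
  tests assert exactly that value, so the discretization is characterized
  rather than hidden.
* `gaussian`: derivative-of-Gaussian convolution (order-2 filters),
  which evaluates the continuous derivative of the smoothed field.

Both are exposed because the tool chains used for this kind of analysis
differ on this point; the default is the simpler, more oracle-friendly
choice.  Edges are handled by replicate padding.  Anisotropic spacing is
supported by expressing `sigma` and all stencils in physical units.

**Threshold calibration.**  Absolute tubeness values depend on the
intensity normalization, so no threshold is hard-coded.  Instead, each
volume's within-brain intensity histogram peak (256 bins over the
0.5–99.5 percentile range; mode = center of the tallest bin) may first be
aligned to a common reference, and the threshold for each region is the
mean over naive control volumes of that volume's 95th-percentile
tubeness in the region.  Two regions are used: the brain interior and a
surface shell (default 3 voxels of 26-connected erosion), because the
brain/background interface produces strong curvature even without any
tracer and needs a higher threshold.  The "surface" definition is the
main free choice in this stage and is configurable.

A structural consequence of percentile calibration: by construction,
about 5% of parenchymal voxels in a contrast volume with control-like
noise statistics exceed the threshold.  Segmentations therefore always
carry a false-positive floor; overlap scores against ground truth are
only meaningful on phantoms whose true tube volume is not negligible
against that floor.  This is why `demo_spec` is tube-dense (~15% of the
brain) — the Dice ≈ 0.78 recovery result demonstrates that the pipeline
finds what is there, not that real segmentations are 78% correct.
A second, related effect: at tube edges the tangential curvature is
strongly negative while the radial curvature is near zero, so noise can
flip the sign and produce a one-voxel halo of high scores around true
tubes.  Both effects are properties of the method, not bugs, and bound
the achievable phantom-recovery Dice.

## Connectivity and segment length

"Immediately adjacent" is interpreted as 26-connectivity by default
(consistent with counting the three-voxel diagonal, `sqrt(3)·3·40 um =
208 um`, as within reach); 6 and 18 are available.  The periventricular
network is obtained by dilating the ventricle mask 3 voxels and growing
it into the PVS mask for at most 100 iterations; the result is the
captured PVS (grown set minus seed, plus any PVS already inside the
dilated margin).  Growth is monotone in iterations and equals a
depth-bounded breadth-first search, which the tests verify against an
independent BFS oracle.

Segment length is the sum of distances between centroids of successive
growth layers from a seed voxel at one end of the segment.  On a
one-voxel-wide straight tube each layer is one voxel and the estimate is
exact ((n-1)·spacing); at corners and branch points layer centroids blend
and shorten the estimate slightly (the L-shaped-tube test bounds this at
5%).  Seeds are explicit inputs (voxel indices); no automatic endpoint
detection is attempted.

## Clearance distances and time scales

CSF is defined as everything outside the brain mask (subarachnoid proxy)
plus the ventricles, optionally plus the segmented PVS.  The distance
map is the Euclidean distance transform of the complement of that set
with anisotropy-aware sampling, i.e. center-to-center distances: a voxel
face-adjacent to CSF is one spacing away.  This convention is stated so
the brute-force oracle in the tests and the implementation agree
exactly.  Time scales are `tau_d = L²/D*` and `tau_a = L/u`; with the
amyloid-beta effective diffusivity `D* = 62.3 um²/s`, a mean distance of
0.784 mm gives 2.74 h, and reducing the distance to 0.169 mm reduces the
time by the squared ratio, >21-fold.

Two corrections quantify systematic biases of voxelized ex vivo data:

* voxel-vertex underestimate: a vessel of diameter d centred on the
  shared vertex of four in-plane voxels that are all segmented as PVS
  hides `sqrt(2)·(h/2) - d/2` of clearance distance (19.36 um for
  d = 17.85 um on a 40 um grid); clamped at zero when the vessel reaches
  the voxel centers;
* fixation shrinkage: a volume shrinkage fraction f implies in vivo
  increases of `1/(1-f) - 1` in volume, its cube root in length, and its
  square in the diffusive time scale (f = 0.106 → +11.9%, +3.81%,
  +7.76%).

## Oscillatory dispersion

Oscillatory flow in the perivascular annulus enhances effective axial
diffusion by a factor `k` (literature values 1.05 and 1.7 bracket the
published estimates).  With a well-mixed CSF reservoir at the mouth of a
semi-infinite channel, `dC/dt = kD d²C/dx²` admits the self-similar
solution `alpha = 1 - erf(eta)`, `eta = x/sqrt(4kDt)`.  Front position,
velocity and traversal time follow by inverting the erf (via the
standard high-accuracy numerical inverse).  The closed form is verified
in the tests against an explicit finite-difference solution of the PDE
(801-point grid over 4 mm, stability factor 0.2, <1% pointwise at
t = 600 s).  Note `v = x/2t` diverges as `t -> 0` — a step boundary
condition has infinite initial front speed — so velocity queries require
`t > 0`.

## Design decisions that were genuinely open

* Hessian discretization: smooth-then-difference chosen as default over
  Gaussian-derivative filtering (both implemented; see above).
* Region-grow neighborhood: 26, inferred from the diagonal-distance
  reasoning behind the 3-voxel margin; not certain, hence configurable.
* Surface region: erosion-based shell of 3 voxels; "surface" is
  otherwise undefined.
* Thresholds: calibrated, never hard-coded; printed literature values
  (e.g. an interior threshold of 3.75 on one dataset's scale) are
  dataset-specific and not reproduced.
* Histogram mode estimator: fixed-bin argmax, robust to outliers by
  percentile-range binning.
* Phantom study conditions: contrast 4:1, CNR 10, dense radial tube
  arrangement — chosen once as a regime in which recovery statistics are
  informative (see the false-positive floor discussion).

## Limitations

* Phantom tubes are straight-to-gently-curved cylinders; no branching
  trees, varying calibre, or contact between tubes.  Passing recovery
  tests show the machinery is correct, not that segmentation accuracy
  transfers to anatomically realistic networks.
* The percentile threshold guarantees ~5% background false positives on
  any volume with control-like statistics; real percent-volume readouts
  inherit this bias.
* Segment-length estimation blends centroids at branches and bends;
  lengths of tortuous segments are biased short.
* The dispersion model has no explicit oscillatory flow, no annular
  geometry, and treats `k` as an input constant; it addresses order-of-
  magnitude transport questions only.
* A radial-diffusion estimate of perivascular-to-tissue concentration
  ratios (cylindrical source geometry) is not implemented; the published
  description of that estimate does not specify the formula used.
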