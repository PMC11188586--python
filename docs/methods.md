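# Methods

This note documents the models, parameters, numerical choices and known
limitations of `fibertrack`. It is written for users who need to judge
what a result on synthetic or real data does and does not demonstrate.

## Imaging model and coordinate conventions

The package operates on stacks of aligned 2D grayscale slices cut
transversely to a nerve: one PNG per slice, lexicographic filename order =
ascending z, plus an XML metadata file carrying `pixel_size_xy` (µm),
`image_slice_thickness` (µm), `image_type`, `num_images_to_read` and
`step_size`, each stored in a `name` attribute. Voxel indices are 0-based;
a streamline point (x, y, z) is physical µm with x = column·pixel_size,
y = row·pixel_size, z = slice·slice_thickness. Stacks are read lazily
(bounded cache of 8 decoded slices by default) because production stacks
exceed RAM.

RGB input is converted to grayscale as 0.5·R + 0.5·G: the fluorescent and
absorptive stains used in block-face imaging of nerve put essentially all
signal in the red and green channels. The rounding rule (half-up, then
clip) is fixed so conversions are exactly reproducible; gamma correction,
when requested, is applied after grayscale conversion.

## Seeding

Connected components of the user mask are the ROIs (8-connectivity, which
merges diagonal touches — the safer interpretation for hand-drawn masks).
Within each component the pixels are enumerated row-major, permuted by a
generator re-seeded per component with `rng_seed + label`, and the first
`max(1, floor(count·density))` become seeds. Re-seeding per component means
editing one ROI never perturbs another ROI's seeds; the floor-with-minimum
rule guarantees every ROI is tracked at any density. Default density is
1 seed per 100 foreground pixels, capped at 1 per pixel.

## Lucas–Kanade optic flow

Both slices are blurred (Gaussian, σ = 2 px by default, reflect
boundaries); Ix, Iy are central differences of the first blurred slice and
Iz is the blurred difference. The window sum of gradient products gives
the 2×2 normal equations at every pixel, solved in closed form. Flow is
computed densely so that tracking can interpolate displacements at
arbitrary sub-pixel positions.

* Window default 50 px, pyramid levels 2. An even window is incremented so
  the window has a center pixel. The window is unweighted (plain sum).
* Validity: the smaller eigenvalue of the normal matrix must reach
  1e-4 × window area. The constant scales with window area so the rule is
  invariant to the window choice; below it the aperture problem makes the
  solution meaningless and the flow is reported as invalid zeros.
* Pyramid: factor-2 block-average downsampling; coarse-to-fine with
  bilinear warping (replicated borders) and flow doubling at each level.
  Levels whose coarsest image would fall below twice the window are
  dropped with a warning. A single level reduces exactly to plain
  Lucas–Kanade.
* Accuracy at the borders degrades over roughly a window width (and more
  at coarse pyramid levels, where the window covers a proportionally
  larger image fraction); quantitative statements in the tests are made on
  window-deep interiors.

## Structure tensor

Gradients are Gaussian derivatives at the noise scale σn (default 1 px);
the gradient outer products are smoothed componentwise at the neighborhood
scale σnb (default 5 px). This realizes the neighborhood sum as a soft
Gaussian window, matching the scale-space naming of the two parameters.
The per-voxel orientation is the eigenvector of the smallest eigenvalue,
sign-fixed so uz ≥ 0 (ties broken toward uy, then ux ≥ 0).

* Validity: voxels with tensor trace < 1e-2 (≈ gradient magnitudes of
  0.1 gray level on 8-bit data, i.e. below quantization noise) or with the
  two smallest eigenvalues tied within relative 1e-9 carry no direction
  and are invalid.
* Isotropization: orientation is estimated on a grid downsampled in XY by
  the integer factor closest to slice_thickness / pixel_size (e.g. 0.9 µm
  pixels at 3 µm spacing → factor 3, 2.7×2.7×3 µm voxels), because the
  tensor assumes comparable sampling along all axes. Factors below 2 are
  a no-op; the step can be disabled.
* Chunked processing: the stack is processed `step_size` slices at a time
  with an overlap margin of ceil(3·(σn + σnb)) slices per side. All
  Gaussian kernels are truncated at exactly 3σ, so the filter support
  never exceeds the margin and the chunked result is **bit-identical** to
  a single full-volume pass (this invariance is tested, and is the reason
  the package does not use the default 4σ truncation of common filtering
  routines).
* Near the first and last ~3·(σn+σnb) slices, reflected boundaries bias
  orientations toward the stack axis (a reflected tilted structure looks
  locally symmetric). This is inherent to any finite stack; on production
  stacks of a thousand slices the affected fraction is negligible, on
  desk-scale phantoms it is visible in slope estimates near the ends.

## Streamline propagation

One point per crossed slice plane. In optic-flow mode the displacement is
sampled bilinearly and the step is (Vx·px, Vy·px, ±thickness). In tensor
mode the orientation is sampled by nearest neighbor (the estimation grid is
coarse; smoother interpolation would pretend to sub-voxel information the
field does not carry), sign-aligned to the tracking direction, and scaled
so |Δz| = thickness.

* Termination: step angle to the stack axis > 75° (the nerve is sectioned
  transversely, so the stack axis is the anatomical long axis); point
  leaves the image (positions are not clamped); flow invalid at the
  location. In tensor mode up to 2 consecutive invalid voxels are bridged
  by repeating the previous direction — enough to cross isolated
  degenerate voxels without letting tracks wander.
* Anatomical constraint: `truncate` cuts each streamline at its last
  consecutive in-mask point from the seed; `remove` deletes any streamline
  that ever leaves the mask. Both guarantee that surviving points lie in
  mask foreground.
* Editing: polygon-based deletion (streamline removed if its point on the
  chosen slice falls inside the contour) and creation (polygon rasterized,
  seeded and propagated with the same machinery under a fresh ROI label).
* Determinism: seeding, both flow estimators and propagation are exact
  functions of their inputs; a run's provenance (inputs, parameters,
  seeds) regenerates its tractogram byte-for-byte.

## Metrics

* `dice_norm`: tractogram points on a slice are rounded to pixels and
  compared with the ground-truth fiber-group mask by Dice; values are
  normalized by the seeding-slice Dice so seed density cancels. Dice on
  two empty masks, or a zero Dice at the seeding slice, is an error rather
  than a conventional value — silent zeros hide evaluation mistakes. The
  normalization assumes a group's cross-sectional area is roughly constant
  along the sample; values slightly above 1 are possible when it is not.
* `mcn_dist`: both tractograms are simplified by incremental
  QuickBundles-style clustering — streamlines in stored order, resampled
  to K = 12 arc-length-uniform points, assigned to the nearest centroid of
  their own ROI if the minimum-direct-flip (MDF) distance is within
  θ = 50 µm, else opening a new cluster; centroids are running means of
  flip-aligned members. The reported value is the mean over A-centroids of
  the MDF distance to the closest same-ROI B-centroid, averaged with the
  B→A direction. Incremental clustering is order-dependent by
  construction; the stored streamline order is part of provenance, which
  keeps the metric reproducible. ROIs present in only one tractogram are
  skipped with a warning; no shared ROIs is an error.

## Synthetic phantoms

The generator emulates what the tracker actually consumes in transverse
nerve stacks: bright tubular fiber cross-sections (anti-aliased,
coverage-weighted disks, so sub-pixel drift is expressible), grouped into
fascicles that run along z, over a dark background with additive Gaussian
noise, at the production calibration of 0.9 µm pixels and 3 µm slice
spacing. Default fiber radius is 3 px (≈ 5 µm diameter, a typical resolved
fiber profile). Centerline models: straight, tilted, helical, piecewise,
and per-fiber migration paths for split/merge scenes. Every artifact —
slices, labelled seed mask, fascicle masks, fiber-group masks, analytic
ground-truth streamlines — is a deterministic function of the spec and its
seed.

* Ground-truth fiber-group masks emulate manual group tracing: a convex
  outline around each visually coherent cluster of a group's fibers
  (single-linkage at 24 px), so a group that splits apart is outlined as
  separate components, exactly as a human tracer would draw it.
* Fascicle masks are disks around the bundle centers plus a thin corridor
  around every fiber, so migrating groups remain anatomically enclosed
  (phantom self-consistency: ground-truth streamlines always lie inside
  the fascicle masks).
* The split/merge scene places source fascicles on a ring around a central
  target fascicle; fiber groups migrate to disjoint landing sectors along
  smoothstep trajectories staggered in z. The default migration angle is
  20° — real merge events drift at shallow angles over extended depths —
  and angles above 45° are rejected, keeping well inside the 75°
  termination envelope. Groups keep their internal spread while migrating
  so each ROI's cross-sectional area stays constant, the assumption under
  which Dice values are comparable across slices.

What the phantoms do **not** model: stain and illumination variation
across slices, tile-stitching seams, dense packing where fascicles fill
the field, myelin texture inside fibers, and registration error between
slices. Passing the phantom suite therefore demonstrates the correctness
of the algorithms and their implementation, not their accuracy on any
particular tissue preparation.

## Desk-scale run conditions

End-to-end experiments in the test suite and in `scripts/acceptance.py`
run on phantoms of roughly 280×280 px × 112 slices with 24 fibers — about
a hundredfold smaller in area than production stacks. Two parameters are
scaled accordingly, as the package's own choice for these scene sizes:

* the Lucas–Kanade window is 21 px (the production default of 50 px is
  sized for full-frame fascicles; a window much wider than a fascicle
  mixes moving and static structures and violates the locally-constant
  flow assumption);
* the seeding density is 0.2 (phantom ROIs are a few hundred pixels; at
  the production default of 0.01 a point-cloud Dice would rest on a
  handful of points and be dominated by rasterization noise).

All other parameters keep their production defaults (pyramid levels 2,
blur σ 2 px, noise scale 1 px, neighborhood scale 5 px, chunk size 64,
termination 75°, θ = 50 µm, K = 12).

## Numerical notes and limitations

* The structure-tensor eigenvector minimizes the quadratic form uᵀJu
  exactly; the literal displace-and-subtract objective agrees on
  structured (fiber-like) volumes but not on interpolated white noise,
  where the Taylor linearization underlying the tensor breaks down at
  unit displacements. The test suite checks the quadratic form against an
  explicit windowed-sum oracle on random volumes and the literal objective
  on fiber volumes.
* Tensor-mode tracking accumulates a small along-track lag on curved
  trajectories: Gaussian smoothing across the trajectory curvature
  regresses the local slope toward its neighborhood mean, and
  nearest-neighbor sampling quantizes positions to the isotropized grid.
  On the merge phantom this amounts to a few pixels over ~100 slices —
  visible as mean Dice_norm ≈ 0.91 for the tensor route versus ≈ 0.95 for
  optic flow.
* Dice_norm on sparse point clouds is a ratio of small Dice values; it is
  meaningful, but its variance grows as seed counts shrink.
* The `.trk` export writes coordinates in µm with the voxel calibration in
  the header; viewers that assume millimetres will show a scaled scene.
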