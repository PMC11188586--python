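# fibertrack

Microscopic tractography for serial block-face microscopy stacks of
peripheral nerve.

Serial block-face fluorescence microscopy images a resin-embedded nerve
transversely, slice after slice, producing stacks of thousands of aligned
2D images in which fiber cross-sections appear as bright tubular profiles
grouped into fascicles. `fibertrack` estimates the local fiber orientation
in such stacks, propagates seeded streamlines along the nerve, constrains
them anatomically to fascicle masks, and quantifies the resulting
tractograms — so that anatomists and neuromodulation modellers can map how
fiber groups split, merge and travel along a nerve without segmenting
every fiber on every slice.

## Methods at a glance

**Optic flow (Lucas–Kanade).** Consecutive slices are treated as video
frames. Under brightness constancy, the intensity derivatives satisfy

    Ix(p)·Vx + Iy(p)·Vy = −Iz(p)

at every pixel *p*. Assuming the flow (Vx, Vy) constant over an *n*×*n*
window yields *n*² equations in two unknowns, solved in least squares via
the 2×2 normal equations; a coarse-to-fine pyramid (factor 2 per level)
extends the valid displacement range. Pixels whose normal matrix is
near-singular (aperture problem) are marked invalid.

**Structure tensor.** The local fiber direction **u** at a voxel minimizes
the intensity variation

    D(u) = Σ_{p′∈N(p)} ( V(p′+u) − V(p′) )² ≈ uᵀ J u,
    J = Σ_{p′∈N(p)} w(p′) (∇V)(∇V)ᵀ,

and is the eigenvector of the structure tensor *J* with the smallest
eigenvalue. Gradients are Gaussian derivatives at the *noise scale*; the
neighborhood sum is Gaussian smoothing at the *neighborhood scale*. Stacks
are processed in overlapping chunks so that arbitrarily deep stacks fit in
memory, with overlaps chosen so the result is bit-identical to a
single-pass computation.

**Tracking.** Seeds are sampled deterministically from ROI-labelled masks
(1 seed per 100 foreground pixels by default). Streamlines advance one
slice per step — bilinear flow interpolation in optic-flow mode,
nearest-neighbor orientation sampling in tensor mode — and terminate when
the step diverges more than 75° from the stack axis, leaves the image,
exits a fascicle mask (anatomically constrained tracking), or enters a
region with undefined flow.

**Metrics.** `dice_norm` rasterizes a tractogram's per-slice point cloud
to a binary mask and reports its Dice overlap with ground-truth
fiber-group outlines, normalized by the Dice at the seeding slice.
`mcn_dist` clusters both tractograms (QuickBundles-style incremental
clustering under the minimum-direct-flip distance) and reports the
symmetrized mean closest-neighbor distance between cluster centroids of
matching ROIs, in µm.

**Phantoms.** `fibertrack.phantom` generates synthetic stacks with known
geometry — straight, tilted, helical and split/merge fascicles with
anti-aliased sub-pixel rendering, additive noise, per-slice masks and
analytic ground-truth streamlines — so every stage is testable without
any imaging data.

## Worked example

```python
from fibertrack import (
    make_split_merge_scene, build_phantom, seeds_from_mask,
    TensorTracker, OpticFlowTracker, propagate, mcn_dist,
)
from fibertrack.cli import mean_dice_norm

# a 4-into-1 fascicle merge: 24 fibers, 280x280 px at 0.9 um, 112 slices
spec = make_split_merge_scene(rng_seed=5)
phantom = build_phantom(spec)

seeds = seeds_from_mask(phantom.seed_mask, density=0.2, rng_seed=1,
                        mask_is_labelled=True)
eval_slices = [spec.depth // 3, 2 * spec.depth // 3, spec.depth - 1]

tracts = {}
for provider in (TensorTracker(phantom.stack),
                 OpticFlowTracker(phantom.stack, window=21, levels=2)):
    tract = propagate(seeds, provider, direction="forward", max_angle_deg=75.0)
    report = mean_dice_norm(tract, phantom.fiber_masks, eval_slices, 0)
    tracts[provider.kind] = tract
    print(f"{provider.kind:16s} {len(tract)} streamlines, "
          f"mean Dice_norm = {report['dice_norm'].mean():.3f}")

d = mcn_dist(tracts["optic-flow"], tracts["structure-tensor"])
print(f"MCN_dist between the two tractograms: {d:.1f} um")
```

prints

```
structure-tensor 133 streamlines, mean Dice_norm = 0.910
optic-flow       133 streamlines, mean Dice_norm = 0.954
MCN_dist between the two tractograms: 1.2 um
```

Both algorithms follow the merging fiber groups: a Dice_norm near 1 means
the tractogram overlaps the hand-traceable group outlines as well at depth
as it did at the seeding slice, and the ~1 µm MCN_dist says the two
algorithms produced nearly interchangeable tractograms on this scene.

## Command line

```sh
fibertrack phantom --preset split-merge --depth 112 --seed 7 --out scene/
fibertrack track --stack scene/slices --meta scene/meta.xml \
    --mask scene/seed_mask.png --mask-is-labelled \
    --algo structure-tensor --density 0.2 --seed 42 --out tract.jsonl
fibertrack evaluate --tract tract.jsonl --gt-masks scene/fiber_masks \
    --slices 37,74,111 --out report.csv
fibertrack compare --tract-a a.jsonl --tract-b b.jsonl --theta 50 --out mcn.json
fibertrack robustness --stack scene/slices --meta scene/meta.xml \
    --mask scene/seed_mask.png --gt-masks scene/fiber_masks \
    --slices 37,74,111 --out robustness.csv
```

Every `track` run writes a provenance JSON beside its output;
`fibertrack rerun <provenance> --out b.jsonl` reproduces the tractogram
byte-for-byte. Tractograms are stored as documented JSON-lines and can be
exported to TrackVis `.trk` (`--trk`) for viewing in standard diffusion
tools. The `robustness` command re-tracks downsampled stack variants (2×/4×
in z, 2×/3× in XY) and tabulates mean Dice_norm plus MCN_dist against the
baseline.

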