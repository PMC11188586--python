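"""Synthetic serial block-face fiber phantoms with known geometry.

The generator emulates transversely sectioned peripheral nerve as imaged by
block-face fluorescence microscopy: bright tubular fiber cross-sections,
grouped into fascicles, running roughly along z with sub-pixel in-plane
drift per slice, over a dark background with additive Gaussian noise.
Default calibration matches a typical acquisition (0.9 um pixels, 3 um
slice spacing); image extent and fiber counts are desk-scale.

Every output is a deterministic function of the spec and its rng_seed:
the PNG stack, the labelled seed mask, per-slice fascicle and fiber-group
masks, and the analytic ground-truth streamlines (the exact fiber
centerlines, one point per slice).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from PIL import Image

from .stack_io import ArrayStack, StackMeta, write_metadata
from .tracking import MaskStack, REACHED_END, Streamline, Tractogram

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "render_phantom",
    "make_straight_scene",
    "make_tilted_scene",
    "make_helix_scene",
    "make_texture_scene",
    "make_split_merge_scene",
    "disk_mask",
]

DEFAULT_PIXEL_SIZE = 0.9  # um
DEFAULT_SLICE_THICKNESS = 3.0  # um
DEFAULT_FIBER_RADIUS = 3.0  # px (~5 um diameter fibers)
DEFAULT_BRIGHTNESS = 200.0
DEFAULT_BACKGROUND = 20.0
#: smooth trajectories stay within this angle of the stack axis by design,
#: leaving headroom below the 75 deg tracking termination envelope
MAX_MIGRATION_ANGLE_DEG = 45.0


@dataclass
class BundleSpec:
    """One fascicle: a centerline model plus fibers at fixed offsets.

    ``kind`` selects the centerline: "straight" (constant center), "tilted"
    (constant in-plane drift of tan(angle)*slice_thickness/pixel_size px per
    slice along ``azimuth_deg``), "helical" (radius/pitch about the center),
    or "piecewise" (linear interpolation of (z, x, y) knots).  Explicit
    ``fiber_paths`` (n_fibers, depth, 2) override the centerline+offset
    model entirely (used by split/merge scenes).
    """

    roi_label: int
    center: tuple  # (x, y) px at z = 0
    n_fibers: int = 6
    fiber_radius_px: float = DEFAULT_FIBER_RADIUS
    fascicle_radius_px: float = 16.0
    kind: str = "straight"
    angle_deg: float = 0.0
    azimuth_deg: float = 0.0
    helix_radius_px: float = 0.0
    helix_pitch_slices: float = 50.0
    knots: list | None = None  # [(z, x, y), ...]
    offsets: np.ndarray | None = None  # (n_fibers, 2) px, sampled if None
    fiber_paths: np.ndarray | None = None  # (n_fibers, depth, 2) px


@dataclass
class PhantomSpec:
    """Full description of a synthetic stack."""

    width: int
    height: int
    depth: int
    bundles: list
    pixel_size_xy: float = DEFAULT_PIXEL_SIZE
    slice_thickness: float = DEFAULT_SLICE_THICKNESS
    fiber_brightness: float = DEFAULT_BRIGHTNESS
    background: float = DEFAULT_BACKGROUND
    noise_sigma: float = 0.0
    drift_per_slice: tuple = (0.0, 0.0)  # global (dx, dy) px per slice
    rng_seed: int = 0
    invert: bool = False  # absorptive-stain appearance (dark fibers)
    step_size: int = 64
    #: fibers closer than this (px, center-to-center) belong to the same
    #: visual cluster when drawing ground-truth group outlines; a group
    #: whose fibers split further apart is outlined as separate components
    group_link_px: float = 24.0

    @property
    def meta(self) -> StackMeta:
        return StackMeta(
            pixel_size_xy=self.pixel_size_xy,
            slice_thickness=self.slice_thickness,
            image_type=".png",
            num_images_to_read=self.depth,
            step_size=self.step_size,
        )


def _centerline(b: BundleSpec, spec: PhantomSpec) -> np.ndarray:
    """Bundle centerline (depth, 2) in px."""
    z = np.arange(spec.depth, dtype=np.float64)
    cx, cy = b.center
    if b.kind == "straight":
        x = np.full_like(z, cx)
        y = np.full_like(z, cy)
    elif b.kind == "tilted":
        drift = (
            math.tan(math.radians(b.angle_deg))
            * spec.slice_thickness
            / spec.pixel_size_xy
        )
        az = math.radians(b.azimuth_deg)
        x = cx + drift * math.cos(az) * z
        y = cy + drift * math.sin(az) * z
    elif b.kind == "helical":
        phase = 2 * math.pi * z / b.helix_pitch_slices
        x = cx + b.helix_radius_px * (np.cos(phase) - 1.0)
        y = cy + b.helix_radius_px * np.sin(phase)
    elif b.kind == "piecewise":
        knots = sorted(b.knots)
        kz = np.array([k[0] for k in knots], dtype=float)
        kx = np.array([k[1] for k in knots], dtype=float)
        ky = np.array([k[2] for k in knots], dtype=float)
        x = np.interp(z, kz, kx)
        y = np.interp(z, kz, ky)
    else:
        raise ValueError(f"unknown centerline kind {b.kind!r}")
    return np.column_stack([x, y])


def _fiber_offsets(b: BundleSpec, rng_seed: int) -> np.ndarray:
    if b.offsets is not None:
        return np.asarray(b.offsets, dtype=np.float64)
    rng = np.random.default_rng(rng_seed + 7919 * b.roi_label)
    r_max = max(b.fascicle_radius_px - b.fiber_radius_px - 1.0, 0.0)
    # rejection-free disk sampling with a minimum spacing pass
    offsets = []
    min_sep = 2.0 * b.fiber_radius_px + 1.0
    attempts = 0
    while len(offsets) < b.n_fibers and attempts < 10000:
        attempts += 1
        r = r_max * math.sqrt(rng.uniform())
        t = rng.uniform(0, 2 * math.pi)
        p = (r * math.cos(t), r * math.sin(t))
        if all(math.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in offsets):
            offsets.append(p)
    if len(offsets) < b.n_fibers:
        raise ValueError(
            f"cannot place {b.n_fibers} fibers of radius {b.fiber_radius_px} "
            f"inside fascicle radius {b.fascicle_radius_px}"
        )
    return np.asarray(offsets)


def fiber_trajectories(spec: PhantomSpec):
    """All fiber centers: (n_total, depth, 2) px, plus per-fiber roi labels."""
    paths, labels = [], []
    drift = np.outer(np.arange(spec.depth), np.asarray(spec.drift_per_slice, float))
    for b in spec.bundles:
        if b.fiber_paths is not None:
            fp = np.asarray(b.fiber_paths, dtype=np.float64)
            if fp.shape[1] != spec.depth:
                raise ValueError("fiber_paths depth does not match spec depth")
        else:
            cl = _centerline(b, spec)
            off = _fiber_offsets(b, spec.rng_seed)
            fp = cl[None, :, :] + off[:, None, :]
        fp = fp + drift[None, :, :]
        paths.append(fp)
        labels.extend([b.roi_label] * fp.shape[0])
    return np.concatenate(paths, axis=0), np.asarray(labels)


def _validate(spec: PhantomSpec, paths: np.ndarray) -> None:
    rmax = max(b.fiber_radius_px for b in spec.bundles)
    if (
        (paths[..., 0] - rmax < 0).any()
        or (paths[..., 0] + rmax > spec.width - 1).any()
        or (paths[..., 1] - rmax < 0).any()
        or (paths[..., 1] + rmax > spec.height - 1).any()
    ):
        raise ValueError("fiber trajectories leave the image bounds")
    # fascicles must not overlap at the seed slice
    for i, a in enumerate(spec.bundles):
        pa = _bundle_center_at(a, spec, 0)
        for b in spec.bundles[i + 1 :]:
            pb = _bundle_center_at(b, spec, 0)
            if math.hypot(pa[0] - pb[0], pa[1] - pb[1]) < (
                a.fascicle_radius_px + b.fascicle_radius_px
            ):
                raise ValueError(
                    f"fascicles {a.roi_label} and {b.roi_label} overlap at the seed slice"
                )


def _bundle_center_at(b: BundleSpec, spec: PhantomSpec, z: int):
    if b.fiber_paths is not None and b.fiber_paths.shape[0] > 0:
        return np.asarray(b.fiber_paths, float)[:, z, :].mean(axis=0)
    return _centerline(b, spec)[z]


def _paint_disks(shape, centers, radius, values=None):
    """Anti-aliased disk coverage image (float in [0, 1]) or label image.

    Coverage per pixel is clip(radius + 0.5 - distance_to_center, 0, 1),
    maxed over disks; with ``values`` a hard label image (distance <=
    radius) is produced instead, later disks winning ties.
    """
    h, w = shape
    if values is None:
        out = np.zeros(shape, dtype=np.float64)
    else:
        out = np.zeros(shape, dtype=np.int32)
    r_int = int(math.ceil(radius)) + 1
    for k, (cx, cy) in enumerate(centers):
        x0, x1 = int(math.floor(cx)) - r_int, int(math.floor(cx)) + r_int + 1
        y0, y1 = int(math.floor(cy)) - r_int, int(math.floor(cy)) + r_int + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        if values is None:
            cov = np.clip(radius + 0.5 - d, 0.0, 1.0)
            out[y0:y1, x0:x1] = np.maximum(out[y0:y1, x0:x1], cov)
        else:
            out[y0:y1, x0:x1] = np.where(d <= radius, values[k], out[y0:y1, x0:x1])
    return out


def _link_clusters(centers: np.ndarray, link_px: float):
    """Single-linkage clusters of fiber centers (indices), threshold link_px."""
    n = len(centers)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if math.hypot(*(centers[i] - centers[j])) <= link_px:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [np.asarray(g) for g in groups.values()]


def _outline_hull(shape, centers, radius) -> np.ndarray:
    """Convex outline around a cluster of fiber disks (manual-tracing model)."""
    from skimage.morphology import convex_hull_image

    disks = _paint_disks(shape, centers, radius, values=np.ones(len(centers))) > 0
    if len(centers) <= 1:
        return disks
    return convex_hull_image(disks)


def render_slice(spec: PhantomSpec, z: int, paths: np.ndarray | None = None) -> np.ndarray:
    """Render one slice as uint8 (deterministic per slice)."""
    if paths is None:
        paths, _ = fiber_trajectories(spec)
    radius = spec.bundles[0].fiber_radius_px
    cov = np.zeros((spec.height, spec.width))
    start = 0
    for b in spec.bundles:
        n = b.fiber_paths.shape[0] if b.fiber_paths is not None else b.n_fibers
        cov = np.maximum(
            cov,
            _paint_disks(
                (spec.height, spec.width), paths[start : start + n, z], b.fiber_radius_px
            ),
        )
        start += n
    img = spec.background + (spec.fiber_brightness - spec.background) * cov
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.rng_seed, z])
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    if spec.invert:
        img = 255.0 - img
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


@dataclass
class Phantom:
    """In-memory phantom: stack, masks and analytic ground truth."""

    spec: PhantomSpec
    stack: ArrayStack
    seed_mask: np.ndarray  # labelled (gray value = ROI) on slice 0
    fascicle_masks: MaskStack
    fiber_masks: MaskStack  # ground-truth fiber-group labels
    truth: Tractogram
    paths: np.ndarray = dc_field(repr=False, default=None)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Materialize a phantom in memory (see :func:`render_phantom` to write)."""
    paths, labels = fiber_trajectories(spec)
    _validate(spec, paths)
    meta = spec.meta
    shape = (spec.height, spec.width)

    volume = np.stack([render_slice(spec, z, paths) for z in range(spec.depth)])

    # ground-truth fiber-group masks: each ROI's fibers outlined as a group,
    # emulating manual tracing — a closed contour (convex outline) around
    # each visually coherent cluster of the group's fibers
    radius = spec.bundles[0].fiber_radius_px
    fiber_labels = np.zeros((spec.depth,) + shape, dtype=np.int32)
    rois = sorted({int(l) for l in labels})
    for z in range(spec.depth):
        for roi in rois:
            centers = paths[labels == roi, z]
            for cluster in _link_clusters(centers, spec.group_link_px):
                blob = _outline_hull(shape, centers[cluster], radius)
                fiber_labels[z] = np.where(
                    blob & (fiber_labels[z] == 0), roi, fiber_labels[z]
                )
    # fascicle masks: fascicle disks around bundle centers plus a corridor
    # around every fiber so migrating groups stay anatomically enclosed
    fasc = np.zeros((spec.depth,) + shape, dtype=np.int32)
    for z in range(spec.depth):
        centers = [_bundle_center_at(b, spec, z) for b in spec.bundles]
        vals = [b.roi_label for b in spec.bundles]
        radii = [b.fascicle_radius_px for b in spec.bundles]
        lab = np.zeros(shape, dtype=np.int32)
        for c, v, r in zip(centers, vals, radii):
            lab = np.where(_paint_disks(shape, [c], r, values=[v]) > 0, v, lab)
        corridor = _paint_disks(shape, paths[:, z], radius + 2.0, values=labels)
        fasc[z] = np.where(lab > 0, lab, corridor)

    # seeds are placed on the bright fiber cross-sections themselves
    seed_mask = _paint_disks(shape, paths[:, 0], radius, values=labels).astype(np.uint8)

    px, th = spec.pixel_size_xy, spec.slice_thickness
    streamlines = [
        Streamline(
            points=np.column_stack(
                [
                    paths[i, :, 0] * px,
                    paths[i, :, 1] * px,
                    np.arange(spec.depth) * th,
                ]
            ),
            roi_label=int(labels[i]),
            termination_reason=REACHED_END,
        )
        for i in range(paths.shape[0])
    ]
    truth = Tractogram(
        streamlines=streamlines,
        meta=meta,
        provenance={
            "algorithm": "ground-truth",
            "rng_seed": spec.rng_seed,
            "stack_shape": [spec.depth, spec.height, spec.width],
        },
    )
    return Phantom(
        spec=spec,
        stack=ArrayStack(volume, meta),
        seed_mask=seed_mask,
        fascicle_masks=MaskStack(fasc, meta),
        fiber_masks=MaskStack(fiber_labels, meta),
        truth=truth,
        paths=paths,
    )


def render_phantom(spec: PhantomSpec, out_dir) -> Phantom:
    """Build the phantom and write all artifacts under ``out_dir``.

    Layout: ``slices/slice_0000.png ...``, ``meta.xml``, ``seed_mask.png``
    (gray value = ROI label), ``fascicle_masks/``, ``fiber_masks/`` and
    ``ground_truth.jsonl``.  Writing is deterministic in the spec.
    """
    from .tracking import write_tractogram_jsonl

    out = Path(out_dir)
    ph = build_phantom(spec)
    for sub in ("slices", "fascicle_masks", "fiber_masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for z in range(spec.depth):
        Image.fromarray(ph.stack.get_slice(z)).save(out / "slices" / f"slice_{z:04d}.png")
        Image.fromarray(ph.fascicle_masks.labels[z].astype(np.uint8)).save(
            out / "fascicle_masks" / f"mask_{z:04d}.png"
        )
        Image.fromarray(ph.fiber_masks.labels[z].astype(np.uint8)).save(
            out / "fiber_masks" / f"mask_{z:04d}.png"
        )
    Image.fromarray(ph.seed_mask).save(out / "seed_mask.png")
    write_metadata(spec.meta, out / "meta.xml")
    write_tractogram_jsonl(ph.truth, out / "ground_truth.jsonl")
    return ph


def disk_mask(shape, center, radius) -> np.ndarray:
    """Binary disk mask (row/col grid, center given as (x, y) px)."""
    return _paint_disks(shape, [center], radius, values=[1]).astype(bool)


# ---------------------------------------------------------------------------
# scene presets


def make_straight_scene(
    depth: int = 100,
    n_fascicles: int = 2,
    size: int = 200,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    **spec_kwargs,
) -> PhantomSpec:
    """Independent straight fascicles running exactly along z."""
    centers = _ring_centers(n_fascicles, size)
    bundles = [
        BundleSpec(roi_label=i + 1, center=c, n_fibers=6, fascicle_radius_px=16.0)
        for i, c in enumerate(centers)
    ]
    return PhantomSpec(
        width=size, height=size, depth=depth, bundles=bundles,
        noise_sigma=noise_sigma, rng_seed=rng_seed, **spec_kwargs,
    )


def make_tilted_scene(
    angle_deg: float,
    depth: int = 40,
    size: int = 160,
    azimuth_deg: float = 0.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    **spec_kwargs,
) -> PhantomSpec:
    """One fascicle tilted ``angle_deg`` from z (drift along ``azimuth_deg``)."""
    spec_kwargs.setdefault("pixel_size_xy", DEFAULT_PIXEL_SIZE)
    spec_kwargs.setdefault("slice_thickness", DEFAULT_SLICE_THICKNESS)
    drift = (
        math.tan(math.radians(angle_deg))
        * spec_kwargs["slice_thickness"]
        / spec_kwargs["pixel_size_xy"]
    )
    total = drift * (depth - 1)
    start = (size / 2 - total * math.cos(math.radians(azimuth_deg)) / 2,
             size / 2 - total * math.sin(math.radians(azimuth_deg)) / 2)
    bundle = BundleSpec(
        roi_label=1, center=start, kind="tilted",
        angle_deg=angle_deg, azimuth_deg=azimuth_deg,
        n_fibers=6, fascicle_radius_px=16.0,
    )
    return PhantomSpec(
        width=size, height=size, depth=depth, bundles=[bundle],
        noise_sigma=noise_sigma, rng_seed=rng_seed, **spec_kwargs,
    )


def make_helix_scene(
    radius_px: float = 12.0,
    pitch_slices: float = 80.0,
    depth: int = 80,
    size: int = 160,
    rng_seed: int = 0,
    **spec_kwargs,
) -> PhantomSpec:
    bundle = BundleSpec(
        roi_label=1, center=(size / 2 + radius_px, size / 2), kind="helical",
        helix_radius_px=radius_px, helix_pitch_slices=pitch_slices,
        n_fibers=4, fascicle_radius_px=12.0,
    )
    return PhantomSpec(
        width=size, height=size, depth=depth, bundles=[bundle],
        rng_seed=rng_seed, **spec_kwargs,
    )


def make_texture_scene(
    depth: int = 60,
    size: int = 256,
    n_fibers: int = 160,
    drift_per_slice: tuple = (0.0, 0.0),
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    **spec_kwargs,
) -> PhantomSpec:
    """Fibers scattered over the whole field (one ROI): a dense texture for
    exercising windowed flow estimation and uniform-drift recovery."""
    rng = np.random.default_rng(rng_seed)
    margin = 12 + abs(drift_per_slice[0]) * depth + abs(drift_per_slice[1]) * depth
    offsets = np.column_stack(
        [
            rng.uniform(margin, size - margin, n_fibers),
            rng.uniform(margin, size - margin, n_fibers),
        ]
    ) - size / 2
    bundle = BundleSpec(
        roi_label=1, center=(size / 2, size / 2), n_fibers=n_fibers,
        fiber_radius_px=2.5, fascicle_radius_px=size / 2, offsets=offsets,
    )
    return PhantomSpec(
        width=size, height=size, depth=depth, bundles=[bundle],
        drift_per_slice=drift_per_slice, noise_sigma=noise_sigma,
        rng_seed=rng_seed, **spec_kwargs,
    )


def _ring_centers(n: int, size: int, radius_frac: float = 0.32):
    if n == 1:
        return [(size / 2, size / 2)]
    r = size * radius_frac
    return [
        (size / 2 + r * math.cos(2 * math.pi * k / n + math.pi / n),
         size / 2 + r * math.sin(2 * math.pi * k / n + math.pi / n))
        for k in range(n)
    ]


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_split_merge_scene(
    depth: int = 112,
    n_fascicles: int = 4,
    size: int = 280,
    fibers_per_fascicle: int = 6,
    migrate_fraction: float = 1.0,
    migration_angle_deg: float = 20.0,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
    **spec_kwargs,
) -> PhantomSpec:
    """Fiber groups from ``n_fascicles`` source fascicles merge into one.

    Each source fascicle sits on a ring; a ``migrate_fraction`` of its
    fibers travels to its own landing sector of a central target fascicle
    along a smoothstep trajectory whose peak slope respects
    ``migration_angle_deg`` (must not exceed 45 deg, keeping well inside
    the 75 deg tracking envelope; real merge events drift at shallow
    angles over extended depths, so the default is gentle).  Migrations
    are staggered in z so that, by the last slice, the central fascicle
    holds fibers from every source ROI.  Groups keep their internal spread
    while migrating, so each ROI's cross-sectional area is constant — the
    assumption under which Dice values are comparable across slices.
    ``migrate_fraction=0`` reduces to independent straight bundles.
    """
    if n_fascicles < 2:
        raise ValueError("need at least 2 fascicles")
    if migration_angle_deg > MAX_MIGRATION_ANGLE_DEG:
        raise ValueError(
            f"migration angle {migration_angle_deg} deg exceeds the "
            f"{MAX_MIGRATION_ANGLE_DEG} deg smooth-trajectory bound"
        )
    spec_kwargs.setdefault("pixel_size_xy", DEFAULT_PIXEL_SIZE)
    spec_kwargs.setdefault("slice_thickness", DEFAULT_SLICE_THICKNESS)
    px = spec_kwargs["pixel_size_xy"]
    th = spec_kwargs["slice_thickness"]
    slope_max = math.tan(math.radians(migration_angle_deg)) * th / px  # px/slice

    centers = _ring_centers(n_fascicles, size, radius_frac=0.30)
    target = np.array([size / 2, size / 2])
    sector_radius = 22.0
    fasc_r = 16.0
    bundles = []
    z_axis = np.arange(depth, dtype=float)
    for k, c in enumerate(centers):
        b = BundleSpec(
            roi_label=k + 1, center=c, n_fibers=fibers_per_fascicle,
            fascicle_radius_px=fasc_r,
        )
        offsets = _fiber_offsets(b, rng_seed)
        n_migrate = int(round(migrate_fraction * fibers_per_fascicle))
        # landing sector: same azimuth as the source, inside the target fascicle
        az = math.atan2(c[1] - target[1], c[0] - target[0])
        sector = target + sector_radius * np.array([math.cos(az), math.sin(az)])
        src = np.asarray(c, float)
        dist = float(np.linalg.norm(sector - src))
        duration = max(2, math.ceil(1.5 * dist / slope_max))  # smoothstep peak slope
        z_start = 6 + k * 8
        z_end = z_start + duration
        if z_end > depth - 2:
            raise ValueError(
                f"migration of fascicle {k + 1} needs slices up to {z_end} "
                f"but the stack has {depth}; increase depth or the angle"
            )
        s = _smoothstep((z_axis - z_start) / duration)[None, :, None]
        base = src[None, None, :] + offsets[:, None, :]
        shift = (sector - src)[None, None, :]
        paths = base + np.where(
            np.arange(fibers_per_fascicle)[:, None, None] < n_migrate, s * shift, 0.0
        )
        b.fiber_paths = paths
        bundles.append(b)

    # the central target fascicle: no fibers of its own, mask region only
    bundles.append(
        BundleSpec(
            roi_label=n_fascicles + 1, center=tuple(target), n_fibers=0,
            fascicle_radius_px=sector_radius + fasc_r + 2,
            fiber_paths=np.zeros((0, depth, 2)),
        )
    )
    return PhantomSpec(
        width=size, height=size, depth=depth, bundles=bundles,
        noise_sigma=noise_sigma, rng_seed=rng_seed, **spec_kwargs,
    )
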