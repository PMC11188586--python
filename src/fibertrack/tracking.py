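"""Streamline propagation, anatomical constraints, and tractogram editing.

Seeds advance one slice plane per step in either direction along the stack.
In optic-flow mode the in-plane displacement is sampled from the per-slice-
pair Lucas-Kanade field by bilinear interpolation; in structure-tensor mode
the per-voxel orientation vector is sampled by nearest neighbor, sign-aligned
to the tracking direction and scaled so the z step equals the slice
thickness.  Tracking stops when the step diverges from the stack axis (the
anatomical long axis of a transversely sectioned nerve) by more than the
termination angle, when the point leaves the image, or when the local flow
is undefined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from matplotlib.path import Path as MplPath
from PIL import Image
from scipy import ndimage

from . import flow_optic, flow_tensor
from .seeding import SeedSet, label_rois, sample_seeds
from .stack_io import SliceStack, StackMeta

__all__ = [
    "Streamline",
    "Tractogram",
    "MaskStack",
    "OpticFlowTracker",
    "TensorTracker",
    "propagate",
    "constrain_to_mask",
    "edit_delete",
    "edit_create",
    "write_tractogram_jsonl",
    "read_tractogram_jsonl",
    "write_tractogram_trk",
]

DEFAULT_MAX_ANGLE_DEG = 75.0
#: tensor mode bridges at most this many consecutive invalid voxels by
#: reusing the previous step direction
MAX_INVALID_BRIDGE = 2

REACHED_END = "reached_end"
ANGLE_EXCEEDED = "angle_exceeded"
LEFT_IMAGE = "left_image"
LEFT_FASCICLE_MASK = "left_fascicle_mask"
INVALID_FLOW = "invalid_flow"


@dataclass
class Streamline:
    """Ordered (x, y, z) points in micrometres, one per crossed slice plane."""

    points: np.ndarray  # (N, 3) float
    roi_label: int
    termination_reason: str

    def __len__(self) -> int:
        return len(self.points)


def _roi_color(label: int) -> str:
    """Deterministic categorical color for an ROI label (hex)."""
    rgba = colormaps["tab20"](int(label) % 20)
    return "#{:02x}{:02x}{:02x}".format(*(int(round(255 * c)) for c in rgba[:3]))


@dataclass
class Tractogram:
    """A collection of streamlines plus the provenance to regenerate them."""

    streamlines: list
    meta: StackMeta
    provenance: dict = field(default_factory=dict)
    colors: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.streamlines)

    def __post_init__(self):
        for s in self.streamlines:
            self.colors.setdefault(int(s.roi_label), _roi_color(s.roi_label))

    def roi_labels(self):
        return sorted({int(s.roi_label) for s in self.streamlines})

    def with_streamlines(self, streamlines, extra_provenance=None) -> "Tractogram":
        prov = dict(self.provenance)
        if extra_provenance:
            prov.setdefault("edits", []).append(extra_provenance)
        return Tractogram(
            streamlines=list(streamlines),
            meta=self.meta,
            provenance=prov,
            colors=dict(self.colors),
        )


class MaskStack:
    """Per-slice label images aligned to a stack (fascicles or fiber groups)."""

    def __init__(self, labels: np.ndarray, meta: StackMeta):
        labels = np.asarray(labels)
        if labels.ndim != 3:
            raise ValueError("MaskStack expects a (z, y, x) label array")
        self.labels = labels
        self.meta = meta

    @property
    def depth(self) -> int:
        return self.labels.shape[0]

    @property
    def shape(self):
        return self.labels.shape[1:]

    @classmethod
    def from_directory(cls, directory, meta: StackMeta) -> "MaskStack":
        files = sorted(Path(directory).glob("*.png"))
        if not files:
            raise ValueError(f"no mask PNGs in {directory}")
        labels = np.stack([np.asarray(Image.open(f)) for f in files])
        return cls(labels, meta)

    def get_slice(self, z: int) -> np.ndarray:
        return self.labels[z]


class OpticFlowTracker:
    """Per-slice-pair pyramidal Lucas-Kanade flow provider.

    Computes (and caches the most recent) dense flow field between
    consecutive slices on demand; tracking advances front-by-front so each
    field is computed exactly once per run.
    """

    kind = "optic-flow"

    def __init__(
        self,
        stack: SliceStack,
        window: int = flow_optic.DEFAULT_WINDOW,
        levels: int = flow_optic.DEFAULT_LEVELS,
        blur_sigma: float = flow_optic.DEFAULT_BLUR_SIGMA,
    ):
        self.stack = stack
        self.window = window
        self.levels = levels
        self.blur_sigma = blur_sigma
        self._cache = {}

    @property
    def meta(self) -> StackMeta:
        return self.stack.meta

    @property
    def shape(self):
        return self.stack.shape

    @property
    def depth(self) -> int:
        return self.stack.depth

    def params(self) -> dict:
        return {
            "algorithm": self.kind,
            "window": self.window,
            "levels": self.levels,
            "blur_sigma": self.blur_sigma,
        }

    def flow(self, z: int, dz: int) -> flow_optic.FlowField:
        """Flow field from slice z to slice z + dz (dz in {+1, -1})."""
        key = (z, dz)
        if key not in self._cache:
            f = flow_optic.pyramidal_flow(
                self.stack.get_slice(z),
                self.stack.get_slice(z + dz),
                window=self.window,
                levels=self.levels,
                blur_sigma=self.blur_sigma,
            )
            self._cache = {key: f}  # keep only the current front's field
        return self._cache[key]

    def step(self, x, y, z, dz):
        """Vectorized step for positions (x, y) um on slice plane z.

        Returns (dx_um, dy_um, dz_um, ok) arrays; ok False where the flow
        is invalid at the sampled location.
        """
        px = self.meta.pixel_size_xy
        f = self.flow(z, dz)
        rows = np.asarray(y) / px
        cols = np.asarray(x) / px
        vx = ndimage.map_coordinates(f.Vx, [rows, cols], order=1, mode="nearest")
        vy = ndimage.map_coordinates(f.Vy, [rows, cols], order=1, mode="nearest")
        ok = (
            ndimage.map_coordinates(
                f.valid.astype(np.float64), [rows, cols], order=0, mode="nearest"
            )
            > 0.5
        )
        dz_um = dz * self.meta.slice_thickness
        return vx * px, vy * px, np.full_like(vx, dz_um), ok


class TensorTracker:
    """Structure-tensor orientation provider over the whole stack.

    The orientation field is computed once (chunked, on the isotropized
    grid) and sampled by nearest neighbor in physical coordinates.
    """

    kind = "structure-tensor"

    def __init__(
        self,
        stack: SliceStack,
        noise_scale: float = flow_tensor.DEFAULT_NOISE_SCALE,
        neighborhood_scale: float = flow_tensor.DEFAULT_NEIGHBORHOOD_SCALE,
        step_size: int | None = None,
        isotropize: bool = True,
        orientation: flow_tensor.OrientationField | None = None,
    ):
        self.stack = stack
        self.noise_scale = noise_scale
        self.neighborhood_scale = neighborhood_scale
        self.step_size = step_size if step_size is not None else stack.meta.step_size
        if orientation is None:
            grid = flow_tensor.isotropize(stack) if isotropize else stack
            orientation = flow_tensor.orientation_field_chunked(
                grid,
                noise_scale=noise_scale,
                neighborhood_scale=neighborhood_scale,
                step_size=self.step_size,
            )
        self.orientation = orientation

    @property
    def meta(self) -> StackMeta:
        return self.stack.meta

    @property
    def shape(self):
        return self.stack.shape

    @property
    def depth(self) -> int:
        return self.stack.depth

    def params(self) -> dict:
        return {
            "algorithm": self.kind,
            "noise_scale": self.noise_scale,
            "neighborhood_scale": self.neighborhood_scale,
            "step_size": self.step_size,
        }

    def step(self, x, y, z, dz):
        """Vectorized step: orientation sampled nearest-neighbor, scaled so
        |dz_um| equals the slice thickness."""
        ori = self.orientation
        px_t = ori.pixel_size_xy
        th = self.meta.slice_thickness
        nz, ny, nx = ori.valid.shape
        rows = np.clip(np.rint(np.asarray(y) / px_t).astype(int), 0, ny - 1)
        cols = np.clip(np.rint(np.asarray(x) / px_t).astype(int), 0, nx - 1)
        zi = np.clip(np.full(rows.shape, z, dtype=int), 0, nz - 1)
        u = ori.u[zi, rows, cols]  # (N, 3), voxel units of the orientation grid
        ok = ori.valid[zi, rows, cols]
        # physical direction on the orientation grid
        d = u * np.array([px_t, px_t, ori.slice_thickness])
        # sign-align to the tracking direction
        sgn = np.where(d[:, 2] * dz < 0, -1.0, 1.0)
        d = d * sgn[:, None]
        absdz = np.abs(d[:, 2])
        # |uz| ~ 0 means a ~90 deg step: keep ok, let the angle rule stop it
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = th / absdz
        scale = np.where(absdz < 1e-12, np.inf, scale)
        dx = d[:, 0] * scale
        dy = d[:, 1] * scale
        dz_um = np.full(dx.shape, dz * th)
        return dx, dy, dz_um, ok


def propagate(
    seeds: SeedSet,
    flow_provider,
    direction: str = "forward",
    max_angle_deg: float = DEFAULT_MAX_ANGLE_DEG,
) -> Tractogram:
    """Propagate every seed through the stack and return the tractogram.

    ``direction`` is "forward" (+z) or "backward" (-z).  A step whose angle
    to the z-axis exceeds ``max_angle_deg`` terminates the streamline
    without emitting the offending point.  In tensor mode, up to
    ``MAX_INVALID_BRIDGE`` consecutive invalid voxels are bridged by
    reusing the previous step direction.
    """
    if not 0 < max_angle_deg < 90:
        raise ValueError("max_angle_deg must be in (0, 90)")
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    dz = 1 if direction == "forward" else -1
    meta = flow_provider.meta
    px, th = meta.pixel_size_xy, meta.slice_thickness
    h, w = flow_provider.shape
    depth = flow_provider.depth
    z0 = seeds.seed_slice_index
    tan_max = math.tan(math.radians(max_angle_deg))
    tensor_mode = flow_provider.kind == "structure-tensor"

    n = len(seeds)
    x = seeds.points[:, 1].astype(np.float64) * px
    y = seeds.points[:, 0].astype(np.float64) * px
    points = [[(xi, yi, z0 * th)] for xi, yi in zip(x, y)]
    reasons = [None] * n
    last_step = np.zeros((n, 3))
    has_last = np.zeros(n, dtype=bool)
    invalid_run = np.zeros(n, dtype=int)
    alive = np.ones(n, dtype=bool)

    zi = z0
    while alive.any():
        if not 0 <= zi + dz < depth:
            for i in np.flatnonzero(alive):
                reasons[i] = REACHED_END
            break
        idx = np.flatnonzero(alive)
        dx, dy, dzu, ok = flow_provider.step(x[idx], y[idx], zi, dz)

        if tensor_mode:
            # bridge isolated invalid voxels with the previous direction
            bridge = ~ok & has_last[idx] & (invalid_run[idx] < MAX_INVALID_BRIDGE)
            bi = np.flatnonzero(bridge)
            if bi.size:
                dx[bi] = last_step[idx[bi], 0]
                dy[bi] = last_step[idx[bi], 1]
                dzu[bi] = last_step[idx[bi], 2]
            invalid_run[idx[~ok & bridge]] += 1
            invalid_run[idx[ok]] = 0
            dead = ~ok & ~bridge
        else:
            dead = ~ok
        for i in idx[dead]:
            reasons[i] = INVALID_FLOW
        alive[idx[dead]] = False
        keep = ~dead
        idx, dx, dy, dzu = idx[keep], dx[keep], dy[keep], dzu[keep]

        # termination angle relative to the stack (nerve long) axis
        steep = np.hypot(dx, dy) > tan_max * np.abs(dzu)
        for i in idx[steep]:
            reasons[i] = ANGLE_EXCEEDED
        alive[idx[steep]] = False
        idx, dx, dy, dzu = idx[~steep], dx[~steep], dy[~steep], dzu[~steep]

        nx_ = x[idx] + dx
        ny_ = y[idx] + dy
        out = (nx_ < 0) | (nx_ > (w - 1) * px) | (ny_ < 0) | (ny_ > (h - 1) * px)
        for i in idx[out]:
            reasons[i] = LEFT_IMAGE
        alive[idx[out]] = False
        idx, nx_, ny_ = idx[~out], nx_[~out], ny_[~out]
        dx, dy, dzu = dx[~out], dy[~out], dzu[~out]

        x[idx], y[idx] = nx_, ny_
        zi += dz
        for k, i in enumerate(idx):
            points[i].append((nx_[k], ny_[k], zi * th))
        last_step[idx] = np.column_stack([dx, dy, dzu])
        has_last[idx] = True

    streamlines = [
        Streamline(
            points=np.asarray(points[i]),
            roi_label=int(seeds.roi_labels[i]),
            termination_reason=reasons[i],
        )
        for i in range(n)
    ]
    provenance = {
        "direction": direction,
        "max_angle_deg": max_angle_deg,
        "seed_slice_index": z0,
        "density": seeds.density,
        "rng_seed": seeds.rng_seed,
        "n_seeds": n,
        "stack_shape": [depth, h, w],
        "pixel_size_xy": px,
        "slice_thickness": th,
        **flow_provider.params(),
    }
    return Tractogram(streamlines=streamlines, meta=meta, provenance=provenance)


def _point_slice_indices(s: Streamline, slice_thickness: float) -> np.ndarray:
    return np.rint(s.points[:, 2] / slice_thickness).astype(int)


def constrain_to_mask(tract: Tractogram, masks: MaskStack, mode: str = "truncate") -> Tractogram:
    """Anatomically constrain a tractogram to fascicle masks.

    ``truncate`` cuts each streamline at its last consecutive in-mask point
    counted from the seed (termination reason ``left_fascicle_mask``);
    ``remove`` deletes any streamline with at least one out-of-mask point.
    """
    if mode not in ("truncate", "remove"):
        raise ValueError(f"mode must be 'truncate' or 'remove', got {mode!r}")
    px = tract.meta.pixel_size_xy
    th = tract.meta.slice_thickness
    h, w = masks.shape
    kept = []
    for s in tract.streamlines:
        zi = _point_slice_indices(s, th)
        if zi.min() < 0 or zi.max() >= masks.depth:
            raise ValueError("tractogram extends beyond the mask stack depth")
        rows = np.clip(np.rint(s.points[:, 1] / px).astype(int), 0, h - 1)
        cols = np.clip(np.rint(s.points[:, 0] / px).astype(int), 0, w - 1)
        inside = masks.labels[zi, rows, cols] > 0
        if inside.all():
            kept.append(s)
            continue
        if mode == "remove":
            continue
        n_keep = int(np.argmin(inside))  # first out-of-mask point
        if n_keep == 0:
            continue  # seed itself outside: nothing survives
        kept.append(
            Streamline(
                points=s.points[:n_keep].copy(),
                roi_label=s.roi_label,
                termination_reason=LEFT_FASCICLE_MASK,
            )
        )
    return tract.with_streamlines(kept, {"op": "constrain_to_mask", "mode": mode})


def _points_at_slice(s: Streamline, z: int, slice_thickness: float) -> np.ndarray:
    zi = _point_slice_indices(s, slice_thickness)
    return s.points[zi == z]


def edit_delete(tract: Tractogram, polygon, z: int) -> Tractogram:
    """Delete streamlines whose point on slice ``z`` falls inside ``polygon``.

    The polygon is an (M, 2) sequence of (x, y) vertices in pixel
    coordinates on slice z.  Returns the edited tractogram; the number of
    removed streamlines is recorded in provenance.
    """
    depth = tract.provenance.get("stack_shape", [None])[0]
    if depth is not None and not 0 <= z < depth:
        raise ValueError(f"slice index {z} outside the stack")
    poly = np.asarray(polygon, dtype=float)
    px = tract.meta.pixel_size_xy
    kept = []
    removed = 0
    path = MplPath(poly) if len(poly) >= 3 else None
    for s in tract.streamlines:
        pts = _points_at_slice(s, z, tract.meta.slice_thickness)
        hit = False
        if path is not None and len(pts):
            hit = bool(path.contains_points(pts[:, :2] / px).any())
        if hit:
            removed += 1
        else:
            kept.append(s)
    return tract.with_streamlines(
        kept, {"op": "edit_delete", "z": z, "removed": removed}
    )


def edit_create(
    tract: Tractogram,
    polygon,
    z: int,
    density: float,
    rng_seed: int,
    flow_provider,
    direction: str = "forward",
    max_angle_deg: float = DEFAULT_MAX_ANGLE_DEG,
) -> Tractogram:
    """Seed new streamlines inside ``polygon`` on slice ``z`` and append them.

    The polygon is rasterized to a mask, seeded and propagated with the
    same machinery as the initial run; new streamlines get a fresh ROI
    label (max existing + 1).
    """
    from skimage.draw import polygon2mask

    poly = np.asarray(polygon, dtype=float)
    if len(poly) < 3:
        return tract.with_streamlines(tract.streamlines, {"op": "edit_create", "added": 0})
    h, w = flow_provider.shape
    # polygon2mask expects (row, col) vertex order
    mask = polygon2mask((h, w), poly[:, ::-1])
    if not mask.any():
        return tract.with_streamlines(tract.streamlines, {"op": "edit_create", "added": 0})
    labels = label_rois(mask)
    seeds = sample_seeds(labels, density, rng_seed, z)
    new = propagate(seeds, flow_provider, direction, max_angle_deg)
    fresh = (max(tract.roi_labels()) if len(tract) else 0) + 1
    relabelled = [
        Streamline(points=s.points, roi_label=fresh + (s.roi_label - 1),
                   termination_reason=s.termination_reason)
        for s in new.streamlines
    ]
    return tract.with_streamlines(
        list(tract.streamlines) + relabelled,
        {"op": "edit_create", "z": z, "added": len(relabelled)},
    )


# ---------------------------------------------------------------------------
# tractogram I/O


def write_tractogram_jsonl(tract: Tractogram, path) -> None:
    """Write a tractogram as JSON lines (bit-exact round trip).

    Line 1 is a header with provenance, calibration, and ROI colors; each
    further line is one streamline: roi_label, termination_reason, points
    as (x, y, z) triplets in micrometres.
    """
    with open(path, "w") as fh:
        header = {
            "type": "fibertrack-tractogram",
            "version": 1,
            "pixel_size_xy": tract.meta.pixel_size_xy,
            "slice_thickness": tract.meta.slice_thickness,
            "image_type": tract.meta.image_type,
            "num_images_to_read": tract.meta.num_images_to_read,
            "step_size": tract.meta.step_size,
            "provenance": tract.provenance,
            "colors": {str(k): v for k, v in tract.colors.items()},
        }
        fh.write(json.dumps(header) + "\n")
        for s in tract.streamlines:
            rec = {
                "roi_label": int(s.roi_label),
                "termination_reason": s.termination_reason,
                "points": [[float(v) for v in p] for p in s.points],
            }
            fh.write(json.dumps(rec) + "\n")


def read_tractogram_jsonl(path) -> Tractogram:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("type") != "fibertrack-tractogram":
            raise ValueError(f"{path} is not a fibertrack tractogram file")
        meta = StackMeta(
            pixel_size_xy=header["pixel_size_xy"],
            slice_thickness=header["slice_thickness"],
            image_type=header["image_type"],
            num_images_to_read=header["num_images_to_read"],
            step_size=header["step_size"],
        )
        streamlines = []
        for line in fh:
            rec = json.loads(line)
            streamlines.append(
                Streamline(
                    points=np.asarray(rec["points"], dtype=np.float64),
                    roi_label=int(rec["roi_label"]),
                    termination_reason=rec["termination_reason"],
                )
            )
    return Tractogram(
        streamlines=streamlines,
        meta=meta,
        provenance=header["provenance"],
        colors={int(k): v for k, v in header["colors"].items()},
    )


def write_tractogram_trk(tract: Tractogram, path) -> None:
    """Export to TrackVis .trk (via nibabel) for viewing in diffusion tools.

    Coordinates are written in micrometres; the header carries the voxel
    size and stack dimensions from the metadata.
    """
    import nibabel as nib

    px, th = tract.meta.pixel_size_xy, tract.meta.slice_thickness
    depth, h, w = tract.provenance.get("stack_shape", [1, 1, 1])
    header = {
        "voxel_sizes": (px, px, th),
        "dimensions": (w, h, depth),
        "voxel_order": "RAS",
    }
    t = nib.streamlines.Tractogram(
        [s.points for s in tract.streamlines], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(t, str(path), header=header)
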