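"""Deterministic seed-point sampling from a region-of-interest mask.

Tracking is initialized from a user mask on one slice.  Connected
components of the mask are the ROIs (typically one per fascicle); within
each ROI a fixed fraction of pixels is selected by a seeded permutation so
that repeated runs — and runs with different algorithm parameters — start
from exactly the same coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["SeedSet", "label_rois", "sample_seeds", "seeds_from_mask"]

#: default sampling density: 1 seed per 100 foreground pixels
DEFAULT_DENSITY = 0.01

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class SeedSet:
    """ROI-labelled seed coordinates on one slice.

    ``points[i] = (row, col)`` lies in the foreground of component
    ``roi_labels[i]``.  Regenerating with identical mask, density and
    rng_seed reproduces the identical ordered list.
    """

    points: np.ndarray  # (N, 2) int, (row, col)
    roi_labels: np.ndarray  # (N,) int
    seed_slice_index: int
    density: float
    rng_seed: int
    label_values: dict = field(default_factory=dict)  # roi label -> source mask value

    def __len__(self) -> int:
        return len(self.points)


def label_rois(mask: np.ndarray) -> np.ndarray:
    """Label connected components of a binary mask (8-connectivity).

    Components are numbered 1..K in order of their first pixel in a
    row-major scan, so labelling is reproducible across library versions.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("seed mask has no foreground pixels")
    raw, k = ndimage.label(mask, structure=_EIGHT_CONN)
    flat = raw.ravel()
    first = {}
    order = []
    for lab in flat[flat > 0]:
        if lab not in first:
            first[lab] = True
            order.append(lab)
    remap = np.zeros(k + 1, dtype=raw.dtype)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return remap[raw]


def sample_seeds(labels: np.ndarray, density: float, rng_seed: int, z0: int) -> SeedSet:
    """Sample seeds from a label image.

    For each component, pixels are enumerated in row-major order, permuted
    by a generator re-seeded per component with ``rng_seed + label`` (so
    editing one ROI never perturbs the seeds of the others), and the first
    ``max(1, floor(count * density))`` are taken.
    """
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    labels = np.asarray(labels)
    pts, labs = [], []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        coords = np.argwhere(labels == lab)  # row-major order
        n_take = max(1, math.floor(len(coords) * density))
        rng = np.random.default_rng(int(rng_seed) + int(lab))
        perm = rng.permutation(len(coords))
        chosen = coords[perm[:n_take]]
        pts.append(chosen)
        labs.append(np.full(n_take, lab, dtype=int))
    return SeedSet(
        points=np.concatenate(pts, axis=0),
        roi_labels=np.concatenate(labs),
        seed_slice_index=int(z0),
        density=float(density),
        rng_seed=int(rng_seed),
    )


def seeds_from_mask(
    mask: np.ndarray,
    density: float = DEFAULT_DENSITY,
    rng_seed: int = 0,
    z0: int = 0,
    mask_is_labelled: bool = False,
) -> SeedSet:
    """Convenience wrapper: label a mask (unless pre-labelled) and sample.

    With ``mask_is_labelled`` every distinct nonzero gray value is treated
    as its own ROI instead of running connected components.
    """
    mask = np.asarray(mask)
    labels = mask.astype(int) if mask_is_labelled else label_rois(mask)
    if mask_is_labelled and not (labels > 0).any():
        raise ValueError("seed mask has no foreground pixels")
    ss = sample_seeds(labels, density, rng_seed, z0)
    ss.label_values = {int(l): int(l) for l in np.unique(ss.roi_labels)}
    return ss
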