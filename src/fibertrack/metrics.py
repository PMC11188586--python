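"""Tractogram evaluation metrics.

Accuracy against ground truth: a tractogram restricted to one slice is a 2D
point cloud; rounding each point to its nearest pixel gives a binary mask
that can be compared with a ground-truth fiber-group mask by the Dice
coefficient.  Because a denser seeding trivially raises raw Dice, values are
normalized by the Dice at the seeding slice (Dice_norm).

Similarity between tractograms: both are simplified by QuickBundles-style
incremental clustering under the minimum-direct-flip (MDF) streamline
distance, and the symmetrized mean closest-neighbor distance between the
cluster centroids (restricted to matching ROIs) is reported (MCN_dist, um).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tracking import MaskStack, Streamline, Tractogram

__all__ = [
    "rasterize_tract_slice",
    "dice",
    "dice_norm",
    "resample_streamline",
    "quickbundles",
    "ClusterSet",
    "mcn_dist",
]

DEFAULT_CLUSTER_THRESHOLD_UM = 50.0
DEFAULT_RESAMPLE_POINTS = 12


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def _points_at_slice(tract: Tractogram, z: int, roi_label: int) -> np.ndarray:
    th = tract.meta.slice_thickness
    pts = []
    for s in tract.streamlines:
        if s.roi_label != roi_label:
            continue
        zi = np.rint(s.points[:, 2] / th).astype(int)
        pts.append(s.points[zi == z, :2])
    return np.concatenate(pts) if pts else np.empty((0, 2))


def rasterize_tract_slice(
    tract: Tractogram, z: int, roi_label: int, shape: tuple
) -> np.ndarray:
    """Binary mask of one ROI's streamline points on slice ``z``.

    Each point present on the slice sets its nearest pixel; points rounding
    to the same pixel coincide (the mask is a set).
    """
    if roi_label not in tract.roi_labels():
        raise ValueError(f"unknown roi_label {roi_label}")
    px = tract.meta.pixel_size_xy
    mask = np.zeros(shape, dtype=bool)
    pts = _points_at_slice(tract, z, roi_label)
    if len(pts):
        cols = np.rint(pts[:, 0] / px).astype(int)
        rows = np.rint(pts[:, 1] / px).astype(int)
        keep = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
        mask[rows[keep], cols[keep]] = True
    return mask


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A|+|B|); undefined (error) when both empty."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa == 0 and sb == 0:
        raise UndefinedMetricError("Dice is undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (sa + sb)


def dice_norm(
    tract: Tractogram, gt: MaskStack, roi_label: int, z: int, z0: int
) -> float:
    """Dice at slice ``z`` normalized by Dice at the seeding slice ``z0``.

    Ground-truth foreground for the ROI is ``gt == roi_label`` when the
    label appears in the mask stack, otherwise any foreground (binary
    ground truth).
    """
    shape = gt.shape

    def gt_mask(zz):
        sl = gt.get_slice(zz)
        return sl == roi_label if (sl == roi_label).any() else sl > 0

    d0 = dice(rasterize_tract_slice(tract, z0, roi_label, shape), gt_mask(z0))
    if d0 == 0:
        raise UndefinedMetricError(
            f"Dice at the seeding slice z0={z0} is zero; Dice_norm undefined"
        )
    dz = dice(rasterize_tract_slice(tract, z, roi_label, shape), gt_mask(z))
    return dz / d0


def resample_streamline(s: Streamline, K: int) -> Streamline:
    """Resample to ``K`` arc-length-uniform points (linear interpolation).

    Endpoints are preserved exactly.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    pts = np.asarray(s.points, dtype=np.float64)
    if len(pts) < 2:
        raise ValueError("cannot resample a single-point streamline")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        new = np.repeat(pts[:1], K, axis=0)
    else:
        t = np.linspace(0.0, total, K)
        new = np.column_stack([np.interp(t, arc, pts[:, i]) for i in range(3)])
        new[0], new[-1] = pts[0], pts[-1]
    return Streamline(points=new, roi_label=s.roi_label,
                      termination_reason=s.termination_reason)


def mdf(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum direct-flip distance between two equal-length polylines (um)."""
    a = np.asarray(a)
    b = np.asarray(b)
    direct = np.linalg.norm(a - b, axis=1).mean()
    flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
    return float(min(direct, flipped))


@dataclass
class _Cluster:
    total: np.ndarray  # running sum of flip-aligned member point arrays
    n: int
    roi_label: int

    @property
    def centroid(self) -> np.ndarray:
        return self.total / self.n


@dataclass
class ClusterSet:
    """Result of streamline clustering: per-cluster centroids and members."""

    centroids: list  # (K, 3) arrays
    roi_labels: list
    members: list  # list of lists of input streamline indices
    threshold_um: float
    resample_points: int

    def __len__(self) -> int:
        return len(self.centroids)


def quickbundles(
    tract: Tractogram,
    threshold_um: float = DEFAULT_CLUSTER_THRESHOLD_UM,
    K: int = DEFAULT_RESAMPLE_POINTS,
) -> ClusterSet:
    """Incremental streamline clustering under the MDF distance.

    Streamlines are processed in stored order (clustering is order-
    dependent by construction; provenance fixes the order).  Each is
    resampled to ``K`` points and joins the nearest existing cluster of its
    own ROI if the MDF distance to that cluster's centroid is within the
    threshold, otherwise it opens a new cluster.  Centroids are running
    means of flip-aligned member arrays.  Streamlines too short to resample
    (single point) are skipped.
    """
    if threshold_um <= 0:
        raise ValueError("threshold must be > 0")
    clusters: list[_Cluster] = []
    members: list[list[int]] = []
    for i, s in enumerate(tract.streamlines):
        if len(s.points) < 2:
            continue
        pts = resample_streamline(s, K).points
        best, best_d = None, np.inf
        for ci, c in enumerate(clusters):
            if c.roi_label != s.roi_label:
                continue
            d = mdf(pts, c.centroid)
            if d < best_d:
                best, best_d = ci, d
        if best is not None and best_d <= threshold_um:
            c = clusters[best]
            cen = c.centroid
            if np.linalg.norm(pts - cen, axis=1).mean() > np.linalg.norm(
                pts[::-1] - cen, axis=1
            ).mean():
                pts = pts[::-1]
            c.total = c.total + pts
            c.n += 1
            members[best].append(i)
        else:
            clusters.append(_Cluster(total=pts.copy(), n=1, roi_label=s.roi_label))
            members.append([i])
    return ClusterSet(
        centroids=[c.centroid for c in clusters],
        roi_labels=[c.roi_label for c in clusters],
        members=members,
        threshold_um=threshold_um,
        resample_points=K,
    )


def _directed_mean_closest(ca: ClusterSet, cb: ClusterSet, shared) -> float:
    dists = []
    for cen, lab in zip(ca.centroids, ca.roi_labels):
        if lab not in shared:
            continue
        best = min(
            mdf(cen, other)
            for other, lab_b in zip(cb.centroids, cb.roi_labels)
            if lab_b == lab
        )
        dists.append(best)
    return float(np.mean(dists))


def mcn_dist(
    tract_a: Tractogram,
    tract_b: Tractogram,
    threshold_um: float = DEFAULT_CLUSTER_THRESHOLD_UM,
    K: int = DEFAULT_RESAMPLE_POINTS,
) -> float:
    """Mean closest-neighbor distance between two tractograms (um).

    Both tractograms are clustered; each centroid of A records the MDF
    distance to its closest same-ROI centroid of B, the mean is taken, the
    computation is repeated from B to A, and the two means are averaged.
    ROIs present in only one tractogram are skipped with a warning.
    """
    ca = quickbundles(tract_a, threshold_um, K)
    cb = quickbundles(tract_b, threshold_um, K)
    la, lb = set(ca.roi_labels), set(cb.roi_labels)
    shared = la & lb
    if not shared:
        raise ValueError("tractograms share no ROI labels; MCN_dist undefined")
    skipped = (la | lb) - shared
    if skipped:
        warnings.warn(f"ROIs present in only one tractogram skipped: {sorted(skipped)}")
    return 0.5 * (
        _directed_mean_closest(ca, cb, shared) + _directed_mean_closest(cb, ca, shared)
    )
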