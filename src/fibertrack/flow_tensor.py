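"""3D structure-tensor orientation estimation.

The local fiber direction at a voxel is the displacement ``u`` that changes
image intensity least over a neighborhood: the minimizer of
``D(u) = sum_{p' in N(p)} (V(p'+u) - V(p'))^2``.  To second order this is
the quadratic form ``u^T J u`` with the structure tensor
``J = sum_{p' in N(p)} w(p') (grad V)(grad V)^T``, and the minimizing unit
vector is the eigenvector of J with the smallest eigenvalue.

Gradients are Gaussian derivatives at the *noise scale* sigma_n; the
neighborhood sum is realized as Gaussian smoothing of the gradient outer
products at the *neighborhood scale* sigma_nb (a soft window, standard
structure-tensor practice).  All Gaussian kernels are truncated at 3 sigma
so that processing the stack in overlapping chunks of ``step_size`` slices
(overlap ``ceil(3*(sigma_n + sigma_nb))`` per side) is bit-identical to a
single full-volume pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack_io import SliceStack, downsample_stack

__all__ = [
    "StructureTensorField",
    "OrientationField",
    "isotropize",
    "structure_tensor_chunk",
    "principal_orientation",
    "orientation_field_chunked",
    "chunk_margin",
]

DEFAULT_NOISE_SCALE = 1.0  # sigma_n, pixels
DEFAULT_NEIGHBORHOOD_SCALE = 5.0  # sigma_nb, pixels
DEFAULT_STEP_SIZE = 64  # slices per chunk
#: Gaussian kernels cut at 3 sigma (keeps the chunk-overlap contract exact)
GAUSS_TRUNCATE = 3.0
#: voxels whose tensor trace falls below this are direction-less (validity
#: False); 1e-2 corresponds to gradient magnitudes around 0.1 gray level,
#: far below the quantization noise of 8-bit data
TRACE_EPS = 1e-2
#: relative tolerance for "two smallest eigenvalues equal" degeneracy
EIG_TIE_RTOL = 1e-9

# component order of the packed symmetric tensor
_COMPS = ("xx", "xy", "xz", "yy", "yz", "zz")


@dataclass
class StructureTensorField:
    """Packed symmetric 3x3 tensor per voxel: (6, z, y, x) array.

    Component order: Jxx, Jxy, Jxz, Jyy, Jyz, Jzz.
    """

    J: np.ndarray
    noise_scale: float
    neighborhood_scale: float

    def as_matrices(self) -> np.ndarray:
        """Return a (..., 3, 3) array of full symmetric matrices."""
        xx, xy, xz, yy, yz, zz = self.J
        M = np.empty(xx.shape + (3, 3))
        M[..., 0, 0] = xx
        M[..., 0, 1] = M[..., 1, 0] = xy
        M[..., 0, 2] = M[..., 2, 0] = xz
        M[..., 1, 1] = yy
        M[..., 1, 2] = M[..., 2, 1] = yz
        M[..., 2, 2] = zz
        return M


@dataclass
class OrientationField:
    """Per-voxel unit fiber orientation u = (ux, uy, uz), uz >= 0.

    ``u`` has shape (z, y, x, 3), components in voxel units of the grid the
    field was computed on (see ``pixel_size_xy`` / ``slice_thickness`` for
    the physical calibration of that grid).  ``valid`` is False where the
    direction is undefined (flat intensity or degenerate eigenvalues).
    """

    u: np.ndarray
    valid: np.ndarray
    noise_scale: float
    neighborhood_scale: float
    pixel_size_xy: float = 1.0
    slice_thickness: float = 1.0


def isotropize(stack: SliceStack, min_factor: int = 2) -> SliceStack:
    """Downsample in XY to make voxels near-isotropic.

    Block-face stacks are usually finer in-plane than across slices (e.g.
    0.9 um pixels at 3 um slice spacing).  The structure tensor assumes
    comparable sampling in all axes, so XY is reduced by the integer factor
    closest to ``slice_thickness / pixel_size_xy``.  A factor below
    ``min_factor`` is a no-op.
    """
    factor = round(stack.meta.slice_thickness / stack.meta.pixel_size_xy)
    if factor < min_factor:
        return stack
    return downsample_stack(stack, xy_factor=factor, z_keep_every=1)


def _gaussian(vol, sigma, order=0):
    return ndimage.gaussian_filter(
        vol, sigma, order=order, mode="reflect", truncate=GAUSS_TRUNCATE
    )


def min_chunk_depth(neighborhood_scale: float) -> int:
    return 2 * math.ceil(3 * neighborhood_scale) + 3


def structure_tensor_chunk(
    volume: np.ndarray,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    neighborhood_scale: float = DEFAULT_NEIGHBORHOOD_SCALE,
) -> StructureTensorField:
    """Compute the structure tensor of a (z, y, x) volume.

    Gradients Vx, Vy, Vz are Gaussian derivatives at ``noise_scale``; the
    six products are then smoothed componentwise at ``neighborhood_scale``
    (reflect boundaries).
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("expected a (z, y, x) volume")
    need = min_chunk_depth(neighborhood_scale)
    if vol.shape[0] < need:
        raise ValueError(
            f"volume depth {vol.shape[0]} too thin for neighborhood scale "
            f"{neighborhood_scale}; need >= {need} slices"
        )
    # axis order (z, y, x): derivative order tuples select the axis
    Vz = _gaussian(vol, noise_scale, order=(1, 0, 0))
    Vy = _gaussian(vol, noise_scale, order=(0, 1, 0))
    Vx = _gaussian(vol, noise_scale, order=(0, 0, 1))

    J = np.empty((6,) + vol.shape)
    grads = {"x": Vx, "y": Vy, "z": Vz}
    for i, comp in enumerate(_COMPS):
        J[i] = _gaussian(grads[comp[0]] * grads[comp[1]], neighborhood_scale)
    return StructureTensorField(
        J=J, noise_scale=noise_scale, neighborhood_scale=neighborhood_scale
    )


def _canonical_sign(u: np.ndarray) -> np.ndarray:
    """Flip eigenvectors so uz > 0 (ties: uy > 0, then ux > 0)."""
    ux, uy, uz = u[..., 0], u[..., 1], u[..., 2]
    flip = (uz < 0) | ((uz == 0) & ((uy < 0) | ((uy == 0) & (ux < 0))))
    return np.where(flip[..., None], -u, u)


def principal_orientation(tensor: StructureTensorField) -> OrientationField:
    """Extract the minimal-variation direction from a tensor field.

    Per voxel the eigenvector of the smallest eigenvalue is taken, sign
    fixed so uz >= 0.  Voxels with trace below ``TRACE_EPS`` (no contrast)
    or with the two smallest eigenvalues tied (direction ambiguous, e.g.
    isotropic neighborhoods) are marked invalid with u = (0, 0, 1).
    """
    M = tensor.as_matrices()
    w, v = np.linalg.eigh(M)  # ascending eigenvalues
    u = _canonical_sign(v[..., :, 0])

    trace = M[..., 0, 0] + M[..., 1, 1] + M[..., 2, 2]
    tie = (w[..., 1] - w[..., 0]) <= EIG_TIE_RTOL * np.maximum(trace, TRACE_EPS)
    valid = (trace >= TRACE_EPS) & ~tie
    u = np.where(valid[..., None], u, np.array([0.0, 0.0, 1.0]))
    return OrientationField(
        u=u,
        valid=valid,
        noise_scale=tensor.noise_scale,
        neighborhood_scale=tensor.neighborhood_scale,
    )


def chunk_margin(noise_scale: float, neighborhood_scale: float) -> int:
    """Slices of overlap needed per chunk side: ceil(3*(sigma_n + sigma_nb)).

    With kernels truncated at 3 sigma, the gradient filter reaches
    ``int(3*sigma_n + 0.5)`` slices and the tensor smoothing a further
    ``int(3*sigma_nb + 0.5)``; the margin covers both, making chunk
    interiors bit-identical to a full-volume pass.
    """
    radius = int(GAUSS_TRUNCATE * noise_scale + 0.5) + int(
        GAUSS_TRUNCATE * neighborhood_scale + 0.5
    )
    return max(math.ceil(3 * (noise_scale + neighborhood_scale)), radius)


def orientation_field_chunked(
    stack: SliceStack,
    noise_scale: float = DEFAULT_NOISE_SCALE,
    neighborhood_scale: float = DEFAULT_NEIGHBORHOOD_SCALE,
    step_size: int = DEFAULT_STEP_SIZE,
) -> OrientationField:
    """Orientation field of a whole stack, processed ``step_size`` slices at
    a time with overlap margins so the result is independent of chunking.

    Falls back to a single chunk (with a warning) when the stack is too
    shallow for the requested step plus margins.
    """
    if step_size < 1:
        raise ValueError("step_size must be >= 1")
    depth = stack.depth
    margin = chunk_margin(noise_scale, neighborhood_scale)
    if step_size >= depth or depth < min_chunk_depth(neighborhood_scale) + 1:
        step_size = depth
    elif step_size + 2 * margin > depth:
        warnings.warn(
            f"step_size {step_size} + margins {2 * margin} exceed stack depth "
            f"{depth}; falling back to single-chunk processing"
        )
        step_size = depth

    h, w = stack.shape
    u = np.empty((depth, h, w, 3))
    valid = np.empty((depth, h, w), dtype=bool)
    for start in range(0, depth, step_size):
        stop = min(start + step_size, depth)
        lo = max(0, start - margin)
        hi = min(depth, stop + margin)
        # extra context never changes interior voxels; take enough to satisfy
        # the filter-support minimum even for clipped end chunks
        need = min_chunk_depth(neighborhood_scale)
        while hi - lo < need and (lo > 0 or hi < depth):
            hi = min(depth, hi + (need - (hi - lo)))
            lo = max(0, lo - (need - (hi - lo)))
        vol = stack.volume(lo, hi)
        # pad-by-clipping never shrinks a chunk below the filter support
        J = structure_tensor_chunk(vol, noise_scale, neighborhood_scale)
        ori = principal_orientation(J)
        u[start:stop] = ori.u[start - lo : stop - lo]
        valid[start:stop] = ori.valid[start - lo : stop - lo]
    return OrientationField(
        u=u,
        valid=valid,
        noise_scale=noise_scale,
        neighborhood_scale=neighborhood_scale,
        pixel_size_xy=stack.meta.pixel_size_xy,
        slice_thickness=stack.meta.slice_thickness,
    )
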