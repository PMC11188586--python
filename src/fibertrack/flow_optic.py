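"""Dense Lucas-Kanade optic flow between consecutive slices.

Consecutive block-face slices are treated as video frames: under brightness
constancy and small displacement, the intensity gradients satisfy
``Ix*Vx + Iy*Vy = -Iz`` at every pixel.  Assuming the flow constant over an
n x n window yields an overdetermined linear system solved in least squares
through the 2x2 normal equations.  A coarse-to-fine pyramid (factor 2 per
level) extends the valid displacement range beyond the window size.

Flow is computed densely at every pixel so that streamline propagation can
interpolate displacements at arbitrary sub-pixel positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "GradientTriple",
    "FlowField",
    "compute_gradients",
    "lucas_kanade",
    "pyramidal_flow",
]

DEFAULT_WINDOW = 50  # pixels; even values are incremented to center the window
DEFAULT_LEVELS = 2
DEFAULT_BLUR_SIGMA = 2.0
#: validity threshold: smaller eigenvalue of the normal matrix must exceed
#: EIG_EPS * window_area, making the rule scale-invariant in window size
EIG_EPS = 1e-4


@dataclass
class GradientTriple:
    """Spatial (Ix, Iy) and inter-slice (Iz) derivatives after blurring."""

    Ix: np.ndarray
    Iy: np.ndarray
    Iz: np.ndarray


@dataclass
class FlowField:
    """Per-pixel displacement (pixels; x = columns, y = rows) slice z -> z+1.

    ``valid`` is False where the windowed normal matrix is near-singular
    (aperture problem); there Vx = Vy = 0.
    """

    Vx: np.ndarray
    Vy: np.ndarray
    valid: np.ndarray
    window: int = DEFAULT_WINDOW
    levels: int = DEFAULT_LEVELS
    blur_sigma: float = DEFAULT_BLUR_SIGMA


def compute_gradients(slice_a, slice_b, blur_sigma: float = DEFAULT_BLUR_SIGMA) -> GradientTriple:
    """Blur both slices (Gaussian, reflect boundary), then differentiate.

    Ix, Iy are central differences of the blurred first slice; Iz is the
    blurred difference (second minus first).
    """
    a = np.asarray(slice_a, dtype=np.float64)
    b = np.asarray(slice_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"slice shapes differ: {a.shape} vs {b.shape}")
    if blur_sigma > 0:
        a = ndimage.gaussian_filter(a, blur_sigma, mode="reflect")
        b = ndimage.gaussian_filter(b, blur_sigma, mode="reflect")
    Iy, Ix = np.gradient(a)  # rows = y, cols = x
    return GradientTriple(Ix=Ix, Iy=Iy, Iz=b - a)


def _odd_window(n: int) -> int:
    if n < 3:
        raise ValueError(f"window must be >= 3 pixels, got {n}")
    return n if n % 2 == 1 else n + 1


def lucas_kanade(gradients: GradientTriple, window: int = DEFAULT_WINDOW) -> FlowField:
    """Solve the windowed least-squares flow at every pixel.

    The n x n window sums of gradient products form the 2x2 normal matrix
    ``[[Sxx, Sxy], [Sxy, Syy]]`` and right-hand side ``-[Sxz, Syz]``.
    Pixels whose smaller eigenvalue falls below ``EIG_EPS * n**2`` are
    flagged invalid (flow set to zero).
    """
    n = _odd_window(window)
    Ix, Iy, Iz = gradients.Ix, gradients.Iy, gradients.Iz

    def wsum(img):
        # uniform_filter computes the window mean; scale back to the sum
        return ndimage.uniform_filter(img, size=n, mode="reflect") * (n * n)

    Sxx = wsum(Ix * Ix)
    Sxy = wsum(Ix * Iy)
    Syy = wsum(Iy * Iy)
    Sxz = wsum(Ix * Iz)
    Syz = wsum(Iy * Iz)

    half_tr = 0.5 * (Sxx + Syy)
    disc = np.sqrt(np.maximum(0.25 * (Sxx - Syy) ** 2 + Sxy**2, 0.0))
    lam_min = half_tr - disc
    valid = lam_min >= EIG_EPS * n * n

    det = Sxx * Syy - Sxy * Sxy
    with np.errstate(divide="ignore", invalid="ignore"):
        Vx = (-Syy * Sxz + Sxy * Syz) / det
        Vy = (Sxy * Sxz - Sxx * Syz) / det
    Vx = np.where(valid, Vx, 0.0)
    Vy = np.where(valid, Vy, 0.0)
    return FlowField(Vx=Vx, Vy=Vy, valid=valid, window=n, levels=1)


def _pyr_down(img: np.ndarray) -> np.ndarray:
    """Factor-2 reduction by 2x2 block averaging (odd trailing edge dropped)."""
    h, w = img.shape
    h2, w2 = h // 2, w // 2
    return img[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def _upsample_flow(v: np.ndarray, shape) -> np.ndarray:
    zoom = (shape[0] / v.shape[0], shape[1] / v.shape[1])
    return ndimage.zoom(v, zoom, order=1, mode="nearest", grid_mode=True)


def _warp(img: np.ndarray, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """Sample ``img`` at (row + vy, col + vx), bilinear, replicated borders."""
    rows, cols = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(np.float64)
    return ndimage.map_coordinates(
        img, [rows + vy, cols + vx], order=1, mode="nearest"
    )


def pyramidal_flow(
    slice_a,
    slice_b,
    window: int = DEFAULT_WINDOW,
    levels: int = DEFAULT_LEVELS,
    blur_sigma: float = DEFAULT_BLUR_SIGMA,
) -> FlowField:
    """Coarse-to-fine Lucas-Kanade flow from slice_a to slice_b.

    At each level the current estimate (upsampled and doubled from the
    coarser level) warps slice_b toward slice_a; the residual flow is then
    re-estimated and accumulated.  ``levels=1`` reduces exactly to
    single-level :func:`lucas_kanade`.  Levels whose coarsest image would be
    smaller than twice the window are dropped with a warning.
    """
    import warnings

    a = np.asarray(slice_a, dtype=np.float64)
    b = np.asarray(slice_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"slice shapes differ: {a.shape} vs {b.shape}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = _odd_window(window)

    max_levels = 1
    h, w = a.shape
    while max_levels < levels and min(h, w) // 2 >= 2 * n:
        h, w = h // 2, w // 2
        max_levels += 1
    if max_levels < levels:
        warnings.warn(
            f"pyramid reduced from {levels} to {max_levels} level(s): "
            f"coarsest image must keep >= {2 * n} px per side"
        )
        levels = max_levels

    pyr_a, pyr_b = [a], [b]
    for _ in range(levels - 1):
        pyr_a.append(_pyr_down(pyr_a[-1]))
        pyr_b.append(_pyr_down(pyr_b[-1]))

    vx = np.zeros_like(pyr_a[-1])
    vy = np.zeros_like(pyr_a[-1])
    valid = np.ones(pyr_a[-1].shape, dtype=bool)
    for lev in range(levels - 1, -1, -1):
        al, bl = pyr_a[lev], pyr_b[lev]
        if vx.shape != al.shape:
            vx = 2.0 * _upsample_flow(vx, al.shape)
            vy = 2.0 * _upsample_flow(vy, al.shape)
        bw = _warp(bl, vx, vy) if (lev < levels - 1) else bl
        grads = compute_gradients(al, bw, blur_sigma)
        res = lucas_kanade(grads, n)
        vx = vx + res.Vx
        vy = vy + res.Vy
        valid = res.valid
    return FlowField(Vx=vx, Vy=vy, valid=valid, window=n, levels=levels, blur_sigma=blur_sigma)
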