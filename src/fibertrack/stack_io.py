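"""Reading serial block-face image stacks.

A stack is a directory of single-slice PNG images (lexicographic filename
order = ascending z) plus an XML metadata file carrying the physical
calibration.  Stacks routinely exceed RAM, so slices are decoded lazily
through :class:`VirtualStack` with a small bounded cache.

Conventions used throughout the package:

* a slice is a 2D ``uint8`` array indexed ``[row, col]`` = ``[y, x]``;
* a volume is indexed ``[z, y, x]``;
* physical coordinates are micrometres with ``x = col * pixel_size_xy``,
  ``y = row * pixel_size_xy``, ``z = slice_index * slice_thickness``.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from collections import OrderedDict
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "StackMeta",
    "MetadataError",
    "StackError",
    "VirtualStack",
    "ArrayStack",
    "load_metadata",
    "write_metadata",
    "open_stack",
    "to_grayscale",
    "gamma_correct",
    "downsample_stack",
]

#: number of decoded slices kept resident per stack
DEFAULT_CACHE_SLICES = 8

_META_FIELDS = (
    "pixel_size_xy",
    "image_slice_thickness",
    "image_type",
    "num_images_to_read",
    "step_size",
)


class MetadataError(ValueError):
    """Raised when the stack metadata file is missing or malformed."""


class StackError(ValueError):
    """Raised when the slice directory violates the stack contract."""


@dataclass(frozen=True)
class StackMeta:
    """Physical and processing calibration of an image stack.

    Parameters
    ----------
    pixel_size_xy : float
        In-plane size of one pixel, in micrometres.
    slice_thickness : float
        Distance between consecutive slices, in micrometres.
    image_type : str
        File suffix of the slice images (e.g. ``".png"``).
    num_images_to_read : int
        Number of slices to load; must not exceed the files present.
    step_size : int
        Slices per processing chunk for the structure-tensor analysis.
    """

    pixel_size_xy: float
    slice_thickness: float
    image_type: str
    num_images_to_read: int
    step_size: int

    def __post_init__(self):
        if self.pixel_size_xy <= 0:
            raise MetadataError("pixel_size_xy must be > 0")
        if self.slice_thickness <= 0:
            raise MetadataError("image_slice_thickness must be > 0")
        if self.num_images_to_read < 2:
            raise MetadataError("num_images_to_read must be >= 2")
        if self.step_size < 1:
            raise MetadataError("step_size must be >= 1")


def load_metadata(xml_path) -> StackMeta:
    """Parse a stack metadata XML file.

    The dialect stores every value in a ``name`` attribute of a child
    element of the root, e.g. ``<pixel_size_xy name="0.9"/>``.  Unknown
    extra elements are ignored.
    """
    xml_path = Path(xml_path)
    if not xml_path.exists():
        raise MetadataError(f"metadata file not found: {xml_path}")
    try:
        root = ET.parse(xml_path).getroot()
    except ET.ParseError as exc:
        raise MetadataError(f"malformed XML in {xml_path}: {exc}") from exc

    values = {}
    for child in root:
        if child.tag in _META_FIELDS and "name" in child.attrib:
            values[child.tag] = child.attrib["name"]
    missing = [f for f in _META_FIELDS if f not in values]
    if missing:
        raise MetadataError(f"metadata missing field(s): {', '.join(missing)}")

    def _num(field, caster):
        try:
            return caster(values[field])
        except ValueError as exc:
            raise MetadataError(
                f"field {field} is not numeric: {values[field]!r}"
            ) from exc

    return StackMeta(
        pixel_size_xy=_num("pixel_size_xy", float),
        slice_thickness=_num("image_slice_thickness", float),
        image_type=values["image_type"],
        num_images_to_read=_num("num_images_to_read", int),
        step_size=_num("step_size", int),
    )


def write_metadata(meta: StackMeta, xml_path) -> None:
    """Write ``meta`` in the same XML dialect that :func:`load_metadata` reads."""

    def _fmt(v):
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    root = ET.Element("root")
    ET.SubElement(root, "pixel_size_xy", name=_fmt(meta.pixel_size_xy))
    ET.SubElement(root, "image_slice_thickness", name=_fmt(meta.slice_thickness))
    ET.SubElement(root, "image_type", name=meta.image_type)
    ET.SubElement(root, "num_images_to_read", name=str(meta.num_images_to_read))
    ET.SubElement(root, "step_size", name=str(meta.step_size))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(xml_path, xml_declaration=True, encoding="unicode")


class SliceStack:
    """Common interface of lazily-evaluated slice stacks."""

    meta: StackMeta
    shape: tuple  # (height, width) of one slice

    @property
    def depth(self) -> int:
        return self.meta.num_images_to_read

    def get_slice(self, z: int) -> np.ndarray:
        raise NotImplementedError

    def volume(self, z0: int = 0, z1: int | None = None) -> np.ndarray:
        """Materialize slices ``z0..z1`` as a (z, y, x) float64 volume."""
        if z1 is None:
            z1 = self.depth
        return np.stack(
            [np.asarray(self.get_slice(z), dtype=np.float64) for z in range(z0, z1)]
        )


class VirtualStack(SliceStack):
    """Lazy PNG stack reader with a bounded decoded-slice cache.

    Slice order is the ascending lexicographic order of filenames.  Repeated
    reads of a slice return bit-identical pixel data; mutating the returned
    array does not corrupt the cache (a copy is handed out).
    """

    def __init__(self, directory, meta: StackMeta, cache_slices: int = DEFAULT_CACHE_SLICES):
        directory = Path(directory)
        files = sorted(p for p in directory.iterdir() if p.suffix == meta.image_type)
        if not files:
            raise StackError(f"no {meta.image_type} slices found in {directory}")
        if meta.num_images_to_read > len(files):
            raise StackError(
                f"num_images_to_read={meta.num_images_to_read} but only "
                f"{len(files)} {meta.image_type} files present in {directory}"
            )
        self.directory = directory
        self.files = files[: meta.num_images_to_read]
        self.meta = meta
        self._cache: OrderedDict[int, np.ndarray] = OrderedDict()
        self._cache_slices = max(1, cache_slices)
        self.peak_cache_occupancy = 0

        # header-only dimension check (no full decode)
        with Image.open(self.files[0]) as im:
            w, h = im.size
        self.shape = (h, w)
        for f in self.files[1:]:
            with Image.open(f) as im:
                if im.size != (w, h):
                    raise StackError(
                        f"slice {f.name} has size {im.size[::-1]}, expected {(h, w)}"
                    )

    def get_slice(self, z: int) -> np.ndarray:
        if not 0 <= z < self.depth:
            raise IndexError(f"slice index {z} outside [0, {self.depth})")
        if z in self._cache:
            self._cache.move_to_end(z)
            return self._cache[z].copy()
        arr = np.asarray(Image.open(self.files[z]))
        if arr.ndim == 3:
            arr = to_grayscale(arr)
        while len(self._cache) >= self._cache_slices:
            self._cache.popitem(last=False)
        self._cache[z] = arr
        self.peak_cache_occupancy = max(self.peak_cache_occupancy, len(self._cache))
        return arr.copy()


class ArrayStack(SliceStack):
    """In-memory stack over a (z, y, x) array, sharing the lazy interface."""

    def __init__(self, data: np.ndarray, meta: StackMeta):
        data = np.asarray(data)
        if data.ndim != 3:
            raise StackError("ArrayStack expects a (z, y, x) array")
        if meta.num_images_to_read > data.shape[0]:
            raise StackError("num_images_to_read exceeds array depth")
        self._data = data
        self.meta = meta
        self.shape = data.shape[1:]

    def get_slice(self, z: int) -> np.ndarray:
        if not 0 <= z < self.depth:
            raise IndexError(f"slice index {z} outside [0, {self.depth})")
        return self._data[z].copy()


def open_stack(directory, meta: StackMeta, cache_slices: int = DEFAULT_CACHE_SLICES) -> VirtualStack:
    """Open a slice directory as a :class:`VirtualStack`."""
    return VirtualStack(directory, meta, cache_slices=cache_slices)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB slice to grayscale as 0.5*R + 0.5*G (blue ignored).

    The 50:50 red/green weighting matches the fluorescent + absorptive
    staining contrast of block-face microscopy, where the blue channel
    carries little signal.  Grayscale input passes through unchanged.
    Rounding is half-up, clipped to [0, 255].
    """
    img = np.asarray(img)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[2] < 3:
        raise StackError(f"expected RGB image, got shape {img.shape}")
    g = 0.5 * img[..., 0].astype(np.float64) + 0.5 * img[..., 1].astype(np.float64)
    return np.clip(_round_half_up(g), 0, 255).astype(np.uint8)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Apply gamma correction ``out = round(255 * (in/255)**gamma)``."""
    if gamma <= 0:
        raise ValueError(f"gamma must be > 0, got {gamma}")
    x = np.asarray(img, dtype=np.float64) / 255.0
    return np.clip(_round_half_up(255.0 * np.power(x, gamma)), 0, 255).astype(np.uint8)


class _DownsampledStack(SliceStack):
    """Lazy view of a parent stack, z-subsampled and XY block-averaged."""

    def __init__(self, parent: SliceStack, xy_factor: int, z_keep_every: int):
        depth = (parent.depth + z_keep_every - 1) // z_keep_every
        if depth < 2:
            raise StackError(
                f"z_keep_every={z_keep_every} leaves {depth} slice(s); need >= 2"
            )
        h, w = parent.shape
        self.parent = parent
        self.xy_factor = xy_factor
        self.z_keep_every = z_keep_every
        self.shape = (h // xy_factor, w // xy_factor)
        if min(self.shape) < 1:
            raise StackError("xy_factor larger than the image")
        self.meta = replace(
            parent.meta,
            pixel_size_xy=parent.meta.pixel_size_xy * xy_factor,
            slice_thickness=parent.meta.slice_thickness * z_keep_every,
            num_images_to_read=depth,
        )

    def get_slice(self, z: int) -> np.ndarray:
        if not 0 <= z < self.depth:
            raise IndexError(f"slice index {z} outside [0, {self.depth})")
        sl = self.parent.get_slice(z * self.z_keep_every)
        f = self.xy_factor
        if f == 1:
            return sl
        h, w = self.shape
        blocks = sl[: h * f, : w * f].astype(np.float64).reshape(h, f, w, f)
        return np.clip(_round_half_up(blocks.mean(axis=(1, 3))), 0, 255).astype(np.uint8)


def downsample_stack(stack: SliceStack, xy_factor: int = 1, z_keep_every: int = 1) -> SliceStack:
    """Produce a downsampled lazy view of ``stack``.

    Slices with index ``z % z_keep_every == 0`` are retained; in-plane
    resolution is reduced by ``xy_factor`` using block averaging (any
    trailing rows/columns that do not fill a block are dropped).  Metadata
    is rescaled so physical calibration stays correct.
    """
    if xy_factor < 1 or z_keep_every < 1:
        raise ValueError("downsampling factors must be positive integers")
    if xy_factor == 1 and z_keep_every == 1:
        return stack
    return _DownsampledStack(stack, xy_factor, z_keep_every)
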