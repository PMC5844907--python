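"""Reading and writing Z-ordered TIFF image series.

A stack is a folder of single-channel 8- or 16-bit TIFF files, one file per
Z plane, consumed in lexicographic filename order (zero-padded names are
therefore required for numeric ordering).  Multi-page TIFFs are accepted as
an alternative input, with pages taken as planes; output is always one file
per plane.  Alongside the corrected series the tool can persist per-plane
tissue masks ("support images") and a plain-text quantile log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

logger = logging.getLogger("intensify3d")

_ALLOWED_DTYPES = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass
class ImageStack:
    """An ordered sequence of same-shaped 2D intensity planes.

    Pixel values are analog-to-digital units (ADU); ``bit_depth`` records the
    integer range of the source files.  Planes may be held as floats during
    processing — conversion back to integers happens only on write.
    """

    planes: list[np.ndarray]
    bit_depth: int
    source_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("no input images")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        shape = self.planes[0].shape
        for p in self.planes:
            if p.ndim != 2:
                raise ValueError("not single-channel")
            if p.shape != shape:
                raise ValueError("inconsistent stack")
        if not self.source_names:
            width = max(4, len(str(len(self.planes) - 1)))
            self.source_names = [f"z{i:0{width}d}" for i in range(len(self.planes))]
        if len(self.source_names) != len(self.planes):
            raise ValueError("source_names must align with planes")

    @property
    def height(self) -> int:
        return self.planes[0].shape[0]

    @property
    def width(self) -> int:
        return self.planes[0].shape[1]

    @property
    def z_count(self) -> int:
        return len(self.planes)

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    def as_array(self) -> np.ndarray:
        """Stack planes into a (Z, Y, X) array."""
        return np.stack(self.planes, axis=0)

    @classmethod
    def from_array(cls, volume: np.ndarray, bit_depth: int) -> "ImageStack":
        return cls(planes=[volume[z] for z in range(volume.shape[0])], bit_depth=bit_depth)


def _check_plane(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError(f"not single-channel: {path}")
    if arr.ndim != 2:
        raise ValueError(f"not single-channel: {path}")
    if arr.dtype not in _ALLOWED_DTYPES:
        raise ValueError(f"unsupported dtype {arr.dtype} in {path}; expected uint8/uint16")
    return arr


def read_stack(directory: str | Path, pattern: str = "*.tif*") -> ImageStack:
    """Read a Z-ordered TIFF series from ``directory``.

    Files matching ``pattern`` are taken in lexicographic order.  A single
    multi-page TIFF is unpacked page-by-page.  All planes must share shape and
    dtype; bit depth is inferred from the dtype.
    """
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no input images in {directory} matching {pattern!r}")
    planes: list[np.ndarray] = []
    names: list[str] = []
    for path in paths:
        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            data = tif.asarray()
        if n_pages > 1:
            # multi-page file: pages are planes
            for k in range(n_pages):
                planes.append(_check_plane(data[k], path))
                names.append(f"{path.stem}_p{k:04d}")
        else:
            planes.append(_check_plane(data, path))
            names.append(path.stem)
    dtypes = {p.dtype for p in planes}
    if len(dtypes) > 1:
        raise ValueError("inconsistent stack: mixed dtypes")
    shapes = {p.shape for p in planes}
    if len(shapes) > 1:
        raise ValueError("inconsistent stack: mixed shapes")
    return ImageStack(planes=planes, bit_depth=_ALLOWED_DTYPES[planes[0].dtype], source_names=names)


def quantize(plane: np.ndarray, bit_depth: int) -> np.ndarray:
    """Round half-up and clip to the integer range of ``bit_depth``."""
    hi = (1 << bit_depth) - 1
    out = np.clip(np.floor(np.asarray(plane, dtype=np.float64) + 0.5), 0, hi)
    return out.astype(np.uint8 if bit_depth == 8 else np.uint16)


def write_stack(stack: ImageStack, directory: str | Path, suffix: str = "") -> list[Path]:
    """Write one TIFF per plane; dtype matches ``stack.bit_depth``.

    Float-valued planes are rounded half-up and clipped, so an integer-valued
    stack round-trips bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, plane in zip(stack.source_names, stack.planes):
        path = directory / f"{name}{suffix}.tif"
        tifffile.imwrite(path, quantize(plane, stack.bit_depth))
        written.append(path)
    return written


def write_support_masks(
    masks: Sequence[np.ndarray], directory: str | Path, names: Sequence[str] | None = None
) -> list[Path]:
    """Write per-plane tissue masks as 8-bit TIFFs (tissue=255, medium=0)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for i, mask in enumerate(masks):
        name = names[i] if names is not None else f"mask{i:04d}"
        path = directory / f"{name}_support.tif"
        tifffile.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))
        written.append(path)
    return written


def read_support_masks(directory: str | Path, pattern: str = "*.tif*") -> list[np.ndarray]:
    """Read support images back as boolean masks (threshold at 128)."""
    stack = read_stack(directory, pattern)
    return [p >= 128 for p in stack.planes]


def write_quantile_log(records, directory: str | Path, filename: str = "quantile_log.tsv") -> Path:
    """Persist per-plane quantile profiles as a tab-separated text table.

    One row per plane: plane name, MBI, MBI quantile rank, then the recorded
    quantile values.  This is the sufficient statistic for re-running any
    Z-normalization mode without the pixel data.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / filename
    with open(path, "w") as fh:
        for name, mbi, rank, quantiles in records:
            qtxt = "\t".join(f"{q:.6g}" for q in np.asarray(quantiles))
            fh.write(f"{name}\t{mbi:.6g}\t{rank:.8g}\t{qtxt}\n")
    return path
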