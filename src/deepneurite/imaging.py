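"""3D stack I/O, maximum-intensity projection and patch cropping.

Arrays are indexed ``(z, y, x)``; user-facing coordinates are ``(x, y, z)``.
Bright-field images carry dark signal on a bright background; they are
inverted once by :func:`normalize_polarity` so every downstream stage can
assume signal-positive intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "Patch",
    "read_stack",
    "write_stack",
    "mip_xy",
    "normalize_polarity",
    "crop_block",
    "block_mip_patch",
    "image_patch",
    "sliding_centers",
]

BRIGHT = "bright_signal"
DARK = "dark_signal"


@dataclass
class ImageStack:
    """A 3D grayscale volume with voxel spacing and signal polarity."""

    voxels: np.ndarray  # (z, y, x)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (sx, sy, sz) um
    polarity: str = BRIGHT

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x), got {self.voxels.ndim}D")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError("all stack dims must be >= 1")
        if not np.all(np.isfinite(np.asarray(self.voxels, dtype=float))):
            raise ValueError("stack intensities must be finite")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        if self.polarity not in (BRIGHT, DARK):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # (Z, Y, X)

    def contains(self, x: float, y: float, z: float) -> bool:
        zs, ys, xs = self.voxels.shape
        return 0 <= x <= xs - 1 and 0 <= y <= ys - 1 and 0 <= z <= zs - 1


@dataclass
class Patch:
    """A k×k tile normalized to [0, 1], tagged with its source center."""

    pixels: np.ndarray
    center: tuple  # (x, y) or (x, y, z)
    size: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.size % 2 == 0:
            raise ValueError("patch size k must be odd")
        if self.pixels.shape != (self.size, self.size):
            raise ValueError("pixels must be k x k")


def read_stack(path, voxel_size=(1.0, 1.0, 1.0), polarity=BRIGHT) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected grayscale pages, got shape {arr.shape}")
    return ImageStack(arr, tuple(voxel_size), polarity)


def write_stack(stack: ImageStack, path) -> None:
    """Write the stack as a multi-page TIFF, preserving dtype."""
    tifffile.imwrite(path, stack.voxels)


def to_uint16(stack: ImageStack) -> ImageStack:
    v = np.clip(np.round(stack.voxels), 0, 65535).astype(np.uint16)
    return replace(stack, voxels=v)


def mip_xy(stack: ImageStack) -> np.ndarray:
    """Maximum-intensity projection onto the XY plane: per-pixel max over z."""
    return stack.voxels.max(axis=0)


def normalize_polarity(stack: ImageStack) -> ImageStack:
    """Invert dark-signal (bright-field) stacks so signal is bright.

    Idempotent: bright-signal stacks pass through unchanged.
    """
    if stack.polarity == BRIGHT:
        return stack
    v = stack.voxels
    return ImageStack(v.max() - v, stack.voxel_size, BRIGHT)


def _round_half_up(c: float) -> int:
    return int(np.floor(c + 0.5))


def crop_block(stack: ImageStack, center, k: int) -> np.ndarray:
    """k×k×k block centered on the rounded (x, y, z) center.

    Out-of-bounds voxels are padded with the stack's minimum intensity
    (background, once polarity is normalized) so no structure is invented
    at the borders.
    """
    if k % 2 == 0:
        raise ValueError("block size k must be odd")
    x, y, z = (float(c) for c in center)
    if not stack.contains(x, y, z):
        raise ValueError(f"center {center} outside stack bounds {stack.shape}")
    cz, cy, cx = _round_half_up(z), _round_half_up(y), _round_half_up(x)
    h = k // 2
    Z, Y, X = stack.voxels.shape
    fill = stack.voxels.min()
    out = np.full((k, k, k), fill, dtype=stack.voxels.dtype)
    z0, z1 = max(0, cz - h), min(Z, cz + h + 1)
    y0, y1 = max(0, cy - h), min(Y, cy + h + 1)
    x0, x1 = max(0, cx - h), min(X, cx + h + 1)
    out[
        z0 - (cz - h) : z1 - (cz - h),
        y0 - (cy - h) : y1 - (cy - h),
        x0 - (cx - h) : x1 - (cx - h),
    ] = stack.voxels[z0:z1, y0:y1, x0:x1]
    return out


def _minmax(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def block_mip_patch(stack: ImageStack, center, k: int) -> Patch:
    """MIP of the local k³ block along z, min-max normalized to [0, 1].

    Constant blocks map to all zeros. This is the patch representation
    used for every classification stage.
    """
    block = crop_block(stack, center, k)
    return Patch(_minmax(block.max(axis=0)), tuple(center), k)


def image_patch(image: np.ndarray, center_xy, k: int) -> Patch:
    """k×k patch from a 2D image around (x, y), min-padded and
    min-max normalized — the 2D analogue of :func:`block_mip_patch`."""
    if k % 2 == 0:
        raise ValueError("patch size k must be odd")
    x, y = (float(c) for c in center_xy)
    H, W = image.shape
    if not (0 <= x <= W - 1 and 0 <= y <= H - 1):
        raise ValueError(f"center {center_xy} outside image {image.shape}")
    cy, cx = _round_half_up(y), _round_half_up(x)
    h = k // 2
    out = np.full((k, k), image.min(), dtype=image.dtype)
    y0, y1 = max(0, cy - h), min(H, cy + h + 1)
    x0, x1 = max(0, cx - h), min(W, cx + h + 1)
    out[y0 - (cy - h) : y1 - (cy - h), x0 - (cx - h) : x1 - (cx - h)] = image[
        y0:y1, x0:x1
    ]
    return Patch(_minmax(out), (float(x), float(y)), k)


def sliding_centers(image_shape, stride: int, k: int) -> list[tuple[int, int]]:
    """Regular sliding-window grid of patch centers, row-major (x, y).

    Centers lie on ``range(0, dim, stride)`` in each axis, so every center
    is inside the image; border patches are handled by min-padding.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if k % 2 == 0:
        raise ValueError("patch size k must be odd")
    H, W = image_shape
    return [(x, y) for y in range(0, H, stride) for x in range(0, W, stride)]
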