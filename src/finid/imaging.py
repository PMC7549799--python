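"""Image loading, ROI cropping and fin-contour extraction.

Conventions used throughout the package:

* Rasters are 2-D float64 arrays of luminance in [0, 1], indexed ``[y, x]``
  (row = y, col = x).
* Coordinates are 0-based; regions of interest are half-open
  ``[x0, x1) x [y0, y1)``.
* Gradients at image borders use replicate padding, so a constant image has
  zero gradient everywhere and no spurious border edges appear.

Color images are collapsed to luminance with fixed ITU-style weights
(0.299, 0.587, 0.114) so that results do not depend on the decoder.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

#: Fixed RGB -> luminance weights.
LUMINANCE_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Minimum raster side length accepted by the feature-extraction entry points.
MIN_FEATURE_SIZE = 8


@dataclass(frozen=True)
class GrayImage:
    """A 2-D luminance raster with values in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError(f"GrayImage expects a 2-D raster, got shape {p.shape}")
        if p.size == 0:
            raise ValueError("GrayImage raster is empty")
        if not np.all(np.isfinite(p)):
            raise ValueError("GrayImage raster contains non-finite values")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("GrayImage luminance must lie in [0, 1]")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open pixel rectangle [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"empty or inverted ROI: {self}")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError(f"negative ROI origin: {self}")

    @classmethod
    def parse(cls, text: str) -> "RegionOfInterest":
        """Parse 'x0,y0,x1,y1'."""
        parts = text.split(",")
        if len(parts) != 4:
            raise ValueError(f"ROI must be 'x0,y0,x1,y1', got {text!r}")
        x0, y0, x1, y1 = (int(p) for p in parts)
        return cls(x0, y0, x1, y1)


@dataclass(frozen=True)
class ContourMask:
    """Boolean raster marking fin-edge pixels; same shape as its source."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ContourMask expects a 2-D boolean raster")
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def load_image(path: str | Path) -> GrayImage:
    """Load a PNG/JPEG/TIFF photograph as a [0, 1] luminance raster.

    8-bit samples are divided by 255, 16-bit by 65535; color images are
    collapsed with the fixed 0.299/0.587/0.114 weights.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as img:
            img.load()
            arr = np.asarray(img)
    except UnidentifiedImageError as exc:
        raise ValueError(f"unreadable image file: {path}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path}")
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[:, :, :3] @ LUMINANCE_WEIGHTS / scale
    else:
        arr = arr / scale
    return GrayImage(np.clip(arr, 0.0, 1.0))


def crop_roi(image: GrayImage, roi: RegionOfInterest) -> GrayImage:
    """Crop ``image`` to ``roi``; raises on out-of-bounds rectangles."""
    if roi.x1 > image.width or roi.y1 > image.height:
        raise IndexError(
            f"ROI {roi} exceeds image bounds {image.width}x{image.height}"
        )
    return GrayImage(image.pixels[roi.y0 : roi.y1, roi.x0 : roi.x1].copy())


def gradient_magnitude(pixels: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude with replicate border padding."""
    padded = np.pad(pixels, 1, mode="edge")
    dx = padded[1:-1, 2:] - padded[1:-1, :-2]
    dy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    return np.sqrt(dx * dx + dy * dy)


def extract_fin_contour(
    image: GrayImage, grad_threshold: float = 0.1, min_component: int = 20
) -> ContourMask:
    """Isolate the dorsal-fin edge as a boolean mask.

    Marks pixels whose central-difference gradient magnitude exceeds
    ``grad_threshold``.  When ``min_component > 0`` the mask is restricted to
    the largest 8-connected component (the fin outline), which discards
    isolated noise responses; a largest component smaller than
    ``min_component`` pixels yields an empty mask.  Deterministic; a constant
    image yields an empty mask.
    """
    if grad_threshold <= 0:
        raise ValueError("grad_threshold must be > 0")
    mask = gradient_magnitude(image.pixels) > grad_threshold
    if min_component > 0 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        if sizes[best - 1] < min_component:
            mask = np.zeros_like(mask)
        else:
            mask = labels == best
    return ContourMask(mask)
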