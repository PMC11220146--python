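"""Tissue segmentation and tile extraction for whole-slide images.

A slide is segmented from its white background by Otsu thresholding of the
grayscale image.  The slide is then cut into a non-overlapping grid of
square tiles — 1024 px at 40x magnification, 512 px at 20x (upsampled to
1024 px so both magnifications share one output contract) — tiles that are
mostly white background are excluded, and a fixed number of tiles is
sampled uniformly at random per slide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

#: Output tile edge in pixels, common to both magnifications.
TILE_OUTPUT_PX = 1024

#: Source tile edge per nominal magnification.
SOURCE_TILE_PX = {40: 1024, 20: 512}

#: A pixel is "white" when every 8-bit channel reaches this level.
WHITE_LEVEL = 220

#: Rec. 601 luminance weights for grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class DegenerateImageError(ValueError):
    """Raised when an image has a single gray level and cannot be thresholded."""


@dataclass
class SlideImage:
    """An RGB slide with a nominal magnification tag.

    The magnification is carried as metadata (sidecar/config), not read from
    image headers, because plain TIFF/PNG stand-ins lack objective-power tags.
    """

    pixels: np.ndarray  # H x W x 3, uint8
    magnification: int  # 20 or 40
    patient_id: str
    tissue_truth: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide pixels must be an H x W x 3 array")
        if self.magnification not in SOURCE_TILE_PX:
            raise ValueError(
                f"magnification must be one of {sorted(SOURCE_TILE_PX)}, "
                f"got {self.magnification}"
            )

    @property
    def source_tile_px(self) -> int:
        return SOURCE_TILE_PX[self.magnification]


class Tile:
    """One square subimage of a slide.

    ``origin`` is the (row, col) of the top-left corner in 0-based slide
    coordinates, always a multiple of ``source_size``.  ``pixels`` is the
    1024 x 1024 x 3 array after any upsampling; for 512-px source tiles the
    upsampling (bilinear) is performed lazily on access.
    """

    __slots__ = ("origin", "source_size", "white_fraction", "_source_pixels")

    def __init__(self, origin, source_pixels, source_size, white_fraction):
        self.origin = (int(origin[0]), int(origin[1]))
        self._source_pixels = source_pixels
        self.source_size = int(source_size)
        self.white_fraction = float(white_fraction)

    @property
    def pixels(self) -> np.ndarray:
        if self.source_size == TILE_OUTPUT_PX:
            return self._source_pixels
        img = Image.fromarray(self._source_pixels)
        img = img.resize((TILE_OUTPUT_PX, TILE_OUTPUT_PX), Image.BILINEAR)
        return np.asarray(img)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"Tile(origin={self.origin}, source_size={self.source_size}, "
            f"white_fraction={self.white_fraction:.3f})"
        )


@dataclass
class TileSample:
    """The tiles randomly sampled (without replacement) from one slide."""

    patient_id: str
    tiles: list
    seed: int


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB array, as float32 in [0, 255]."""
    p = np.asarray(pixels, dtype=np.float32)
    r, g, b = LUMA_WEIGHTS
    return r * p[..., 0] + g * p[..., 1] + b * p[..., 2]


def otsu_threshold(gray_histogram: np.ndarray) -> int:
    """Otsu threshold from a 256-bin gray-level count histogram.

    Returns the integer threshold ``t`` in [0, 254] maximizing the
    between-class variance of the split {levels <= t} vs {levels > t}.
    Ties are broken toward the lower threshold.

    Raises
    ------
    DegenerateImageError
        If fewer than two gray levels are occupied.
    """
    hist = np.asarray(gray_histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError("image has a single occupied gray level")

    levels = np.arange(256, dtype=np.float64)
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]                    # weight of class {<= t}, t = 0..254
    w1 = total - w0
    m0 = np.cumsum(hist * levels)[:-1]
    mu_total = (hist * levels).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer


def tissue_mask(slide: SlideImage) -> np.ndarray:
    """Binary tissue mask: 1 on the darker (tissue) side of the Otsu split."""
    gray = to_grayscale(slide.pixels)
    gray_u8 = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    hist = np.bincount(gray_u8.ravel(), minlength=256)
    t = otsu_threshold(hist)
    return gray_u8 <= t


def tile_slide(slide: SlideImage) -> list:
    """Cut a slide into its non-overlapping grid of candidate tiles.

    Source tiles are 1024 px at 40x and 512 px at 20x; partial tiles at the
    right/bottom edges are discarded.  The white fraction (pixels with all
    channels >= 220) is computed per tile on the source pixels.
    """
    src = slide.source_tile_px
    h, w = slide.pixels.shape[:2]
    n_rows, n_cols = h // src, w // src
    if n_rows == 0 or n_cols == 0:
        raise ValueError(
            f"slide {slide.patient_id}: {h}x{w} px cannot fit one {src}-px tile"
        )
    white = np.all(slide.pixels >= WHITE_LEVEL, axis=2)
    tiles = []
    for i in range(n_rows):
        for j in range(n_cols):
            r, c = i * src, j * src
            wf = white[r : r + src, c : c + src].mean()
            tiles.append(Tile((r, c), slide.pixels[r : r + src, c : c + src], src, wf))
    return tiles


def filter_tiles(tiles, max_white: float = 0.5) -> list:
    """Drop tiles whose white fraction is strictly greater than ``max_white``."""
    return [t for t in tiles if t.white_fraction <= max_white]


def sample_tiles(tiles, patient_id: str = "", k: int = 10, seed: int = 0) -> TileSample:
    """Sample ``k`` tiles uniformly without replacement, reproducibly.

    Slides with fewer than ``k`` candidates return all of them with a
    warning rather than failing, so small fixtures stay usable.
    """
    if len(tiles) == 0:
        raise ValueError(f"slide {patient_id!r}: no candidate tiles to sample")
    rng = np.random.default_rng(seed)
    if len(tiles) <= k:
        if len(tiles) < k:
            warnings.warn(
                f"slide {patient_id!r}: only {len(tiles)} candidate tiles "
                f"(requested {k}); returning all",
                stacklevel=2,
            )
        idx = rng.permutation(len(tiles))
    else:
        idx = rng.choice(len(tiles), size=k, replace=False)
    return TileSample(patient_id, [tiles[i] for i in idx], seed)


def candidate_tiles(slide: SlideImage, max_white: float = 0.5) -> list:
    """Grid tiles of a slide after the white-space filter."""
    return filter_tiles(tile_slide(slide), max_white=max_white)
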