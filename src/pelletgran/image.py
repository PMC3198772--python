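"""Image loading, calibration, contrast preparation and the baseline
isolated-pellet measurement.

Images are carried as :class:`CalibratedImage`: a float 2-D intensity
array on the 0–255 scale together with an isotropic mm-per-pixel
calibration (the reference rig resolves 0.072 mm per pixel, so an
800×600 frame covers about 57.6×43.2 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import exposure, filters, measure

__all__ = [
    "CalibratedImage",
    "ClaheConfig",
    "PelletMeasurement",
    "load_image",
    "save_image",
    "apply_clahe",
    "measure_isolated_pellets",
]


@dataclass(frozen=True)
class CalibratedImage:
    """2-D grayscale intensities (0–255 scale) with a pixel-size calibration."""

    pixels: np.ndarray
    mm_per_pixel: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.isfinite(px).all() or (px < 0).any():
            raise ValueError("intensities must be finite and non-negative")
        if not (self.mm_per_pixel > 0):
            raise ValueError("mm_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height_mm(self) -> float:
        return self.shape[0] * self.mm_per_pixel

    @property
    def width_mm(self) -> float:
        return self.shape[1] * self.mm_per_pixel

    @property
    def total_intensity(self) -> float:
        """Sum of all pixel values (A(f) of the granulometry)."""
        return float(self.pixels.sum(dtype=np.float64))

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class ClaheConfig:
    """Contrast-limited adaptive histogram equalisation settings.

    ``tile_grid`` is (tiles down, tiles across); ``clip_limit`` is the
    fraction of histogram mass at which local contrast amplification is
    clipped.  Defaults (8×8 tiles, clip 0.01) are conventional; the method
    only asks that image contrast be as high as possible.
    """

    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.01
    output_range: tuple[float, float] = (0.0, 255.0)

    def __post_init__(self) -> None:
        ty, tx = self.tile_grid
        if ty < 1 or tx < 1:
            raise ValueError("tile_grid components must be >= 1")
        if not (0 < self.clip_limit <= 1):
            raise ValueError("clip_limit must be in (0, 1]")
        lo, hi = self.output_range
        if not (hi > lo):
            raise ValueError("output_range must be increasing")


@dataclass(frozen=True)
class PelletMeasurement:
    """Principal-axis extents of one connected bright component."""

    major_axis_px: float
    minor_axis_px: float
    touches_border: bool


def load_image(path: str | Path, mm_per_pixel: float) -> CalibratedImage:
    """Read a PNG/TIFF image onto the 0–255 scale.

    Multi-channel images are collapsed by channel mean; 16-bit inputs are
    rescaled by max-value division (×255/65535).
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{path}: expected a non-empty 2-D image, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        arr = arr.astype(float) * (255.0 / 65535.0)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
    else:
        arr = np.asarray(arr, dtype=float)
        if arr.max(initial=0.0) <= 1.0:  # unit-scaled float input
            arr = arr * 255.0
    return CalibratedImage(arr, mm_per_pixel)


def save_image(img: CalibratedImage, path: str | Path) -> None:
    """Write as 8-bit grayscale; exact round-trip for integral 0–255 data."""
    data = np.clip(np.round(img.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def apply_clahe(img: CalibratedImage, cfg: ClaheConfig | None = None) -> CalibratedImage:
    """Local contrast enhancement before granulometry.

    Deterministic; preserves shape and calibration and maps output into
    ``cfg.output_range``.
    """
    cfg = cfg or ClaheConfig()
    ty, tx = cfg.tile_grid
    h, w = img.shape
    if h < ty or w < tx:
        raise ValueError(f"image {h}x{w} smaller than tile grid {ty}x{tx}")
    kernel = (max(h // ty, 1), max(w // tx, 1))
    out = exposure.equalize_adapthist(
        img.pixels / 255.0, kernel_size=kernel, clip_limit=cfg.clip_limit
    )
    lo, hi = cfg.output_range
    return img.with_pixels(lo + out * (hi - lo))


def measure_isolated_pellets(
    img: CalibratedImage, threshold: float | None = None
) -> list[PelletMeasurement]:
    """Baseline measurement of non-piled pellets: threshold, label, and
    report the principal-axis extents (length and width in pixels) of each
    connected bright component.

    ``threshold=None`` selects Otsu's threshold automatically.  Components
    touching the image border are still measured and flagged.  A blank
    image yields an empty list.
    """
    px = img.pixels
    if threshold is None:
        if np.ptp(px) == 0:
            return []
        threshold = float(filters.threshold_otsu(px))
    mask = px > threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    h, w = mask.shape
    out: list[PelletMeasurement] = []
    for region in measure.regionprops(labels):
        rows, cols = np.nonzero(labels == region.label)
        rc = np.stack([rows - rows.mean(), cols - cols.mean()])
        # principal axes from second moments; extents are max-min spans + 1
        cov = rc @ rc.T / rc.shape[1]
        _, vecs = np.linalg.eigh(cov)
        proj = vecs.T @ rc
        spans = np.ptp(proj, axis=1) + 1.0
        major, minor = float(spans.max()), float(spans.min())
        r0, c0, r1, c1 = region.bbox
        border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        out.append(PelletMeasurement(major, minor, border))
    return out
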