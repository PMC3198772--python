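"""Grayscale granulometry: erosion, dilation, opening, the opening
intensity curve and the pattern spectrum.

The opening with a disk of radius r removes every image structure the
disk cannot fit inside.  Sweeping r and summing the surviving intensity
gives the opening intensity (granulometric) curve; its normalised
successive differences form the pattern spectrum

    PS(n) = (A(γ_n f) − A(γ_{n+1} f)) / A(f),

where A(·) is the total pixel sum and γ_n the opening with the n-th
element of the family.  The pattern spectrum is read as an estimated
particle-size distribution, and the location of its maximum tracks the
dominant pellet size — all without segmenting a single pellet.

Border handling: erosion pads with +inf and dilation with −inf, so a
constant image is a fixed point of the opening and pellets touching the
frame edge are not artificially eroded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .elements import StructuringElement
from .image import CalibratedImage

__all__ = [
    "GranulometryCurve",
    "PatternSpectrum",
    "erode",
    "dilate",
    "open_image",
    "opening_curve",
    "curve_derivative",
    "pattern_spectrum",
    "spectrum_peak",
]


def _check_fits(img: CalibratedImage, se: StructuringElement) -> None:
    if se.footprint.shape[0] > min(img.shape):
        raise ValueError(
            f"structuring element {se.footprint.shape} larger than image {img.shape}"
        )


def _chain(img: CalibratedImage, se: StructuringElement, op, cval: float) -> CalibratedImage:
    out = img.pixels
    if se.decomposition and se.is_flat:
        for factor in se.decomposition:
            out = op(out, footprint=factor, mode="constant", cval=cval)
    elif se.is_flat:
        out = op(out, footprint=se.footprint, mode="constant", cval=cval)
    else:
        structure = np.where(se.footprint, se.heights, -np.inf)
        out = op(out, structure=structure, mode="constant", cval=cval)
    return img.with_pixels(out)


def erode(img: CalibratedImage, se: StructuringElement) -> CalibratedImage:
    """Per-pixel minimum over the footprint (heights subtracted first for
    non-flat elements); anti-extensive for flat elements."""
    _check_fits(img, se)
    out = _chain(img, se, ndi.grey_erosion, np.inf)
    if not se.is_flat:  # keep the 0-255 convention meaningful
        out = out.with_pixels(np.maximum(out.pixels, 0.0))
    return out


def dilate(img: CalibratedImage, se: StructuringElement) -> CalibratedImage:
    """Per-pixel maximum over the (reflected) footprint."""
    _check_fits(img, se)
    return _chain(img, se, ndi.grey_dilation, -np.inf)


def open_image(img: CalibratedImage, se: StructuringElement) -> CalibratedImage:
    """Morphological opening: erosion then dilation with the same element.

    Anti-extensive, increasing and idempotent; removes structure the
    element cannot fit inside.
    """
    _check_fits(img, se)
    if se.is_flat:
        return dilate(erode(img, se), se)
    eroded = _chain(img, se, ndi.grey_erosion, np.inf)
    opened = _chain(eroded, se, ndi.grey_dilation, -np.inf)
    return opened.with_pixels(np.clip(opened.pixels, 0.0, None))


@dataclass(frozen=True)
class GranulometryCurve:
    """Opening intensity as a function of element radius.

    ``intensities[i]`` is the total pixel sum after opening with the
    family element of nominal radius ``radii[i]``; ``total_intensity`` is
    A(f), the pixel sum of the analysed image itself.
    """

    radii: np.ndarray
    effective_radii: np.ndarray
    intensities: np.ndarray
    total_intensity: float

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=int)
        eff = np.asarray(self.effective_radii, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if not (len(radii) == len(eff) == len(inten)):
            raise ValueError("radii, effective_radii and intensities must align")
        if len(radii) == 0:
            raise ValueError("curve must have at least one radius")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.total_intensity <= 0 and inten.any():
            raise ValueError("total_intensity must be positive for a non-trivial curve")
        if np.any(inten > self.total_intensity * (1 + 1e-9) + 1e-9):
            raise ValueError("opening intensities cannot exceed the total intensity")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "effective_radii", eff)
        object.__setattr__(self, "intensities", inten)

    def __len__(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class PatternSpectrum:
    """Normalised successive opening differences, indexed by the nominal
    radius at which the structure is lost (effective radii alongside)."""

    radii: np.ndarray
    values: np.ndarray
    effective_radii: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=int)
        values = np.asarray(self.values, dtype=float)
        eff = (
            np.asarray(self.effective_radii, dtype=float)
            if self.effective_radii is not None
            else radii.astype(float)
        )
        if len(radii) != len(values) or len(eff) != len(radii):
            raise ValueError("radii and values must align")
        if len(radii) == 0:
            raise ValueError("pattern spectrum must be non-empty")
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "effective_radii", eff)

    @property
    def is_degenerate(self) -> bool:
        """True when no bin dominates (flat spectrum, e.g. a blank image)."""
        return bool(np.all(self.values == self.values[0]))

    def __len__(self) -> int:
        return len(self.radii)


def _nested(family: list[StructuringElement]) -> bool:
    for small, big in zip(family, family[1:]):
        pad = (big.footprint.shape[0] - small.footprint.shape[0]) // 2
        if pad < 0:
            return False
        n = small.footprint.shape[0]
        window = big.footprint[pad : pad + n, pad : pad + n]
        if np.any(small.footprint & ~window):
            return False
    return True


def opening_curve(
    img: CalibratedImage, family: list[StructuringElement]
) -> GranulometryCurve:
    """Open the image with each element of a nested family and sum the
    surviving intensity per radius.

    Intensities are accumulated in float64 (a full 8-bit frame sums to
    ~1.2e8, far inside exact float64 integer range).
    """
    if not family:
        raise ValueError("element family is empty")
    radii = np.array([se.nominal_radius for se in family])
    if np.any(np.diff(radii) <= 0):
        raise ValueError("family radii must be strictly increasing")
    if not _nested(family):
        raise ValueError("family footprints must be nested (each contains the previous)")
    intensities = np.array(
        [open_image(img, se).pixels.sum(dtype=np.float64) for se in family]
    )
    return GranulometryCurve(
        radii=radii,
        effective_radii=np.array([se.effective_radius for se in family]),
        intensities=intensities,
        total_intensity=img.total_intensity,
    )


def curve_derivative(curve: GranulometryCurve) -> np.ndarray:
    """Successive differences of the opening intensities (≤ 0 for a
    sieving family); the telescoped sum equals last − first intensity."""
    if len(curve) < 2:
        raise ValueError("need at least two radii to differentiate")
    return np.diff(curve.intensities)


def pattern_spectrum(
    curve: GranulometryCurve, include_initial: bool = False
) -> PatternSpectrum:
    """Normalised negative derivative of the opening curve.

    ``include_initial`` prepends a bin at radius 0 holding
    (A(f) − A(γ_first f)) / A(f), so the spectrum sums to 1 when the
    largest radius empties the image; off by default to follow the
    successive-differences definition literally.
    """
    if curve.total_intensity <= 0:
        raise ValueError("total intensity must be positive")
    if len(curve) < 2:
        raise ValueError("need at least two radii for a pattern spectrum")
    values = -np.diff(curve.intensities) / curve.total_intensity
    radii = curve.radii[:-1]
    eff = curve.effective_radii[:-1]
    if include_initial:
        head = (curve.total_intensity - curve.intensities[0]) / curve.total_intensity
        values = np.concatenate([[head], values])
        radii = np.concatenate([[0], radii])
        eff = np.concatenate([[0.0], eff])
    return PatternSpectrum(radii=radii, values=values, effective_radii=eff)


def spectrum_peak(ps: PatternSpectrum) -> int:
    """Nominal radius of the spectrum maximum, ties toward the smallest
    radius (a flat spectrum is degenerate — see ``ps.is_degenerate``)."""
    if len(ps) == 0:
        raise ValueError("empty pattern spectrum")
    return int(ps.radii[int(np.argmax(ps.values))])
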