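"""Structuring elements for rotation-independent granulometry.

The probe shapes used throughout the package: exact digital Euclidean
disks, fast decomposable (octagonal) disk approximations, and the
comparison shapes (octagon, diamond, non-flat ball).  A disk-shaped probe
makes the morphological opening independent of pellet orientation, which
is what allows granulometry on piled, disordered pellets.

Two disk families are offered:

``disk_exact``
    Pixel (i, j) belongs to the footprint iff i² + j² ≤ r².  Footprints
    nest with radius, but the family is *not* a sieving family: a digital
    disk is in general not expressible as a union of translates of a
    smaller digital disk, so opening intensities can ripple slightly.

``disk_decomposable``
    Octagonal approximation built as a Minkowski chain of ``a`` unit
    diamonds (4-neighbourhoods) and ``b`` unit squares, with (a, b)
    non-decreasing along the radius grid.  Because each element is a
    Minkowski factor of every larger one, the family is an exact sieving
    family (opening intensities are provably non-increasing) and openings
    cost O(a + b) small erosions instead of O(r²) per pixel.

Effective radii are always reported as sqrt(area / π), i.e. the radius of
the continuous disk with the same pixel area, which corrects for the
approximation error of the decomposable footprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "StructuringElement",
    "euclidean_disk",
    "decomposable_disk",
    "comparison_element",
    "effective_radius",
    "disk_family",
    "ELEMENT_KINDS",
]

ELEMENT_KINDS = ("disk_exact", "disk_decomposable", "octagon", "diamond", "ball")

# Unit Minkowski factors of the decomposable disk.
_UNIT_DIAMOND = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_UNIT_SQUARE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class StructuringElement:
    """A centred, 180°-symmetric probe shape.

    Parameters
    ----------
    footprint
        Odd-sided square boolean mask, centre pixel set.
    nominal_radius
        The integer radius the element was requested at (pixels).
    kind
        One of :data:`ELEMENT_KINDS`.
    decomposition
        Ordered Minkowski factors: dilating a single-pixel image by each
        factor in turn reproduces ``footprint`` exactly.  Empty for
        non-decomposable kinds.
    heights
        Per-pixel height offsets for the non-flat ``ball`` element
        (``None`` for flat elements).
    """

    footprint: np.ndarray
    nominal_radius: int
    kind: str
    decomposition: tuple[np.ndarray, ...] = ()
    heights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        if fp.ndim != 2 or fp.shape[0] != fp.shape[1] or fp.shape[0] % 2 == 0:
            raise ValueError("footprint must be a square mask with odd side length")
        if self.kind not in ELEMENT_KINDS:
            raise ValueError(f"unknown element kind {self.kind!r}")
        if not fp.any():
            raise ValueError("footprint must be non-empty")
        c = fp.shape[0] // 2
        if not fp[c, c]:
            raise ValueError("centre pixel of the footprint must be set")
        if not np.array_equal(fp, fp[::-1, ::-1]):
            raise ValueError("footprint must be symmetric under 180° rotation")
        if self.heights is not None:
            h = np.asarray(self.heights, dtype=float)
            if h.shape != fp.shape:
                raise ValueError("heights must match the footprint shape")
            object.__setattr__(self, "heights", h)

    @property
    def area(self) -> int:
        """Number of pixels in the footprint."""
        return int(self.footprint.sum())

    @property
    def effective_radius(self) -> float:
        """Radius of the continuous disk with the same pixel area."""
        return math.sqrt(self.area / math.pi)

    @property
    def is_flat(self) -> bool:
        return self.heights is None

    def __eq__(self, other: object) -> bool:  # array fields break default eq
        if not isinstance(other, StructuringElement):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.nominal_radius == other.nominal_radius
            and np.array_equal(self.footprint, other.footprint)
        )

    def __hash__(self) -> int:
        return hash((self.kind, self.nominal_radius, self.footprint.tobytes()))


def _disk_mask(radius: int) -> np.ndarray:
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def euclidean_disk(radius: int) -> StructuringElement:
    """Exact digital disk: (i, j) set iff sqrt(i² + j²) ≤ radius."""
    radius = _check_radius(radius)
    return StructuringElement(_disk_mask(radius), radius, "disk_exact")


def _octagon_mask(a: int, b: int) -> np.ndarray:
    """Minkowski sum of a diamond of radius ``a`` and a square of radius ``b``."""
    n = a + b
    y, x = np.mgrid[-n : n + 1, -n : n + 1]
    return np.maximum(np.abs(x) - b, 0) + np.maximum(np.abs(y) - b, 0) <= a


def _octagon_area(a: int, b: int) -> int:
    return (2 * (a + b) + 1) ** 2 - 2 * a * (a + 1)


@lru_cache(maxsize=None)
def _decomposition_plan(max_radius: int) -> tuple[tuple[int, int], ...]:
    """(a, b) Minkowski factor counts for radii 1..max_radius.

    For each radius the pair minimising |area − πr²| is chosen among pairs
    with half-width within one pixel of r; (a, b) are kept componentwise
    non-decreasing so every element is a Minkowski factor of all larger
    ones (the sieving property of the family follows directly).
    """
    plan: list[tuple[int, int]] = []
    a_prev = b_prev = 0
    for r in range(1, max_radius + 1):
        best: tuple[tuple[float, float, int], tuple[int, int]] | None = None
        for a in range(a_prev, r + 2):
            for b in range(b_prev, r + 2 - a):
                if a + b < 1 or abs(a + b - r) > 1:
                    continue
                key = (
                    abs(_octagon_area(a, b) - math.pi * r * r),
                    abs(b - 0.3827 * r),  # prefer near-regular octagons on ties
                    a,
                )
                if best is None or key < best[0]:
                    best = (key, (a, b))
        assert best is not None  # (a_prev, b_prev + 1) is always admissible
        a_prev, b_prev = best[1]
        plan.append((a_prev, b_prev))
    return tuple(plan)


def decomposable_disk(radius: int, *, _plan_radius: int | None = None) -> StructuringElement:
    """Fast approximated disk, decomposable into unit diamonds and squares.

    The footprint is a convex digital octagon whose area tracks πr² (within
    15 % for r ≥ 3); its decomposition is the list of unit Minkowski
    factors, so erosions and dilations can be chained instead of probing
    the full footprint.  ``decomposable_disk(1)`` coincides with
    ``euclidean_disk(1)``.
    """
    radius = _check_radius(radius)
    plan = _decomposition_plan(max(_plan_radius or radius, radius))
    a, b = plan[radius - 1]
    footprint = _octagon_mask(a, b)
    decomposition = tuple([_UNIT_DIAMOND] * a + [_UNIT_SQUARE] * b)
    return StructuringElement(footprint, radius, "disk_decomposable", decomposition)


def comparison_element(kind: str, radius: int) -> StructuringElement:
    """Alternative probe shapes tried alongside the disk.

    ``octagon``: flat regular-ish octagon of half-width ``radius``.
    ``diamond``: L1 ball (area 2r² + 2r + 1).
    ``ball``: non-flat element — disk footprint with a spherical-cap
    height profile of height ``radius``, quantised to integers.
    """
    radius = _check_radius(radius)
    if kind == "diamond":
        y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        return StructuringElement(np.abs(x) + np.abs(y) <= radius, radius, "diamond")
    if kind == "octagon":
        # regular octagon: corner cut a = w(2 − √2) of the bounding square
        a = round(radius * (2.0 - math.sqrt(2.0)))
        a = min(max(a, 0), radius)
        return StructuringElement(_octagon_mask(a, radius - a), radius, "octagon")
    if kind == "ball":
        fp = _disk_mask(radius)
        y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
        heights = np.where(fp, np.sqrt(np.maximum(radius**2 - x * x - y * y, 0)), 0.0)
        return StructuringElement(fp, radius, "ball", heights=np.round(heights))
    raise ValueError(f"unknown comparison element kind {kind!r}")


def effective_radius(se: StructuringElement) -> float:
    """sqrt(area / π): the equal-area continuous-disk radius of a footprint.

    Strictly increasing in footprint area; used to index granulometry
    results on a scale free of disk-approximation artefacts.
    """
    if not se.footprint.any():
        raise ValueError("footprint is empty")
    return se.effective_radius


def disk_family(
    max_radius: int, kind: str = "disk_decomposable", min_radius: int = 1
) -> list[StructuringElement]:
    """Nested disk family for granulometry, radii ``min_radius..max_radius``.

    The decomposable family shares one decomposition plan across radii so
    the elements are Minkowski factors of each other (exact sieving); the
    exact family nests as footprints.
    """
    if max_radius < min_radius or min_radius < 1:
        raise ValueError("need 1 <= min_radius <= max_radius")
    if kind == "disk_exact":
        make = euclidean_disk
    elif kind == "disk_decomposable":
        def make(r: int) -> StructuringElement:
            return decomposable_disk(r, _plan_radius=max_radius)
    elif kind in ("octagon", "diamond", "ball"):
        def make(r: int) -> StructuringElement:
            return comparison_element(kind, r)
    else:
        raise ValueError(f"unknown element kind {kind!r}")
    return [make(r) for r in range(min_radius, max_radius + 1)]


def _check_radius(radius: int) -> int:
    if int(radius) != radius or radius < 1:
        raise ValueError(f"radius must be an integer >= 1, got {radius!r}")
    return int(radius)
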