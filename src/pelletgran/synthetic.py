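"""Seeded synthetic pellet scenes with known ground truth.

The generator emulates the imaging conditions of the reference rig:
near-shadowless diffuse lighting, bright roughly-cylindrical pellets
piled on a darker background, 0.072 mm per pixel.  Lying pellets project
as capsules (a length×diameter rectangle with semicircular caps), a
configurable fraction stand on end and project as discs of the diameter.
Pellets are composited in z-order (later pellets occlude earlier ones),
with mild per-pellet albedo variation, ~1 px soft edges and additive
sensor noise.  Every generator is a pure function of its seed and
parameters.

Batch series emulate the size drift of an extruder run: the population
diameter and length grow logarithmically in time, with optional widening
of the size distribution, mirroring the drift observed over production
batches of 1.1 mm and 3.0 mm product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .image import CalibratedImage

__all__ = [
    "PelletPopulation",
    "BatchDrift",
    "SceneTruth",
    "render_pile",
    "render_binary_discs",
    "render_batch",
    "batch_c_drift",
    "batch_d_drift",
    "DEFAULT_MM_PER_PIXEL",
]

DEFAULT_MM_PER_PIXEL = 0.072

TRUTH_COLUMNS = ("row_px", "col_px", "angle_rad", "width_px", "length_px", "standing")


@dataclass(frozen=True)
class PelletPopulation:
    """Size distribution of one sampled pellet population (mm units)."""

    diameter_mean: float
    diameter_sd: float
    length_mean: float
    length_sd: float
    count: int
    seed: int

    def __post_init__(self) -> None:
        if self.diameter_mean <= 0 or self.length_mean <= 0:
            raise ValueError("size means must be positive")
        if self.diameter_sd < 0 or self.length_sd < 0:
            raise ValueError("size standard deviations must be non-negative")
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class BatchDrift:
    """Logarithmic size drift of a production batch.

    At sampling time t (minutes) the population means are
    ``start + growth · ln(1 + t)`` plus N(0, noise_sd) sampling noise;
    ``diameter_sd_growth``/``length_sd_growth`` optionally widen the size
    distribution over the run.
    """

    start_population: PelletPopulation
    diameter_growth: float
    length_growth: float
    sampling_times: tuple[float, ...]
    noise_sd: float = 0.0
    diameter_sd_growth: float = 0.0
    length_sd_growth: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.sampling_times, dtype=float)
        if len(t) == 0 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be non-negative and strictly increasing")
        object.__setattr__(self, "sampling_times", tuple(float(x) for x in t))

    def population_at(self, t: float, rng: np.random.Generator) -> PelletPopulation:
        g = math.log1p(t)
        jd = float(rng.normal(0.0, self.noise_sd)) if self.noise_sd else 0.0
        jl = float(rng.normal(0.0, self.noise_sd)) if self.noise_sd else 0.0
        p = self.start_population
        return replace(
            p,
            diameter_mean=max(p.diameter_mean + self.diameter_growth * g + jd, 1e-3),
            length_mean=max(p.length_mean + self.length_growth * g + jl, 1e-3),
            diameter_sd=p.diameter_sd + self.diameter_sd_growth * g,
            length_sd=p.length_sd + self.length_sd_growth * g,
            seed=int(rng.integers(0, 2**31 - 1)),
        )


@dataclass(frozen=True)
class SceneTruth:
    """Per-pellet ground truth of a rendered scene."""

    records: pd.DataFrame = field(default_factory=lambda: _empty_truth())

    def __post_init__(self) -> None:
        missing = set(TRUTH_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"truth records missing columns {sorted(missing)}")
        if len(self.records) and (
            (self.records["width_px"] <= 0).any()
            or (self.records["length_px"] <= 0).any()
        ):
            raise ValueError("projected sizes must be positive")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def mean_projected_width_px(self) -> float:
        return float(self.records["width_px"].mean())


def _empty_truth() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in TRUTH_COLUMNS})


def _capsule_distance(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    half_span: float,
    pad: float,
) -> tuple[slice, slice, np.ndarray]:
    """Distance from each pixel of a local patch to the capsule spine
    segment (length 2·half_span, orientation ``angle``)."""
    r0, c0 = center
    reach = half_span + pad
    rlo = max(int(r0 - reach) - 1, 0)
    rhi = min(int(r0 + reach) + 2, shape[0])
    clo = max(int(c0 - reach) - 1, 0)
    chi = min(int(c0 + reach) + 2, shape[1])
    rows, cols = np.mgrid[rlo:rhi, clo:chi]
    dr, dc = rows - r0, cols - c0
    ur, uc = math.sin(angle), math.cos(angle)
    along = np.clip(dr * ur + dc * uc, -half_span, half_span)
    dist = np.hypot(dr - along * ur, dc - along * uc)
    return slice(rlo, rhi), slice(clo, chi), dist


def render_pile(
    pop: PelletPopulation,
    image_shape: tuple[int, int] = (600, 800),
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    overlap: float = 0.3,
    standing_fraction: float = 0.2,
    background: float = 25.0,
    albedo_mean: float = 205.0,
    albedo_sd: float = 8.0,
    edge_softness: float = 1.0,
    rim_width_px: float = 1.5,
    rim_depth: float = 0.35,
    noise_sd: float = 2.0,
) -> tuple[CalibratedImage, SceneTruth]:
    """Render a pile of capsule-shaped pellets with known ground truth.

    ``overlap`` bounds the fraction of a new pellet's area allowed to
    cover already-placed pellets (rejection sampling with bounded
    retries); ``standing_fraction`` is the probability a pellet stands on
    end and projects as a disc of its diameter.  Each pellet carries a
    slightly darker rim (``rim_width_px`` wide, ``rim_depth`` fractional
    darkening) so pellets lying on top of each other keep a visible seam
    instead of merging into one large bright blob — as in the real
    near-shadowless dishes, where the structure of the constituent
    pellets of a cluster stays visible.  Deterministic for a fixed
    population (the population carries the seed).
    """
    if not (0.0 <= overlap <= 1.0):
        raise ValueError("overlap must be in [0, 1]")
    h, w = image_shape
    rng = np.random.default_rng(pop.seed)
    img = np.full((h, w), background, dtype=float)
    foreground = np.zeros((h, w), dtype=bool)
    rows: list[dict] = []

    for _ in range(pop.count):
        diameter = max(rng.normal(pop.diameter_mean, pop.diameter_sd), 0.2 * pop.diameter_mean)
        length = max(rng.normal(pop.length_mean, pop.length_sd), diameter)
        d_px = diameter / mm_per_pixel
        l_px = length / mm_per_pixel
        if d_px >= min(h, w) or l_px >= min(h, w):
            raise ValueError("pellet larger than the image frame")
        standing = bool(rng.random() < standing_fraction)
        radius = d_px / 2.0
        half_span = 0.0 if standing else max(l_px / 2.0 - radius, 0.0)
        albedo = float(np.clip(rng.normal(albedo_mean, albedo_sd), 80.0, 255.0))

        placed = False
        for _attempt in range(60):
            angle = float(rng.uniform(0.0, math.pi))
            reach = half_span + radius + 1.0
            r0 = float(rng.uniform(reach, h - reach)) if h > 2 * reach else h / 2.0
            c0 = float(rng.uniform(reach, w - reach)) if w > 2 * reach else w / 2.0
            rs, cs, dist = _capsule_distance((h, w), (r0, c0), angle, half_span, radius + 2.0)
            alpha = np.clip(0.5 + (radius - dist) / max(edge_softness, 1e-6), 0.0, 1.0)
            core = alpha > 0.5
            area = core.sum()
            if area == 0:
                continue
            covered = (core & foreground[rs, cs]).sum() / area
            if covered > overlap:
                continue
            # darker rim near the capsule boundary keeps seams visible
            rim = np.clip((radius - dist) / max(rim_width_px, 1e-6), 0.0, 1.0)
            shade = albedo * (1.0 - rim_depth * (1.0 - rim))
            img[rs, cs] = img[rs, cs] * (1.0 - alpha) + shade * alpha
            foreground[rs, cs] |= core
            rows.append(
                {
                    "row_px": r0,
                    "col_px": c0,
                    "angle_rad": angle,
                    "width_px": d_px,
                    "length_px": d_px if standing else l_px,
                    "standing": float(standing),
                }
            )
            placed = True
            break
        if not placed:  # dense pile: drop the pellet rather than loop forever
            continue

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)
    truth = SceneTruth(pd.DataFrame(rows, columns=list(TRUTH_COLUMNS)) if rows else _empty_truth())
    return CalibratedImage(img, mm_per_pixel), truth


def render_binary_discs(
    radius: int,
    count: int,
    image_shape: tuple[int, int] = (192, 256),
    seed: int = 0,
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    min_gap: int | None = None,
) -> tuple[CalibratedImage, SceneTruth]:
    """Oracle fixture: disjoint exact digital discs at 255 on a 0 background.

    Disc centres are rejection-sampled so discs stay well separated
    (``min_gap`` pixels between footprints, default 2·radius + 4) and the
    opening at any radius treats each disc independently.
    """
    from .elements import euclidean_disk  # local import avoids a cycle

    if count < 0:
        raise ValueError("count must be non-negative")
    h, w = image_shape
    rng = np.random.default_rng(seed)
    img = np.zeros((h, w), dtype=float)
    if count == 0:
        return CalibratedImage(img, mm_per_pixel), SceneTruth(_empty_truth())
    fp = euclidean_disk(radius).footprint
    gap = (2 * radius + 4) if min_gap is None else min_gap
    centers: list[tuple[int, int]] = []
    for _ in range(count):
        for _attempt in range(400):
            r0 = int(rng.integers(radius + 1, h - radius - 1))
            c0 = int(rng.integers(radius + 1, w - radius - 1))
            if all(max(abs(r0 - r), abs(c0 - c)) >= 2 * radius + gap for r, c in centers):
                centers.append((r0, c0))
                break
        else:
            raise RuntimeError(
                f"could not place {count} disjoint discs of radius {radius} "
                f"in a {h}x{w} frame"
            )
    for r0, c0 in centers:
        img[r0 - radius : r0 + radius + 1, c0 - radius : c0 + radius + 1][fp] = 255.0
    truth = SceneTruth(
        pd.DataFrame(
            {
                "row_px": [r for r, _ in centers],
                "col_px": [c for _, c in centers],
                "angle_rad": 0.0,
                "width_px": float(2 * radius + 1),
                "length_px": float(2 * radius + 1),
                "standing": 1.0,
            }
        )
    )
    return CalibratedImage(img, mm_per_pixel), truth


def render_batch(
    drift: BatchDrift,
    image_shape: tuple[int, int] = (600, 800),
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    **pile_kwargs,
) -> list[tuple[float, CalibratedImage, SceneTruth]]:
    """One scene per sampling time of a drifting batch (seeded)."""
    rng = np.random.default_rng(drift.start_population.seed)
    out = []
    for t in drift.sampling_times:
        pop_t = drift.population_at(t, rng)
        img, truth = render_pile(pop_t, image_shape, mm_per_pixel, **pile_kwargs)
        out.append((float(t), img, truth))
    return out


def _preset_drift(
    nominal_mm: float,
    stop_over_start: float,
    total_min: float,
    times: tuple[float, ...],
    rel_sd: float,
    seed: int,
    count: int,
) -> BatchDrift:
    # image-domain drift: nominal start size, relative start→stop growth
    # of the projected size under a ln(1+t) trend
    growth = nominal_mm * (stop_over_start - 1.0) / math.log1p(total_min)
    start = PelletPopulation(
        diameter_mean=nominal_mm,
        diameter_sd=rel_sd * nominal_mm,
        length_mean=1.5 * nominal_mm,
        length_sd=1.5 * rel_sd * nominal_mm,
        count=count,
        seed=seed,
    )
    return BatchDrift(
        start_population=start,
        diameter_growth=growth,
        length_growth=1.5 * growth,
        sampling_times=times,
        noise_sd=0.01 * nominal_mm,
    )


def batch_c_drift(seed: int = 0, count: int = 2400) -> BatchDrift:
    """1.1 mm product sampled every 5 min for 50 min (11 observations).

    The start size is the nominal product diameter; the relative drift of
    the projected size reproduces the image-measured opening-diameter
    increase of such a batch (1.008 → 1.152 mm, i.e. ×8/7) under a
    ln(1+t) trend.  Relative size spread follows the calliper spread
    (≈4.3 %); pellet length defaults to 1.5× the diameter (typical
    extruded-feed aspect ratio).
    """
    return _preset_drift(
        1.1, 8.0 / 7.0, 50.0,
        tuple(float(t) for t in range(0, 55, 5)),
        0.043, seed, count,
    )


def batch_d_drift(seed: int = 0, count: int = 360) -> BatchDrift:
    """3.0 mm product, 27 observations over 45 min.

    Start at the nominal 3.0 mm with the image-measured relative drift
    ×25/21 (opening diameter 3.024 → 3.600 mm) and ≈4.5 % relative
    spread.
    """
    times = tuple(float(round(x, 3)) for x in np.linspace(0.0, 45.0, 27))
    return _preset_drift(3.0, 25.0 / 21.0, 45.0, times, 0.045, seed, count)
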