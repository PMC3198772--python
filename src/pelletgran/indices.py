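"""Scalar size indices, millimetre calibration and series comparison.

A single image yields an opening intensity curve; a production batch
yields one curve per sampling time.  Each curve is summarised by a scalar
size index — the mean or median of the curve, or the opening intensity at
the pattern-spectrum maximum (APM) — and by the interquartile range (IQR)
of the curve as a spread/variation measure.  Tracking the index over
batch time reveals the size drift of the extruded pellets, which tends to
follow a logarithmic trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .granulometry import GranulometryCurve, PatternSpectrum, spectrum_peak

__all__ = [
    "SizeIndexSeries",
    "TrendLine",
    "index_mean",
    "index_median",
    "index_apm",
    "index_iqr",
    "compute_index",
    "radius_to_diameter_mm",
    "normalize_series",
    "fit_trend",
    "compare_series",
    "INDEX_METHODS",
]

INDEX_METHODS = ("mean", "median", "apm", "iqr")


@dataclass(frozen=True)
class SizeIndexSeries:
    """One size index tracked over batch time (minutes from batch start)."""

    times: np.ndarray
    values: np.ndarray
    method: str
    units: str = "intensity"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or len(t) == 0:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(v).all():
            raise ValueError("index values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TrendLine:
    """Least-squares trend of a size-index series.

    ``linear``: value ≈ intercept + slope·t.
    ``logarithmic``: value ≈ intercept + slope·ln(1 + t) (defined for
    t ≥ 0, matching the logarithmic drift of extruder batches).
    """

    form: str
    intercept: float
    slope: float
    fit_domain: tuple[float, float]

    def predict(self, times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        x = np.log1p(t) if self.form == "logarithmic" else t
        return self.intercept + self.slope * x


def index_mean(curve: GranulometryCurve) -> float:
    """Arithmetic mean of the opening intensities."""
    return float(np.mean(curve.intensities))


def index_median(curve: GranulometryCurve) -> float:
    """Median of the opening intensities (midpoint rule for even length);
    the robust choice customary in statistical process control."""
    return float(np.median(curve.intensities))


def index_apm(curve: GranulometryCurve, ps: PatternSpectrum) -> float:
    """Opening intensity at the pattern-spectrum maximum (APM).

    ``ps`` must have been computed from ``curve``; on a flat (degenerate)
    spectrum the tie-break selects the smallest radius.
    """
    base = curve.radii[:-1]
    plain = np.array_equal(ps.radii, base)
    with_initial = (
        len(ps.radii) == len(base) + 1
        and ps.radii[0] == 0
        and np.array_equal(ps.radii[1:], base)
    )
    if not (plain or with_initial):
        raise ValueError("pattern spectrum radii do not match the curve")
    peak = spectrum_peak(ps)
    if peak == 0:  # include_initial bin: everything finer than the first radius
        peak = int(curve.radii[0])
    return float(curve.intensities[curve.radii == peak][0])


def index_iqr(curve: GranulometryCurve) -> float:
    """Interquartile range (Q3 − Q1, linear-interpolation quantiles) of
    the opening intensities: a size-variation measure."""
    if len(curve) < 4:
        raise ValueError("IQR needs a curve with at least 4 radii")
    q1, q3 = np.percentile(curve.intensities, [25, 75])
    return float(q3 - q1)


def compute_index(
    method: str, curve: GranulometryCurve, ps: PatternSpectrum | None = None
) -> float:
    """Dispatch one of the index methods by name."""
    if method == "mean":
        return index_mean(curve)
    if method == "median":
        return index_median(curve)
    if method == "iqr":
        return index_iqr(curve)
    if method == "apm":
        if ps is None:
            raise ValueError("APM needs the pattern spectrum of the curve")
        return index_apm(curve, ps)
    raise ValueError(f"unknown index method {method!r}")


def radius_to_diameter_mm(radius: float, mm_per_pixel: float) -> float:
    """Convert an opening radius in pixels to an object diameter in mm
    (2 · radius · mm/px); e.g. radius 21 at 0.072 mm/px → 3.024 mm."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if not (mm_per_pixel > 0):
        raise ValueError("mm_per_pixel must be positive")
    return 2.0 * radius * mm_per_pixel


def normalize_series(series: SizeIndexSeries, reference_mean: float) -> SizeIndexSeries:
    """Rescale a series by one multiplicative factor so its mean equals a
    reference (e.g. the mean calliper diameter), putting the index on a
    millimetre scale.  Correlations with other series are unchanged."""
    if not (reference_mean > 0):
        raise ValueError("reference_mean must be positive")
    mean = series.values.mean()
    if mean == 0:
        raise ValueError("cannot normalise a zero-mean series")
    return replace(
        series, values=series.values * (reference_mean / mean), units="mm"
    )


def fit_trend(series: SizeIndexSeries, form: str = "logarithmic") -> TrendLine:
    """Least-squares linear or logarithmic (in ln(1+t)) trend line."""
    if form not in ("linear", "logarithmic"):
        raise ValueError(f"unknown trend form {form!r}")
    if len(series) < 3:
        raise ValueError("trend fitting needs at least 3 points")
    t = series.times
    if form == "logarithmic" and np.any(t < 0):
        raise ValueError("logarithmic trend requires times >= 0")
    x = np.log1p(t) if form == "logarithmic" else t
    design = np.column_stack([np.ones_like(x), x])
    (intercept, slope), *_ = np.linalg.lstsq(design, series.values, rcond=None)
    return TrendLine(form, float(intercept), float(slope), (float(t[0]), float(t[-1])))


def compare_series(
    a: SizeIndexSeries, b: SizeIndexSeries
) -> tuple[float, float]:
    """Pearson correlation and RMSE between two time-aligned series.

    RMSE is meaningful on a common (e.g. millimetre-normalised) scale.
    With zero variance in either series the correlation is undefined and
    reported as NaN.
    """
    if len(a) != len(b):
        raise ValueError("series lengths differ")
    if len(a) < 2:
        raise ValueError("need at least 2 points to compare")
    if not np.allclose(a.times, b.times):
        raise ValueError("series sampling times do not match")
    va, vb = a.values, b.values
    rmse = float(np.sqrt(np.mean((va - vb) ** 2)))
    if va.std() == 0 or vb.std() == 0:
        return (math.nan, rmse)
    corr = float(np.corrcoef(va, vb)[0, 1])
    return (corr, rmse)
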