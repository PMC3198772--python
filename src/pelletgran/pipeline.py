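"""End-to-end analysis: image → granulometry → size indices → series.

This is the library face of the monitoring tool: :func:`analyze_image`
runs the full single-image pipeline (optional CLAHE, opening curve over a
nested disk family, pattern spectrum, peak size in mm, scalar indices)
and :func:`monitor_series` assembles per-time index series for a batch,
fits trend lines and compares against reference (calliper) measurements.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elements import StructuringElement, disk_family
from .granulometry import (
    GranulometryCurve,
    PatternSpectrum,
    curve_derivative,
    opening_curve,
    pattern_spectrum,
    spectrum_peak,
)
from .image import CalibratedImage, ClaheConfig, apply_clahe
from .indices import (
    INDEX_METHODS,
    SizeIndexSeries,
    TrendLine,
    compare_series,
    compute_index,
    fit_trend,
    normalize_series,
    radius_to_diameter_mm,
)

logger = logging.getLogger("pelletgran")

__all__ = ["AnalysisConfig", "ImageResult", "analyze_image", "monitor_series", "MonitorResult"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tool-wide analysis settings."""

    mm_per_pixel: float = 0.072
    max_radius: int = 30
    min_radius: int = 1
    element_kind: str = "disk_decomposable"
    clahe: ClaheConfig | None = ClaheConfig()
    index_methods: tuple[str, ...] = ("mean", "median", "apm", "iqr")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_radius < 2:
            raise ValueError("max_radius must be >= 2")
        if not (self.mm_per_pixel > 0):
            raise ValueError("mm_per_pixel must be positive")
        unknown = set(self.index_methods) - set(INDEX_METHODS)
        if unknown:
            raise ValueError(f"unknown index methods {sorted(unknown)}")

    def family(self) -> list[StructuringElement]:
        return disk_family(self.max_radius, self.element_kind, self.min_radius)


@dataclass(frozen=True)
class ImageResult:
    """Everything the pipeline computes for one image."""

    curve: GranulometryCurve
    derivative: np.ndarray
    spectrum: PatternSpectrum | None
    peak_radius: int
    peak_effective_radius: float
    peak_diameter_mm: float
    indices: dict[str, float]
    degenerate: bool
    elapsed_s: float

    def as_table(self) -> pd.DataFrame:
        """Long-format per-radius table (plot-ready)."""
        n = len(self.curve)
        ps = np.full(n, np.nan)
        if self.spectrum is not None:
            ps[: n - 1] = self.spectrum.values[-(n - 1):]
        deriv = np.concatenate([self.derivative, [np.nan]])
        return pd.DataFrame(
            {
                "radius_px": self.curve.radii,
                "effective_radius_px": self.curve.effective_radii,
                "intensity": self.curve.intensities,
                "derivative": deriv,
                "ps_value": ps,
            }
        )

    def summary(self) -> dict:
        return {
            "total_intensity": self.curve.total_intensity,
            "peak_radius_px": self.peak_radius,
            "peak_effective_radius_px": self.peak_effective_radius,
            "peak_diameter_mm": self.peak_diameter_mm,
            "indices": dict(self.indices),
            "degenerate": self.degenerate,
            "elapsed_s": self.elapsed_s,
        }


def analyze_image(
    img: CalibratedImage,
    config: AnalysisConfig,
    family: list[StructuringElement] | None = None,
) -> ImageResult:
    """Run the single-image pipeline.

    A blank (zero-intensity) image is analysed with a degenerate flag:
    the spectrum is undefined, the peak falls back to the smallest radius
    and the indices are still emitted.
    """
    t0 = time.perf_counter()
    if config.clahe is not None:
        img = apply_clahe(img, config.clahe)
    family = family if family is not None else config.family()
    curve = opening_curve(img, family)
    deriv = curve_derivative(curve)

    degenerate = curve.total_intensity <= 0
    spectrum: PatternSpectrum | None = None
    if not degenerate:
        spectrum = pattern_spectrum(curve)
        degenerate = spectrum.is_degenerate
        peak = spectrum_peak(spectrum)
    else:
        peak = int(curve.radii[0])

    idx = int(np.nonzero(curve.radii == peak)[0][0])
    peak_eff = float(curve.effective_radii[idx])
    indices: dict[str, float] = {}
    for method in config.index_methods:
        if method == "apm" and spectrum is None:
            indices[method] = float(curve.intensities[0])
        else:
            indices[method] = compute_index(method, curve, spectrum)
    elapsed = time.perf_counter() - t0
    logger.info(
        "analyzed image: element=%s radii=%d..%d peak=%d px (eff %.2f px, %.3f mm) in %.2fs",
        config.element_kind,
        curve.radii[0],
        curve.radii[-1],
        peak,
        peak_eff,
        radius_to_diameter_mm(peak_eff, config.mm_per_pixel),
        elapsed,
    )
    return ImageResult(
        curve=curve,
        derivative=deriv,
        spectrum=spectrum,
        peak_radius=peak,
        peak_effective_radius=peak_eff,
        peak_diameter_mm=radius_to_diameter_mm(peak, config.mm_per_pixel),
        indices=indices,
        degenerate=degenerate,
        elapsed_s=elapsed,
    )


@dataclass(frozen=True)
class MonitorResult:
    """Index series, trend fits, and optional reference comparison."""

    series: dict[str, SizeIndexSeries]
    trends: dict[str, TrendLine]
    reference: pd.DataFrame | None = None
    comparisons: dict[str, dict[str, float]] = field(default_factory=dict)


def _batch_apm(results: list[ImageResult]) -> np.ndarray | None:
    """APM series at the batch reference position.

    Tracked over a batch, the APM index reads every sample's opening
    intensity at one common radius: the maximum of the batch-averaged
    pattern spectrum.  A per-sample argmax would jump between adjacent
    radii whose intensities differ by the largest spectrum bin, burying
    the drift signal under a sawtooth; anchoring the position at the
    batch level keeps APM a smooth function of pellet size (per-sample
    peak locations remain available as ``ImageResult.peak_radius``).
    """
    spectra = [res.spectrum for res in results]
    if len(results) < 2 or any(s is None for s in spectra):
        return None
    radii0 = spectra[0].radii
    if not all(np.array_equal(s.radii, radii0) for s in spectra):
        return None
    mean_ps = np.mean([s.values for s in spectra], axis=0)
    ref = int(radii0[int(np.argmax(mean_ps))])
    out = []
    for res in results:
        idx = np.nonzero(res.curve.radii == ref)[0][0]
        out.append(float(res.curve.intensities[idx]))
    return np.asarray(out)


def monitor_series(
    times: list[float],
    results: list[ImageResult],
    methods: tuple[str, ...] = ("mean", "median", "apm", "iqr"),
    trend_form: str = "logarithmic",
    reference: pd.DataFrame | None = None,
) -> MonitorResult:
    """Assemble per-method size-index series over a batch.

    ``reference`` is an optional calliper table with columns ``time``,
    ``length`` and ``diameter`` (mm, one aggregated row per sampling
    time); indices are compared against the calliper diameter and the
    calliper area (length × diameter), reporting Pearson correlation and,
    on a calliper-normalised mm scale, RMSE against the diameter.
    """
    if len(times) != len(results):
        raise ValueError("times and results must align")
    order = np.argsort(times)
    times_arr = np.asarray(times, dtype=float)[order]
    results = [results[i] for i in order]

    apm_values = _batch_apm(results)
    series: dict[str, SizeIndexSeries] = {}
    trends: dict[str, TrendLine] = {}
    for method in methods:
        if method == "apm" and apm_values is not None:
            values = apm_values
        else:
            values = np.array([res.indices[method] for res in results])
        s = SizeIndexSeries(times_arr, values, method)
        series[method] = s
        if len(s) >= 3:
            trends[method] = fit_trend(s, trend_form)
        else:
            logger.info("trend fitting skipped for %s: fewer than 3 samples", method)

    comparisons: dict[str, dict[str, float]] = {}
    if reference is not None:
        ref = reference.sort_values("time").reset_index(drop=True)
        if not np.allclose(ref["time"].to_numpy(dtype=float), times_arr):
            raise ValueError("reference sampling times do not match the series")
        diam = SizeIndexSeries(times_arr, ref["diameter"].to_numpy(dtype=float), "mean", "mm")
        area_vals = (ref["length"] * ref["diameter"]).to_numpy(dtype=float)
        area = SizeIndexSeries(times_arr, area_vals, "mean", "mm2")
        for method, s in series.items():
            corr_area, _ = compare_series(s, area)
            corr_diam, _ = compare_series(s, diam)
            s_mm = normalize_series(s, float(diam.values.mean()))
            _, rmse_mm = compare_series(s_mm, diam)
            comparisons[method] = {
                "corr_calliper_area": corr_area,
                "corr_calliper_diameter": corr_diam,
                "rmse_mm": rmse_mm,
            }
        return MonitorResult(series, trends, ref, comparisons)
    return MonitorResult(series, trends)
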