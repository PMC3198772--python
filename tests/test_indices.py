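import math

import numpy as np
import pytest
from scipy import stats

from pelletgran import (
    GranulometryCurve,
    PelletPopulation,
    SizeIndexSeries,
    compare_series,
    disk_family,
    fit_trend,
    index_apm,
    index_iqr,
    index_mean,
    index_median,
    normalize_series,
    opening_curve,
    pattern_spectrum,
    radius_to_diameter_mm,
    render_pile,
)


def curve_of(intensities, total=None):
    vals = np.asarray(intensities, dtype=float)
    total = float(vals.max() if total is None else total)
    n = len(vals)
    return GranulometryCurve(
        radii=np.arange(1, n + 1),
        effective_radii=np.arange(1, n + 1, dtype=float),
        intensities=vals,
        total_intensity=total,
    )


class TestScalarIndices:
    def test_mean_and_median_examples(self):
        assert index_mean(curve_of([10, 10, 10])) == 10
        assert index_mean(curve_of([12, 6, 0])) == 6
        assert index_median(curve_of([12, 6, 0])) == 6
        assert index_median(curve_of([12, 8, 6, 0])) == 7  # even-length midpoint

    def test_iqr_linear_interpolation_rule(self):
        assert index_iqr(curve_of([0, 1, 2, 3, 4])) == 2.0
        assert index_iqr(curve_of([5, 5, 5, 5])) == 0.0
        with pytest.raises(ValueError):
            index_iqr(curve_of([3, 2, 1]))

    def test_apm_returns_intensity_at_spectrum_peak(self, disc_scene):
        img, _ = disc_scene
        curve = opening_curve(img, disk_family(8, "disk_exact"))
        ps = pattern_spectrum(curve)
        assert index_apm(curve, ps) == curve.intensities[curve.radii == 5][0]

    def test_apm_on_flat_spectrum_uses_smallest_radius(self):
        curve = curve_of([9, 9, 9, 9])
        ps = pattern_spectrum(curve)
        assert ps.is_degenerate
        assert index_apm(curve, ps) == 9  # == total: opening left the image unchanged

    def test_apm_radius_mismatch_rejected(self):
        a, b = curve_of([9, 8, 7, 6]), curve_of([9, 8, 7])
        with pytest.raises(ValueError):
            index_apm(a, pattern_spectrum(b))


class TestCalibration:
    @pytest.mark.parametrize(
        "radius,mm",
        [(7, 1.008), (9, 1.296), (8, 1.152), (21, 3.024), (25, 3.600), (0, 0.0)],
    )
    def test_radius_to_diameter_reference_rig(self, radius, mm):
        assert radius_to_diameter_mm(radius, 0.072) == pytest.approx(mm, abs=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            radius_to_diameter_mm(-1, 0.072)


def series(values, times=None, method="mean"):
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values), dtype=float) if times is None else np.asarray(times, float)
    return SizeIndexSeries(times, values, method)


class TestNormalize:
    def test_scaling_examples(self):
        assert np.allclose(normalize_series(series([2, 4, 6]), 4.0).values, [2, 4, 6])
        out = normalize_series(series([1, 2, 3]), 4.0)
        assert np.allclose(out.values, [2, 4, 6])
        assert out.values.mean() == pytest.approx(4.0)
        assert out.units == "mm"

    def test_normalisation_preserves_correlation_exactly(self):
        rng = np.random.default_rng(5)
        a = series(rng.normal(10, 2, 8))
        third = series(rng.normal(5, 1, 8))
        before, _ = compare_series(a, third)
        after, _ = compare_series(normalize_series(a, 3.0), third)
        assert after == pytest.approx(before, abs=1e-14)

    def test_zero_mean_series_rejected(self):
        with pytest.raises(ValueError):
            normalize_series(series([-1, 0, 1]), 2.0)


class TestTrend:
    def test_linear_fit_recovers_an_exact_line(self):
        t = np.array([0.0, 5, 10, 15, 20])
        s = series(3.0 + 0.25 * t, times=t)
        tl = fit_trend(s, "linear")
        assert tl.intercept == pytest.approx(3.0)
        assert tl.slope == pytest.approx(0.25)

    def test_logarithmic_fit_generate_then_recover(self):
        t = np.arange(0.0, 55, 5)
        s = series(1.2 + 0.145 * np.log1p(t), times=t)
        tl = fit_trend(s, "logarithmic")
        assert tl.intercept == pytest.approx(1.2, abs=1e-9)
        assert tl.slope == pytest.approx(0.145, abs=1e-9)
        assert np.allclose(tl.predict(t), s.values)

    @pytest.mark.parametrize("form", ["linear", "logarithmic"])
    def test_monotone_series_gives_positive_slope(self, form):
        s = series([1, 2, 4, 4.5, 6])
        assert fit_trend(s, form).slope > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(series([1, 2]), "linear")


class TestCompareSeries:
    def test_identical_and_negated(self):
        a = series([1, 3, 2, 5])
        assert compare_series(a, a) == (pytest.approx(1.0), 0.0)
        neg = series(-a.values)
        corr, _ = compare_series(a, neg)
        assert corr == pytest.approx(-1.0)

    def test_matches_independent_formula_on_noisy_drift(self):
        rng = np.random.default_rng(17)
        t = np.arange(0.0, 55, 5)
        latent = 1.2 + 0.145 * np.log1p(t)
        a = series(latent + rng.normal(0, 0.05, len(t)), times=t)
        b = series(latent + rng.normal(0, 0.05, len(t)), times=t)
        corr, rmse = compare_series(a, b)
        assert corr == pytest.approx(stats.pearsonr(a.values, b.values)[0], abs=1e-12)
        assert rmse == pytest.approx(
            math.sqrt(np.mean((a.values - b.values) ** 2)), abs=1e-12
        )

    def test_zero_variance_reports_missing_correlation(self):
        corr, rmse = compare_series(series([2, 2, 2]), series([1, 2, 3]))
        assert math.isnan(corr)
        assert rmse == pytest.approx(math.sqrt(2 / 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_series(series([1, 2, 3]), series([1, 2]))


class TestDomainProperties:
    def test_moist_and_dry_surrogates_stay_highly_correlated(self):
        """Two noisy observations of the same latent drift, one with the
        small positive offset seen for moist pellets, correlate >= 0.95
        at the batch sampling density."""
        rng = np.random.default_rng(42)
        t = np.arange(0.0, 55, 5)
        latent = 1.236 + 0.145 * np.log1p(t)
        dry = series(latent + rng.normal(0, 0.02, len(t)), times=t)
        moist = series(latent + 0.05 + rng.normal(0, 0.02, len(t)), times=t)
        corr, _ = compare_series(moist, dry)
        assert corr >= 0.95

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_indices_grow_with_pellet_scale(self, seed):
        """Piles differing only in pellet scale: mean, median and APM are
        all larger for the larger pellets."""
        family = disk_family(14)
        values = {}
        for scale in (1.0, 1.35):
            pop = PelletPopulation(
                1.1 * scale, 0.05, 1.65 * scale, 0.08, count=15, seed=seed
            )
            img, _ = render_pile(pop, (192, 256), overlap=0.0, standing_fraction=0.0)
            curve = opening_curve(img, family)
            ps = pattern_spectrum(curve)
            values[scale] = (
                index_mean(curve),
                index_median(curve),
                index_apm(curve, ps),
            )
        small, large = values[1.0], values[1.35]
        assert all(l > s for s, l in zip(small, large))
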