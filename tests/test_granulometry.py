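import numpy as np
import pytest
from _oracles import brute_dilate, brute_erode, brute_open, loop_erode

from pelletgran import (
    CalibratedImage,
    PatternSpectrum,
    comparison_element,
    curve_derivative,
    decomposable_disk,
    dilate,
    disk_family,
    erode,
    euclidean_disk,
    open_image,
    opening_curve,
    pattern_spectrum,
    spectrum_peak,
)


def make(pixels, mm=0.072):
    return CalibratedImage(np.asarray(pixels, dtype=float), mm)


ELEMENTS = [
    euclidean_disk(1),
    euclidean_disk(2),
    euclidean_disk(3),
    decomposable_disk(3),
    comparison_element("diamond", 2),
    comparison_element("octagon", 3),
]


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("se", ELEMENTS, ids=lambda s: f"{s.kind}-r{s.nominal_radius}")
def test_flat_morphology_matches_direct_evaluation(seed, se, random_image):
    """Erosion, dilation and opening agree pixel-exactly with a direct
    from-the-definition evaluation on random images."""
    img = random_image(seed)
    assert np.array_equal(erode(img, se).pixels, brute_erode(img.pixels, se.footprint))
    assert np.array_equal(dilate(img, se).pixels, brute_dilate(img.pixels, se.footprint))
    assert np.array_equal(open_image(img, se).pixels, brute_open(img.pixels, se.footprint))


def test_erosion_matches_nested_loop_minimum_on_small_fixture():
    rng = np.random.default_rng(3)
    px = np.zeros((7, 7))
    px[2:5, 2:5] = 200.0
    px += rng.integers(0, 20, size=px.shape)
    se = comparison_element("diamond", 1)
    assert np.array_equal(erode(make(px), se).pixels, loop_erode(px, se.footprint))


def test_constant_image_is_a_fixed_point_including_borders():
    img = make(np.full((15, 15), 42.0))
    for se in (euclidean_disk(3), decomposable_disk(5)):
        assert np.array_equal(erode(img, se).pixels, img.pixels)
        assert np.array_equal(dilate(img, se).pixels, img.pixels)
        assert np.array_equal(open_image(img, se).pixels, img.pixels)


def test_single_bright_pixel():
    px = np.zeros((11, 11))
    px[5, 5] = 200.0
    eroded = erode(make(px), euclidean_disk(1))
    assert not eroded.pixels.any()
    dilated = dilate(make(px), euclidean_disk(2))
    assert (dilated.pixels == 200.0).sum() == 13
    assert dilated.pixels.sum() == 13 * 200.0


def test_opening_is_anti_extensive_increasing_and_idempotent(random_image):
    img = random_image(9)
    se = euclidean_disk(2)
    opened = open_image(img, se)
    assert np.all(opened.pixels <= img.pixels)
    again = open_image(opened, se)
    assert np.array_equal(again.pixels, opened.pixels)
    brighter = img.with_pixels(np.minimum(img.pixels + 30.0, 255.0))
    assert np.all(open_image(brighter, se).pixels >= opened.pixels)


def test_disc_survives_its_own_radius_and_vanishes_beyond():
    r = 5
    px = np.zeros((21, 21))
    fp = euclidean_disk(r).footprint
    px[10 - r : 10 + r + 1, 10 - r : 10 + r + 1][fp] = 255.0
    img = make(px)
    assert np.array_equal(open_image(img, euclidean_disk(r)).pixels, px)
    assert not open_image(img, euclidean_disk(r + 1)).pixels.any()


def test_sieving_composition_for_the_decomposable_family(random_image):
    """open(open(f, small), large) == open(f, large) for Minkowski-chain disks."""
    img = random_image(21, shape=(40, 40))
    small, large = decomposable_disk(2), decomposable_disk(6)
    lhs = open_image(open_image(img, small), large)
    rhs = open_image(img, large)
    assert np.array_equal(lhs.pixels, rhs.pixels)


def test_footprint_larger_than_image_rejected():
    with pytest.raises(ValueError):
        erode(make(np.zeros((5, 5))), euclidean_disk(4))


class TestOpeningCurve:
    def test_constant_image_curve_is_flat_at_total(self):
        img = make(np.full((30, 30), 10.0))
        curve = opening_curve(img, disk_family(4))
        assert curve.total_intensity == 9000.0
        assert np.all(curve.intensities == 9000.0)

    def test_disjoint_disc_fixture(self, disc_scene):
        img, _ = disc_scene
        curve = opening_curve(img, disk_family(8, "disk_exact"))
        expected = 3 * 255.0 * 81
        assert curve.intensities[curve.radii == 5][0] == expected
        assert np.all(curve.intensities[curve.radii > 5] == 0.0)
        assert curve.intensities[-1] <= curve.intensities[0]

    def test_decomposable_family_curve_is_monotone(self, pellet_pile):
        img, _ = pellet_pile
        curve = opening_curve(img, disk_family(12))
        assert np.all(np.diff(curve.intensities) <= 0)

    def test_non_nested_family_rejected(self, random_image):
        from pelletgran.elements import StructuringElement

        line = np.zeros((9, 9), dtype=bool)
        line[4, :] = True  # radius-4 horizontal line cannot contain disk(3)
        family = [euclidean_disk(3), StructuringElement(line, 4, "disk_exact")]
        with pytest.raises(ValueError):
            opening_curve(random_image(0), family)


class TestDerivativeAndSpectrum:
    def test_derivative_telescopes(self, disc_scene):
        img, _ = disc_scene
        curve = opening_curve(img, disk_family(8, "disk_exact"))
        deriv = curve_derivative(curve)
        assert deriv.sum() == curve.intensities[-1] - curve.intensities[0]
        # the discs vanish between radius 5 and 6: dominant negative step
        assert np.argmin(deriv) == np.nonzero(curve.radii == 5)[0][0]

    def test_derivative_needs_two_radii(self):
        img = make(np.full((20, 20), 5.0))
        curve = opening_curve(img, disk_family(2, min_radius=2))
        with pytest.raises(ValueError):
            curve_derivative(curve)

    def test_spectrum_telescoping_sum_is_exact(self, pellet_pile):
        img, _ = pellet_pile
        curve = opening_curve(img, disk_family(12))
        ps = pattern_spectrum(curve)
        assert len(ps) == len(curve) - 1
        assert np.all(ps.values >= 0)
        expected = (curve.intensities[0] - curve.intensities[-1]) / curve.total_intensity
        assert ps.values.sum() == pytest.approx(expected, abs=0, rel=1e-12)
        assert ps.values.sum() <= 1.0 + 1e-12

    def test_spectrum_with_initial_bin_sums_to_one_when_image_empties(self, disc_scene):
        img, _ = disc_scene
        curve = opening_curve(img, disk_family(8, "disk_exact"))
        ps = pattern_spectrum(curve, include_initial=True)
        assert ps.radii[0] == 0
        assert ps.values.sum() == pytest.approx(1.0)

    def test_constant_image_spectrum_is_all_zero_and_degenerate(self):
        img = make(np.full((30, 30), 10.0))
        ps = pattern_spectrum(opening_curve(img, disk_family(5)))
        assert not ps.values.any()
        assert ps.is_degenerate
        assert spectrum_peak(ps) == 1  # tie-break toward the smallest radius

    def test_zero_total_intensity_rejected(self):
        img = make(np.zeros((20, 20)))
        with pytest.raises(ValueError):
            pattern_spectrum(opening_curve(img, disk_family(3)))

    def test_peak_location_and_tie_break(self, disc_scene):
        img, _ = disc_scene
        ps = pattern_spectrum(opening_curve(img, disk_family(8, "disk_exact")))
        assert spectrum_peak(ps) == 5
        tied = PatternSpectrum(np.array([2, 4, 7, 9]), np.array([0.1, 0.4, 0.2, 0.4]))
        assert spectrum_peak(tied) == 4
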