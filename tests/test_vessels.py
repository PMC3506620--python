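"""Binarization, density, region selection, and diameter measurement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from choromorph import enface, rpe, synthetic, vessels
from choromorph.enface import EnFaceSlab


def make_slab(image: np.ndarray, pitch_x=11.71875, pitch_y=46.875) -> EnFaceSlab:
    return EnFaceSlab(
        image=np.asarray(image, dtype=np.uint8),
        depth_offset_um=10.0,
        thickness_um=2.0,
        pitch_x_um=pitch_x,
        pitch_y_um=pitch_y,
    )


def brute_force_density(mask: np.ndarray) -> float:
    count = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            count += bool(mask[i, j])
    return count / mask.size


def brute_force_run(mask: np.ndarray, i: int, j: int) -> int:
    length = 0
    k = i
    while k >= 0 and mask[k, j]:
        length += 1
        k -= 1
    k = i + 1
    while k < mask.shape[0] and mask[k, j]:
        length += 1
        k += 1
    return length


class TestBinarize:
    def test_threshold_is_inclusive(self):
        slab = make_slab([[64, 65, 66]])
        mask = vessels.binarize(slab, 65)
        assert mask.mask.tolist() == [[True, True, False]]

    def test_bright_slab_has_zero_density(self):
        slab = make_slab(np.full((8, 8), 255))
        assert vessels.vessel_density(vessels.binarize(slab, 110)).density == 0.0

    def test_strict_mask_subset_of_loose(self):
        rng = np.random.default_rng(0)
        slab = make_slab(rng.integers(0, 256, size=(32, 16)))
        strict = vessels.binarize(slab, 65).mask
        loose = vessels.binarize(slab, 110).mask
        assert not (strict & ~loose).any()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 2**31 - 1))
    def test_density_monotone_in_threshold(self, t_low, t_high, seed):
        t_low, t_high = sorted((t_low, t_high))
        slab = make_slab(np.random.default_rng(seed).integers(0, 256, (16, 8)))
        d_low = vessels.vessel_density(vessels.binarize(slab, t_low)).density
        d_high = vessels.vessel_density(vessels.binarize(slab, t_high)).density
        assert d_low <= d_high


class TestDensity:
    def test_fixed_fixture_fraction(self):
        rng = np.random.default_rng(123)
        mask_arr = np.zeros((10, 10), dtype=bool)
        flat = rng.choice(100, size=37, replace=False)
        mask_arr.ravel()[flat] = True
        mask = vessels.VesselMask(mask_arr, 65, 11.71875, 46.875)
        result = vessels.vessel_density(mask)
        assert result.density == pytest.approx(0.37, abs=1e-15)
        assert result.density == pytest.approx(brute_force_density(mask_arr))

    def test_all_vessel_is_one(self):
        mask = vessels.VesselMask(np.ones((4, 4), dtype=bool), 65, 11.71875, 46.875)
        assert vessels.vessel_density(mask).density == 1.0

    def test_region_window_uses_ceiling_convention(self):
        """500x500 um at (11.72, 46.88) um pitches is a 43x11 pixel window."""
        mask_arr = np.zeros((512, 128), dtype=bool)
        mask_arr[:43, :11] = True  # exactly the expected window
        mask = vessels.VesselMask(mask_arr, 65, 11.71875, 46.875)
        result = vessels.vessel_density(mask, (0.0, 0.0), (500.0, 500.0))
        assert result.density == 1.0
        shifted = vessels.vessel_density(mask, (11.72, 0.0), (500.0, 500.0))
        assert shifted.density == pytest.approx(42 / 43)

    def test_region_outside_slab_errors(self):
        mask = vessels.VesselMask(np.ones((43, 11), dtype=bool), 65, 11.71875, 46.875)
        with pytest.raises(ValueError, match="outside"):
            vessels.vessel_density(mask, (100.0, 0.0), (500.0, 500.0))

    def test_full_density_is_weighted_mean_of_partition(self):
        rng = np.random.default_rng(5)
        mask_arr = rng.random((40, 20)) < 0.3
        mask = vessels.VesselMask(mask_arr, 65, 10.0, 10.0)
        full = vessels.vessel_density(mask).density
        parts = []
        for i0 in range(0, 40, 20):
            for j0 in range(0, 20, 10):
                d = vessels.vessel_density(
                    mask, (i0 * 10.0, j0 * 10.0), (200.0, 100.0)
                ).density
                parts.append(d * 200)
        assert full == pytest.approx(sum(parts) / 800, abs=1e-12)


class TestSelectRegion:
    def test_prefers_textured_quadrant(self):
        rng = np.random.default_rng(2)
        image = np.full((128, 64), 180, dtype=np.uint8)
        image[64:, 32:] = rng.choice([40, 180], size=(64, 32))
        slab = make_slab(image, pitch_x=10.0, pitch_y=10.0)
        ox, oy = vessels.select_region(slab, (200.0, 200.0))
        assert ox >= 640.0 and oy >= 320.0

    def test_manual_override_verbatim(self):
        slab = make_slab(np.zeros((64, 32)))
        assert vessels.select_region(slab, manual_origin_um=(123.0, 45.0)) == (123.0, 45.0)

    def test_oversized_region_errors(self):
        slab = make_slab(np.zeros((16, 8)))
        with pytest.raises(ValueError, match="exceeds"):
            vessels.select_region(slab, (10_000.0, 10_000.0))


class TestMeasureDiameter:
    def test_vertical_bar_width(self):
        mask_arr = np.zeros((32, 8), dtype=bool)
        mask_arr[10:15, :] = True  # 5 px wide bar
        mask = vessels.VesselMask(mask_arr, 65, 11.71875, 46.875)
        m = vessels.measure_diameter(mask, (12, 3))
        assert m.diameter_px == 5
        assert m.diameter_um == pytest.approx(5 * 11.71875)

    def test_seed_on_stroma_errors(self):
        mask = vessels.VesselMask(np.zeros((8, 8), dtype=bool), 65, 11.71875, 46.875)
        with pytest.raises(ValueError, match="stroma"):
            vessels.measure_diameter(mask, (2, 2))

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mask_arr = rng.random((32, 32)) < 0.4
            mask = vessels.VesselMask(mask_arr, 65, 11.71875, 46.875)
            assert vessels.vessel_density(mask).density == pytest.approx(
                brute_force_density(mask_arr), abs=1e-15
            )
            seeds = np.argwhere(mask_arr)
            for i, j in seeds[rng.choice(len(seeds), size=min(5, len(seeds)),
                                         replace=False)]:
                measured = vessels.measure_diameter(mask, (i, j)).diameter_px
                assert measured == brute_force_run(mask_arr, i, j)

    def test_recovers_tube_caliber_from_random_seeds(self, small_geometry):
        """~20 random lumen seeds on a rendered slab recover the drawn caliber
        to within one pixel on average."""
        sparse = (
            synthetic.LayerSpec(0.25, 50.0, 8.0, 0.10, max_axial_extent_um=30.0),
            synthetic.LayerSpec(0.35, 100.0, 10.0, 0.10, max_axial_extent_um=60.0),
            synthetic.LayerSpec(0.40, 215.0, 0.0, 0.10, max_axial_extent_um=50.0),
        )
        params = synthetic.default_eye_params(
            "control", seed=17, layer_specs=sparse, **small_geometry
        )
        volume, truth = synthetic.generate_volume(params)
        surface = rpe.segment_rpe(volume)
        slab = enface.extract_slab(volume, surface, truth.layer_offsets_um[2])
        mask = vessels.binarize(slab, 65)
        rng = np.random.default_rng(3)
        seeds = np.argwhere(mask.mask)
        picks = seeds[rng.choice(len(seeds), size=20, replace=False)]
        diameters = [
            vessels.measure_diameter(mask, tuple(p)).diameter_px for p in picks
        ]
        expected_px = truth.per_layer_mean_diameter_um[2] / volume.lateral_pitch_x_um
        assert np.mean(diameters) == pytest.approx(expected_px, abs=1.0)


class TestMagnifiedCoords:
    @pytest.mark.parametrize(
        "point,magnified,original,expected",
        [
            ((760, 760), (760, 760), (644, 644), (644, 644)),
            ((380, 380), (760, 760), (644, 644), (322, 322)),
            ((100, 200), (644, 644), (644, 644), (100, 200)),
        ],
    )
    def test_mapping(self, point, magnified, original, expected):
        assert vessels.map_magnified_coords(point, magnified, original) == expected

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            vessels.map_magnified_coords((1, 1), (0, 10), (5, 5))


class TestSummaries:
    def test_standard_is_mean_of_extremes(self):
        px, um = vessels.summarize_diameters([2.8, 4.0, 6.5], "standard",
                                             pitch_x_um=11.71875)
        assert px == pytest.approx(4.65)
        assert um == pytest.approx(4.65 * 11.71875)

    def test_rpd_is_mean_of_five(self):
        px, _ = vessels.summarize_diameters([3, 5, 7, 9, 11], "rpd", pitch_x_um=1.0)
        assert px == 7.0

    def test_insufficient_measurements_error_names_scheme(self):
        with pytest.raises(ValueError, match="standard"):
            vessels.summarize_diameters([4.0], "standard")
        with pytest.raises(ValueError, match="rpd"):
            vessels.summarize_diameters([1, 2, 3, 4], "rpd")


class TestPixelPitch:
    def test_standard_cube_pitches(self):
        assert vessels.pixel_pitch(6000, 512) == pytest.approx(11.71875)
        assert round(vessels.pixel_pitch(6000, 512), 1) == 11.7
        assert round(vessels.pixel_pitch(6000, 128)) == 47
        assert vessels.pixel_pitch(1000, 1000) == 1.0

    def test_zero_samples_error(self):
        with pytest.raises(ValueError):
            vessels.pixel_pitch(6000, 0)
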