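"""Roughness parameters, levelling, lacuna detection and wear staging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cartafm import (
    HeightMap,
    LacunaSpec,
    Profile,
    RoughnessResult,
    SurfaceSpec,
    UndefinedPeakSpacingError,
    compute_Ra,
    compute_Rp,
    compute_S,
    compute_Sa,
    detect_lacunae,
    extract_profiles,
    generate_height_map,
    level_height_map,
    percent_change,
    stage_wear,
    summarize_roughness,
    wear_stage_bounds,
)

profiles_st = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=64
).map(lambda v: Profile(np.array(v), spacing=1.0))


class TestLeveling:
    def test_pure_plane_levels_to_zero(self):
        x, y = np.meshgrid(np.arange(16.0), np.arange(12.0))
        hmap = HeightMap(2 * x + 3 * y + 7, pixel_size=10.0)
        out = level_height_map(hmap)
        np.testing.assert_allclose(out.heights, 0.0, atol=1e-9)

    def test_residual_recovered_after_adding_plane(self):
        rng = np.random.default_rng(5)
        residual = rng.normal(0, 10, (20, 20))
        residual -= residual.mean()
        # remove any incidental tilt so the stored residual is plane-free
        residual = level_height_map(HeightMap(residual, 1.0)).heights
        x, y = np.meshgrid(np.arange(20.0), np.arange(20.0))
        hmap = HeightMap(residual + 0.7 * x - 1.3 * y + 42, pixel_size=1.0)
        out = level_height_map(hmap)
        rms = np.sqrt(np.mean((out.heights - residual) ** 2))
        assert rms < 1e-9

    def test_idempotence(self):
        rng = np.random.default_rng(11)
        hmap = HeightMap(rng.normal(0, 5, (15, 17)), 2.0)
        once = level_height_map(hmap)
        twice = level_height_map(once)
        np.testing.assert_allclose(twice.heights, once.heights, atol=1e-9)

    def test_constant_map_levels_to_zero_without_error(self):
        out = level_height_map(HeightMap(np.full((8, 8), 5.0), 1.0))
        np.testing.assert_allclose(out.heights, 0.0, atol=1e-9)


class TestExtractProfiles:
    def test_one_profile_per_row_in_order(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=(9, 13))
        hmap = HeightMap(z, pixel_size=4.0)
        profiles = extract_profiles(hmap)
        assert len(profiles) == 9
        for i, p in enumerate(profiles):
            assert p.spacing == 4.0
            np.testing.assert_array_equal(p.y, z[i])


class TestAmplitudeParameters:
    @pytest.mark.parametrize(
        "y, ra, rp",
        [
            ([5.0, 5.0, 5.0, 5.0], 0.0, 0.0),
            ([1.0, -1.0, 1.0, -1.0], 1.0, 1.0),
            ([0.0, 1.0, 2.0, 3.0, 4.0], 1.2, 2.0),  # deviations (2,1,0,1,2)
        ],
    )
    def test_hand_enumerated_Ra_Rp(self, y, ra, rp):
        p = Profile(np.array(y), 1.0)
        assert compute_Ra(p) == pytest.approx(ra)
        assert compute_Rp(p) == pytest.approx(rp)

    def test_sine_Rp_equals_amplitude(self):
        x = np.linspace(0, 4 * 2 * np.pi, 4000, endpoint=False)
        p = Profile(7.5 * np.sin(x), 1.0)
        assert compute_Rp(p) == pytest.approx(7.5, rel=1e-4)

    @given(p=profiles_st, c=st.floats(-50, 50), s=st.floats(0.1, 10))
    @settings(max_examples=60, deadline=None)
    def test_translation_invariance_and_homogeneity(self, p, c, s):
        shifted = Profile(p.y + c, p.spacing)
        scaled = Profile(p.y * s, p.spacing)
        assert compute_Ra(shifted) == pytest.approx(compute_Ra(p), abs=1e-6)
        assert compute_Rp(shifted) == pytest.approx(compute_Rp(p), abs=1e-6)
        assert compute_Ra(scaled) == pytest.approx(abs(s) * compute_Ra(p), rel=1e-9, abs=1e-9)

    @given(p=profiles_st)
    @settings(max_examples=60, deadline=None)
    def test_Ra_and_Rp_bounds(self, p):
        dev = p.y - p.y.mean()
        assert compute_Ra(p) <= np.max(np.abs(dev)) + 1e-12
        assert compute_Rp(p) <= p.y.max() - p.y.min() + 1e-12


class TestPeakSpacing:
    def test_alternating_profile(self):
        p = Profile(np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0]), spacing=10.0)
        assert compute_S(p) == pytest.approx(20.0)  # peaks at 1, 3, 5

    def test_monotone_profile_has_no_peaks(self):
        with pytest.raises(UndefinedPeakSpacingError):
            compute_S(Profile(np.arange(10.0), 1.0))

    def test_sampled_sine_period(self):
        # 10 periods of a 100 nm-period sine, sampled so crests fall on
        # grid points (40 samples/period puts x = 25 nm on the grid)
        n_per_period = 40
        spacing = 100.0 / n_per_period
        x = np.arange(10 * n_per_period) * spacing
        p = Profile(np.sin(2 * np.pi * x / 100.0), spacing=spacing)
        assert compute_S(p) == pytest.approx(100.0, rel=1e-6)

    def test_plateau_collapses_to_first_sample(self):
        p = Profile(np.array([0.0, 2.0, 2.0, 0.0, 3.0, 0.0]), spacing=1.0)
        assert compute_S(p) == pytest.approx(3.0)  # peaks at 1 (plateau start) and 4

    @given(s=st.floats(0.5, 20.0), c=st.floats(0.1, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_scaling_behaviour(self, s, c):
        y = np.array([0.0, 1.0, 0.0, 2.0, 0.0, 1.5, 0.0])
        base = compute_S(Profile(y, 1.0))
        assert compute_S(Profile(c * y, 1.0)) == pytest.approx(base)
        assert compute_S(Profile(y, s)) == pytest.approx(s * base, rel=1e-12)


class TestSa:
    def test_constant_and_alternating_maps(self):
        assert compute_Sa(HeightMap(np.full((6, 6), 3.0), 1.0)) == 0.0
        row = np.tile([1.0, -1.0], 4)
        assert compute_Sa(HeightMap(np.tile(row, (5, 1)), 1.0)) == pytest.approx(1.0)

    def test_equals_Ra_of_flattened_grid(self):
        rng = np.random.default_rng(8)
        z = rng.normal(0, 20, (12, 16))
        hmap = HeightMap(z, 1.0)
        flat = Profile(z.ravel(), 1.0)
        assert compute_Sa(hmap) == pytest.approx(compute_Ra(flat), rel=1e-12)


class TestDetectLacunae:
    def test_flat_map_has_none(self):
        hmap = HeightMap(np.zeros((32, 32)), 10.0)
        assert detect_lacunae(hmap, 100.0) == []

    def test_three_inserted_depressions_recovered(self):
        spec = SurfaceSpec(
            nx=96, ny=96, pixel_size=50.0, target_Ra=5.0, correlation_length=150.0,
            seed=4,
            lacunae=(
                LacunaSpec((1000.0, 1000.0), (400.0, 300.0), 500.0),
                LacunaSpec((2500.0, 2400.0), (350.0, 350.0), 500.0),
                LacunaSpec((3800.0, 1200.0), (300.0, 450.0), 500.0),
            ),
        )
        hmap = level_height_map(generate_height_map(spec))
        regions = detect_lacunae(hmap, depth_threshold=250.0)
        assert len(regions) == 3
        for r in regions:
            assert r.depth_nm == pytest.approx(500.0, rel=0.1)

    def test_count_non_increasing_in_threshold(self):
        spec = SurfaceSpec(
            nx=64, ny=64, pixel_size=50.0, target_Ra=5.0, correlation_length=150.0,
            seed=9, lacunae=(LacunaSpec((1600.0, 1600.0), (400.0, 400.0), 500.0),),
        )
        hmap = level_height_map(generate_height_map(spec))
        counts = [len(detect_lacunae(hmap, thr)) for thr in (100.0, 250.0, 450.0, 600.0)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0  # threshold above the deepest depression


class TestSummarize:
    @pytest.mark.parametrize("n_specimens, expected", [(25, 375), (75, 1125)])
    def test_measurement_counts(self, n_specimens, expected):
        # 5 points x n specimens x 3 scan areas
        grouped = {
            ar: [RoughnessResult(10.0 + i, 50.0, 100.0) for i in range(5 * n_specimens)]
            for ar in ("3x3", "9x9", "18x18")
        }
        assert summarize_roughness(grouped).n_total == expected

    def test_single_result_stats(self):
        summary = summarize_roughness({"9x9": [RoughnessResult(86.0, 436.0, 816.0)]})
        row = summary.table.set_index("parameter").loc["Ra"]
        assert row["mean"] == 86.0
        assert row["sd"] == 0.0
        assert row["min"] == row["max"] == 86.0

    def test_min_mean_max_ordering(self):
        grouped = {"9x9": [RoughnessResult(80.0 + i, 400.0 + i, 800.0 + i) for i in range(10)]}
        t = summarize_roughness(grouped).table
        assert (t["min"] <= t["mean"]).all() and (t["mean"] <= t["max"]).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_roughness({"9x9": []})


class TestPercentChange:
    @pytest.mark.parametrize(
        "healthy, worn, expected", [(86.0, 25.0, 71), (436.0, 86.0, 80), (816.0, 403.0, 51)]
    )
    def test_printed_table_values(self, healthy, worn, expected):
        assert percent_change(healthy, worn) == expected

    def test_identity_gives_zero(self):
        assert percent_change(123.4, 123.4) == 0

    def test_non_positive_healthy_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 10.0)


class TestWearStaging:
    def test_equal_width_tripartition(self):
        b0, b1, b2, b3 = wear_stage_bounds()
        widths = np.diff([b0, b1, b2, b3])
        np.testing.assert_allclose(widths, 12.2, atol=1e-9)
        assert b1 == pytest.approx(36.8)
        assert b2 == pytest.approx(49.0)
        assert (b0, b3) == (24.6, 61.2)

    @pytest.mark.parametrize(
        "ra, label",
        [
            (86.0, "healthy"),
            (73.0, "healthy"),
            (55.0, "small"),
            (40.0, "medium"),
            (30.0, "heavy"),
            (24.6, "heavy"),
            (10.0, "out_of_range"),
            (61.2, "small"),   # boundary falls to the more-worn stage
            (49.0, "medium"),
            (36.8, "heavy"),
        ],
    )
    def test_stage_assignment(self, ra, label):
        assert stage_wear(ra).label == label

    def test_negative_Ra_rejected(self):
        with pytest.raises(ValueError):
            stage_wear(-1.0)

    def test_bounds_are_contiguous(self):
        labels = ["heavy", "medium", "small"]
        prev_hi = 24.6
        for lab, ra in zip(labels, (30.0, 40.0, 55.0)):
            stage = stage_wear(ra)
            assert stage.label == lab
            assert stage.Ra_bounds[0] == pytest.approx(prev_hi)
            prev_hi = stage.Ra_bounds[1]
        assert prev_hi == pytest.approx(61.2)
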