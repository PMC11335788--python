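"""Color conversion, canvas projection, region aggregation, event extraction."""

import numpy as np
import pytest

from pupilkit.video_events import (
    GazeTrace,
    RegionGrid,
    build_canvas,
    downsample_gaze,
    extract_event_traces,
    lightness_to_luminance,
    region_means,
    rgb_to_lightness,
)


def reference_lightness(rgb):
    """Independent CIE 1976 L* oracle: sRGB linearization → XYZ(Y) → L*."""
    srgb = np.asarray(rgb, dtype=float) / 255.0
    lin = np.where(srgb <= 0.04045, srgb / 12.92, ((srgb + 0.055) / 1.055) ** 2.4)
    y = lin @ np.array([0.2126729, 0.7151522, 0.0721750])
    f = np.where(y > (6 / 29) ** 3, np.cbrt(y), y / (3 * (6 / 29) ** 2) + 4 / 29)
    lstar = 116 * f - 16
    return lstar * 255.0 / 100.0


class TestLightness:
    def test_black_and_white_map_to_extremes(self):
        black = np.zeros((4, 4, 3), dtype=np.uint8)
        white = np.full((4, 4, 3), 255, dtype=np.uint8)
        assert np.allclose(rgb_to_lightness(black), 0.0, atol=1e-6)
        assert np.allclose(rgb_to_lightness(white), 255.0, atol=1e-6)

    @pytest.mark.parametrize("rgb", [(100, 150, 200), (30, 30, 30), (255, 0, 0), (12, 200, 99)])
    def test_matches_independent_cie_oracle(self, rgb):
        frame = np.full((2, 2, 3), rgb, dtype=np.uint8)
        got = rgb_to_lightness(frame)
        assert np.all(np.abs(got - reference_lightness(rgb)) <= 1.0)

    def test_rejects_non_rgb_input(self):
        with pytest.raises(ValueError):
            rgb_to_lightness(np.zeros((4, 4), dtype=np.uint8))


class TestGammaCorrection:
    def test_full_scale_maps_to_display_max(self):
        assert lightness_to_luminance(255.0, 2.2, 212.0) == pytest.approx(212.0)
        assert lightness_to_luminance(0.0, 2.2, 212.0) == 0.0

    def test_midpoint_power_law(self):
        assert lightness_to_luminance(127.5, 2.2, 212.0) == pytest.approx(212.0 * 0.5**2.2)

    def test_strictly_increasing(self):
        ls = np.linspace(0, 255, 100)
        out = lightness_to_luminance(ls, gamma=0.7, max_luminance=100.0)
        assert np.all(np.diff(out) > 0)

    def test_range_and_parameter_errors(self):
        with pytest.raises(ValueError):
            lightness_to_luminance(300.0)
        with pytest.raises(ValueError):
            lightness_to_luminance(10.0, gamma=-1)


class TestCanvas:
    def test_screen_mode_is_identity(self):
        frame = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(build_canvas(frame, None), frame)
        assert np.array_equal(build_canvas(frame, (2.0, 1.0), canvas_scale=1.0), frame)

    def test_centered_gaze_mean_ratio(self):
        frame = np.full((48, 64), 60.0)
        canvas = build_canvas(frame, (32.0, 24.0), canvas_scale=1.5)
        assert canvas.shape == (72, 96)
        assert canvas.mean() == pytest.approx(60.0 / 2.25)

    def test_corner_gaze_matches_bruteforce_placement(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0, 100, size=(4, 4))
        canvas = build_canvas(frame, (0.0, 0.0), canvas_scale=1.5)
        # brute-force oracle: paint pixel by pixel
        oracle = np.zeros((6, 6))
        cy, cx = 3, 3  # canvas center for 6x6
        for i in range(4):
            for j in range(4):
                r, c = cy + i, cx + j  # gaze pixel (0,0) at center
                if 0 <= r < 6 and 0 <= c < 6:
                    oracle[r, c] = frame[i, j]
        assert np.allclose(canvas, oracle)

    def test_offscreen_gaze_is_clamped(self):
        frame = np.ones((4, 4))
        canvas = build_canvas(frame, (-50.0, -50.0), canvas_scale=1.5)
        assert np.allclose(canvas, build_canvas(frame, (0.0, 0.0), canvas_scale=1.5))


class TestRegionMeans:
    def test_uniform_canvas(self):
        grid = RegionGrid()
        means = region_means(np.full((48, 64), 50.0), grid)
        assert means.shape == (48,)
        assert np.allclose(means, 50.0)

    def test_half_split_by_columns(self):
        grid = RegionGrid()
        canvas = np.zeros((48, 64))
        canvas[:, 32:] = 100.0
        means = region_means(canvas, grid).reshape(6, 8)
        assert np.allclose(means[:, :4], 0.0)
        assert np.allclose(means[:, 4:], 100.0)

    def test_matches_bruteforce_and_conserves_total(self, rng):
        grid = RegionGrid()
        canvas = rng.uniform(0, 212, size=(50, 67))  # non-divisible on purpose
        means = region_means(canvas, grid)
        row_edges, col_edges = grid.edges(50, 67)
        k = 0
        total = 0.0
        for i in range(6):
            for j in range(8):
                block = canvas[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
                assert means[k] == pytest.approx(block.mean())
                total += means[k] * block.size
                k += 1
        assert total == pytest.approx(canvas.sum())


class TestWeightGroups:
    def test_symmetric_about_vertical_midline(self):
        grid = RegionGrid()
        g = grid.weight_group_of_region().reshape(6, 8)
        assert np.array_equal(g, g[:, ::-1])

    def test_w1_is_top_central(self):
        g = RegionGrid().weight_group_of_region().reshape(6, 8)
        assert g[0, 3] == 0 and g[0, 4] == 0
        assert g[5, 0] == 5  # bottom-peripheral is W6


class TestExtractEvents:
    def test_constant_video_black_reference(self):
        frames = np.full((5, 12, 16, 3), 128, dtype=np.uint8)
        traces = extract_event_traces(frames, 25.0)
        # first two steps carry the frame's own luminance; zero afterwards
        assert np.all(traces.luminance_change[:2] > 0)
        assert np.allclose(traces.luminance_change[2:], 0.0, atol=1e-9)

    def test_step_video_lag2_differencing(self):
        from pupilkit.video_events import lightness_to_luminance, rgb_to_lightness

        k = 10
        frames = np.full((20, 12, 16, 3), 30, dtype=np.uint8)
        frames[k:] = 120
        traces = extract_event_traces(frames, 25.0)
        low = lightness_to_luminance(rgb_to_lightness(np.full((1, 1, 3), 30, np.uint8)))[0, 0]
        high = lightness_to_luminance(rgb_to_lightness(np.full((1, 1, 3), 120, np.uint8)))[0, 0]
        expected = high - low
        assert np.allclose(traces.luminance_change[k], expected, atol=1e-9)
        assert np.allclose(traces.luminance_change[k + 1], expected, atol=1e-9)
        assert np.allclose(traces.luminance_change[k + 2:], 0.0, atol=1e-9)
        assert np.allclose(traces.luminance_change[2:k], 0.0, atol=1e-9)

    def test_contrast_is_absolute_luminance_change(self, rng):
        frames = rng.integers(0, 256, size=(10, 12, 16, 3)).astype(np.uint8)
        traces = extract_event_traces(frames, 25.0)
        assert np.array_equal(traces.contrast_change, np.abs(traces.luminance_change))
        assert np.all(traces.contrast_change >= 0)

    def test_gaze_contingent_center_matches_screen_change(self):
        """With static centered gaze, interior-region changes match co-located
        screen-based changes (black surround contributes zero change)."""
        rng = np.random.default_rng(3)
        frames = rng.integers(0, 256, size=(6, 48, 64, 3)).astype(np.uint8)
        gaze = GazeTrace(
            timestamps=np.arange(120) / 500.0,
            x=np.full(120, 32.0),
            y=np.full(120, 24.0),
            valid=np.ones(120, dtype=bool),
        )
        screen = extract_event_traces(frames, 25.0)
        contingent = extract_event_traces(frames, 25.0, gaze, canvas_scale=1.5)
        # canvas is 72x96; screen occupies rows 12..60, cols 16..80.
        # canvas region (2,2) spans rows 24-36, cols 24-36 → inside the frame,
        # co-located with frame pixels rows 12-24, cols 8-20.
        grid = screen.grid
        frame_lums = []
        for fr in frames:
            from pupilkit.video_events import lightness_to_luminance, rgb_to_lightness

            frame_lums.append(lightness_to_luminance(rgb_to_lightness(fr))[12:24, 8:20].mean())
        frame_lums = np.array(frame_lums)
        expected = np.empty(6)
        expected[:2] = frame_lums[:2]
        expected[2:] = frame_lums[2:] - frame_lums[:-2]
        region_idx = 2 * 8 + 2
        assert np.allclose(contingent.luminance_change[:, region_idx], expected, atol=1e-9)


class TestDownsampleGaze:
    def test_constant_gaze_stays_constant(self):
        t = np.arange(100) / 500.0
        gaze = GazeTrace(t, np.full(100, 7.0), np.full(100, 9.0), np.ones(100, bool))
        frames_t = np.arange(5) / 25.0
        out = downsample_gaze(gaze, frames_t, (32, 24))
        assert np.allclose(out.x, 7.0) and np.allclose(out.y, 9.0)
        assert out.valid.all()

    def test_interval_means_match_oracle(self):
        t = np.arange(200) / 500.0
        x = np.arange(200, dtype=float)
        gaze = GazeTrace(t, x, x * 2, np.ones(200, bool))
        frames_t = np.arange(10) / 25.0
        out = downsample_gaze(gaze, frames_t, (0, 0))
        for f in range(10):
            block = x[f * 20 : (f + 1) * 20]  # 500 Hz / 25 Hz = 20 per frame
            assert out.x[f] == pytest.approx(block.mean())
            assert out.y[f] == pytest.approx(2 * block.mean())

    def test_all_invalid_falls_back_to_center(self):
        t = np.arange(100) / 500.0
        gaze = GazeTrace(t, np.zeros(100), np.zeros(100), np.zeros(100, bool))
        out = downsample_gaze(gaze, np.arange(5) / 25.0, (32.0, 24.0))
        assert np.allclose(out.x, 32.0) and np.allclose(out.y, 24.0)
        assert not out.valid.any()

    def test_gap_carries_last_valid_forward(self):
        t = np.arange(100) / 500.0
        valid = np.ones(100, bool)
        valid[20:60] = False  # frames 1 and 2 have no valid samples
        gaze = GazeTrace(t, np.full(100, 5.0), np.full(100, 6.0), valid)
        out = downsample_gaze(gaze, np.arange(5) / 25.0, (0, 0))
        assert np.allclose(out.x, 5.0)
        assert list(out.valid) == [True, False, False, True, True]
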