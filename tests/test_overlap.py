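import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from embryoeval import (
    BinaryMask,
    HueConfig,
    disc_attention,
    gradcam_to_mask,
    iou,
    lime_to_mask,
    median_ci,
    render_gradcam_overlay,
    render_lime_overlay,
    stagewise_iou_summary,
)
from embryoeval.exceptions import ParameterError, ShapeMismatchError
from embryoeval.io import read_mask_png, write_mask_png
from embryoeval.render import OverlayImage


def solid_overlay(rgb, kind, shape=(16, 16)):
    px = np.zeros(shape + (3,), dtype=np.uint8)
    px[...] = rgb
    return OverlayImage(pixels=px, kind=kind)


class TestIoU:
    def test_identical_nonempty_masks(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        assert iou(m, m).iou == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:2], b[5:7] = True, True
        res = iou(a, b)
        assert res.iou == 0.0
        assert not res.degenerate

    def test_worked_ten_by_ten_case(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0:5] = True  # rows 0-4, 50 px
        b[3:8] = True  # rows 3-7, 50 px
        res = iou(a, b)
        assert res.intersection_px == 20
        assert res.union_px == 80
        assert res.iou == pytest.approx(0.25)
        assert res.percent == pytest.approx(25.0)

    def test_empty_union_flags_degenerate(self):
        z = np.zeros((5, 5), bool)
        res = iou(z, z)
        assert res.iou == 0.0
        assert res.degenerate

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            iou(np.zeros((5, 5), bool), np.zeros((6, 5), bool))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_symmetry_and_transpose_invariance(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        assert iou(a, b).iou == iou(b, a).iou
        assert iou(a, b).iou == iou(a.T, b.T).iou

    def test_growing_intersection_is_monotone(self, rng):
        a = rng.random((12, 12)) < 0.4
        b = np.zeros_like(a)
        last = iou(a, b).iou
        for idx in np.argwhere(a):
            b[tuple(idx)] = True
            cur = iou(a, b).iou
            assert cur >= last
            last = cur


class TestGradcamMask:
    def test_all_blue_image_is_non_contributive(self):
        img = solid_overlay((0, 0, 255), "gradcam")
        assert gradcam_to_mask(img).positive_count == 0

    def test_all_red_image_is_fully_contributive(self):
        img = solid_overlay((255, 0, 0), "gradcam")
        assert gradcam_to_mask(img).positive_count == 16 * 16

    def test_gray_background_excluded_by_saturation(self):
        img = solid_overlay((128, 128, 128), "gradcam")
        assert gradcam_to_mask(img).positive_count == 0

    def test_disc_round_trip(self):
        truth = disc_attention((224, 224))
        overlay = render_gradcam_overlay(truth, seed=11)
        rec = gradcam_to_mask(overlay)
        assert iou(rec.grid, truth.truth_mask).iou >= 0.95

    def test_wrong_kind_rejected(self):
        img = solid_overlay((255, 0, 0), "lime")
        with pytest.raises(ParameterError):
            gradcam_to_mask(img)

    def test_malformed_raster_rejected(self):
        with pytest.raises(ParameterError):
            gradcam_to_mask(np.zeros((8, 8), dtype=np.uint8))

    def test_hue_config_validation(self):
        with pytest.raises(ParameterError):
            HueConfig(contributive_hue_ranges=((200.0, 100.0),))


class TestLimeMask:
    def test_no_yellow_gives_empty_mask_with_warning(self):
        img = solid_overlay((128, 128, 128), "lime")
        with pytest.warns(UserWarning):
            mask = lime_to_mask(img)
        assert mask.positive_count == 0
        assert mask.empty_input

    def test_rectangle_outline_fills_to_area(self):
        region = np.zeros((224, 224), bool)
        region[100:140, 80:120] = True  # 40x40
        img = render_lime_overlay([region], background=128, line_width=1)
        mask = lime_to_mask(img, gap_closing_px=0)
        assert mask.positive_count == 1600

    def test_nested_contours_merge_to_outer_region(self):
        outer = np.zeros((128, 128), bool)
        outer[20:100, 20:100] = True
        inner = np.zeros((128, 128), bool)
        inner[45:75, 45:75] = True
        img = render_lime_overlay([outer, inner], background=128, line_width=1)
        mask = lime_to_mask(img, gap_closing_px=0)
        assert iou(mask.grid, outer).iou == pytest.approx(1.0)

    def test_two_disjoint_regions_round_trip(self):
        a = np.zeros((224, 224), bool)
        a[30:80, 30:90] = True
        b = np.zeros((224, 224), bool)
        b[130:190, 120:200] = True
        img = render_lime_overlay([a, b], background=128, line_width=2)
        mask = lime_to_mask(img)
        assert iou(mask.grid, a | b).iou >= 0.90


class TestRoundTripSeeds:
    """Render/extract agreement across a fixed seed battery."""

    @pytest.mark.parametrize("seed", range(10))
    def test_gradcam_round_trip_over_seeds(self, seed):
        from embryoeval import blob_attention

        rng = np.random.default_rng(seed)
        truth = blob_attention((224, 224), rng, n_blobs=2)
        overlay = render_gradcam_overlay(truth, seed=seed)
        assert iou(gradcam_to_mask(overlay).grid, truth.truth_mask).iou >= 0.95

    @pytest.mark.parametrize("seed", range(10))
    def test_lime_round_trip_over_seeds(self, seed):
        from embryoeval import blob_attention

        rng = np.random.default_rng(100 + seed)
        truth = blob_attention((224, 224), rng, n_blobs=2)
        region = truth.truth_mask
        overlay = render_lime_overlay([region], background=128, line_width=2)
        assert iou(lime_to_mask(overlay).grid, region).iou >= 0.90


class TestMedianCI:
    def test_constant_values_degenerate_ci(self):
        med, lo, hi = median_ci([0.5] * 12)
        assert (med, lo, hi) == (0.5, 0.5, 0.5)

    def test_odd_n_median(self):
        med, _, _ = median_ci([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])
        assert med == pytest.approx(0.4)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_ranks_match_binomial_enumeration(self, n):
        values = np.arange(1, n + 1, dtype=float)
        med, lo, hi = median_ci(values)
        # oracle: largest symmetric order-statistic pair with >= 95% coverage
        best = None
        for a in range(1, n // 2 + 2):
            coverage = 1.0 - 2.0 * sum(
                stats.binom.pmf(i, n, 0.5) for i in range(a)
            )
            if coverage >= 0.95 - 1e-12 and a <= n - a + 1:
                best = a
        if best is None:
            assert np.isnan(lo) and np.isnan(hi)
        else:
            assert lo == values[best - 1]
            assert hi == values[n - best]


class TestStagewiseSummary:
    def test_summary_medians_and_paired_tests(self, rng):
        rows = []
        for stage in (1, 2):
            for f in range(8):
                base = 0.3 + 0.05 * stage
                rows.append(
                    {"frame_id": f"f{stage}{f}", "stage": stage,
                     "model": "m1", "iou": base + 0.2}
                )
                rows.append(
                    {"frame_id": f"f{stage}{f}", "stage": stage,
                     "model": "m2", "iou": base + rng.normal(0, 0.01)}
                )
        summary, tests = stagewise_iou_summary(pd.DataFrame(rows))
        assert len(summary) == 4
        m1 = summary[(summary["stage"] == 1) & (summary["model"] == "m1")]
        assert m1["median_percent"].iloc[0] == pytest.approx(55.0)
        assert not np.isnan(m1["ci_low"].iloc[0])  # n = 8 >= 6
        assert len(tests) == 2
        assert all(t.method == "wilcoxon_signed_rank" for t in tests)

    def test_small_cells_have_undefined_ci(self):
        rows = [
            {"frame_id": f"f{i}", "stage": 1, "model": "m", "iou": 0.1 * i}
            for i in range(4)
        ]
        summary, _ = stagewise_iou_summary(pd.DataFrame(rows))
        assert np.isnan(summary["ci_low"].iloc[0])

    def test_missing_columns_rejected(self):
        with pytest.raises(ParameterError):
            stagewise_iou_summary(pd.DataFrame({"stage": [1], "iou": [0.5]}))


def test_mask_png_round_trip_is_bit_identical(tmp_path, rng):
    grid = rng.random((64, 64)) < 0.3
    path = tmp_path / "mask.png"
    write_mask_png(BinaryMask(grid=grid), path)
    back = read_mask_png(path)
    assert (back.grid == grid).all()
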