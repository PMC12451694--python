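import numpy as np
import pytest

import faractin as fa
from conftest import make_image, rect_roi
from oracles import oracle_far


def fixed_config(**overrides):
    defaults = dict(
        background_method="fixed",
        background_value=0.0,
        dapi_threshold=50.0,
        actin_threshold=5.0,
        min_nucleus_area=0,
        fill_nuclear_holes=False,
        exclude_border_cells=False,
    )
    defaults.update(overrides)
    return fa.SegmentationConfig(**defaults)


def worked_example():
    """4x4 raster: two nuclear pixels of actin 10, four cytoplasmic pixels
    of actin 20; everything supra-threshold, background zero."""
    dapi = np.zeros((4, 4))
    actin = np.zeros((4, 4))
    dapi[0, 0] = dapi[0, 1] = 100.0
    actin[0, 0] = actin[0, 1] = 10.0
    actin[2, 0] = actin[2, 1] = actin[2, 2] = actin[2, 3] = 20.0
    return make_image(dapi, actin), rect_roi(0, 0, 4, 4)


class TestBackground:
    def test_uniform_background_outside_roi(self):
        img = make_image(np.full((20, 20), 7.0), np.full((20, 20), 7.0))
        roi = rect_roi(5, 5, 10, 10)
        bg = fa.estimate_background(img, [roi])
        np.testing.assert_array_equal(bg, [7.0, 7.0])

    def test_no_rois_falls_back_to_image_median(self, caplog):
        img = make_image(np.full((10, 10), 3.0), np.full((10, 10), 9.0))
        with caplog.at_level("WARNING"):
            bg = fa.estimate_background(img, [])
        np.testing.assert_array_equal(bg, [3.0, 9.0])
        assert "median" in caplog.text

    def test_roi_tiling_whole_image_uses_5th_percentile(self, caplog):
        rng = np.random.default_rng(0)
        px = rng.uniform(0, 100, (2, 12, 12))
        img = fa.MultiChannelImage(px)
        roi = rect_roi(0, 0, 12, 12)
        with caplog.at_level("WARNING"):
            bg = fa.estimate_background(img, [roi])
        np.testing.assert_allclose(bg, np.percentile(px, 5, axis=(1, 2)))
        assert "5th percentile" in caplog.text

    def test_synthetic_scene_recovers_background_level(self, default_replicate):
        image, rois, _ = default_replicate
        bg = fa.estimate_background(image, rois)
        # Poisson(200) median plus clipped read noise stays near 200
        np.testing.assert_allclose(bg, [200.0, 200.0], atol=5.0)


class TestSegmentNucleus:
    def test_disk_nucleus_area_within_10_percent(self):
        spec = fa.CellSpec(
            center=(40.0, 40.0),
            cell_axes=(30.0, 25.0),
            nucleus_centers=((40.0, 40.0),),
            nucleus_axes=((10.0, 10.0),),
            rho=0.2,
        )
        raster, _, polygon = fa.render_cell(spec, (80, 80), np.random.default_rng(0))
        img = fa.MultiChannelImage(raster)
        roi = fa.CellROI("c", polygon)
        cfg = fa.SegmentationConfig(background_method="fixed", background_value=0.0)
        mask, n, flags = fa.segment_nucleus(img, roi, cfg)
        assert not flags and n == 1
        assert mask.sum() == pytest.approx(np.pi * 100, rel=0.10)

    def test_two_nuclei_union_semantics(self):
        dapi = np.zeros((30, 30))
        dapi[5:10, 5:10] = 100.0
        dapi[20:25, 20:25] = 100.0
        img = make_image(dapi, np.ones((30, 30)))
        mask, n, flags = fa.segment_nucleus(
            img, rect_roi(0, 0, 30, 30), fixed_config(min_nucleus_area=4)
        )
        assert n == 2
        assert mask.sum() == 50
        assert not flags

    def test_all_zero_dapi_flags_no_nucleus(self):
        img = make_image(np.zeros((10, 10)), np.ones((10, 10)))
        mask, n, flags = fa.segment_nucleus(
            img, rect_roi(0, 0, 10, 10), fixed_config(dapi_threshold="otsu")
        )
        assert n == 0 and not mask.any()
        assert "no_nucleus" in flags

    def test_small_components_are_removed(self):
        dapi = np.zeros((20, 20))
        dapi[2, 2] = 100.0  # single-pixel speck
        dapi[8:14, 8:14] = 100.0  # real nucleus, 36 px
        img = make_image(dapi, np.ones((20, 20)))
        mask, n, _ = fa.segment_nucleus(
            img, rect_roi(0, 0, 20, 20), fixed_config(min_nucleus_area=10)
        )
        assert n == 1
        assert not mask[2, 2]
        assert mask.sum() == 36


class TestSegmentActin:
    def test_otsu_on_two_level_histogram(self):
        actin = np.zeros((10, 10))
        actin[:, 5:] = 100.0
        img = make_image(np.ones((10, 10)), actin)
        mask, flags = fa.segment_actin(
            img, rect_roi(0, 0, 10, 10), fixed_config(actin_threshold="otsu")
        )
        assert not flags
        assert mask.sum() == 50
        assert (actin[mask] == 100.0).all()

    def test_constant_intensity_flags_empty_actin(self):
        img = make_image(np.ones((8, 8)), np.full((8, 8), 42.0))
        mask, flags = fa.segment_actin(
            img, rect_roi(0, 0, 8, 8), fixed_config(actin_threshold="otsu")
        )
        assert "empty_actin" in flags and not mask.any()

    def test_fixed_threshold_strictly_above(self):
        actin = np.where(np.arange(64).reshape(8, 8) % 2 == 0, 40.0, 60.0)
        img = make_image(np.ones((8, 8)), actin)
        mask, _ = fa.segment_actin(
            img, rect_roi(0, 0, 8, 8), fixed_config(actin_threshold=50.0)
        )
        assert (actin[mask] == 60.0).all()
        assert mask.sum() == 32


class TestComputeFar:
    def test_worked_example_equals_20_percent(self):
        img, roi = worked_example()
        cfg = fixed_config()
        ms = fa.process_image(img, [roi], cfg)
        (m,) = ms
        assert m.far_percent == 20.0
        assert m.nuclear_actin_sum == 20.0
        assert m.total_actin_sum == 100.0
        oracle, _, _ = oracle_far(
            img.dapi, img.actin, roi.mask((4, 4)), (0, 0), 50.0, 5.0
        )
        assert m.far_percent == oracle

    def test_all_actin_inside_nucleus_is_100(self):
        dapi = np.zeros((6, 6))
        actin = np.zeros((6, 6))
        dapi[2:4, 2:4] = 100.0
        actin[2:4, 2:4] = 30.0
        img = make_image(dapi, actin)
        (m,) = fa.process_image(img, [rect_roi(0, 0, 6, 6)], fixed_config())
        assert m.far_percent == 100.0

    def test_no_actin_inside_nucleus_is_0(self):
        dapi = np.zeros((6, 6))
        actin = np.zeros((6, 6))
        dapi[0:2, 0:2] = 100.0
        actin[4:6, 4:6] = 30.0
        img = make_image(dapi, actin)
        (m,) = fa.process_image(img, [rect_roi(0, 0, 6, 6)], fixed_config())
        assert m.far_percent == 0.0

    def test_zero_total_actin_flags_and_nan(self):
        img = make_image(np.zeros((5, 5)), np.zeros((5, 5)))
        (m,) = fa.process_image(img, [rect_roi(0, 0, 5, 5)], fixed_config())
        assert np.isnan(m.far_percent)
        assert "empty_actin" in m.qc_flags

    def test_whole_cell_denominator(self):
        img, roi = worked_example()
        cfg = fixed_config(denominator="whole_cell")
        (m,) = fa.process_image(img, [roi], cfg)
        # same sums here: all signal is supra-threshold
        assert m.far_percent == 20.0
        oracle, _, _ = oracle_far(
            img.dapi, img.actin, roi.mask((4, 4)), (0, 0), 50.0, 5.0,
            denominator="whole_cell",
        )
        assert m.far_percent == oracle

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pixel_loop_oracle_on_random_rasters(self, seed):
        rng = np.random.default_rng(seed)
        dapi = rng.integers(0, 200, (12, 12)).astype(float)
        actin = rng.integers(0, 200, (12, 12)).astype(float)
        img = make_image(dapi, actin)
        roi = rect_roi(1, 2, 11, 10)
        for denom in ("actin_positive", "whole_cell"):
            cfg = fixed_config(
                background_value=10.0,
                dapi_threshold=float(rng.integers(20, 150)),
                actin_threshold=float(rng.integers(20, 150)),
                denominator=denom,
            )
            (m,) = fa.process_image(img, [roi], cfg)
            oracle, nuc, tot = oracle_far(
                dapi, actin, roi.mask((12, 12)), (10.0, 10.0),
                cfg.dapi_threshold, cfg.actin_threshold, denom,
            )
            if np.isnan(oracle):
                assert np.isnan(m.far_percent)
            else:
                assert m.far_percent == oracle
                assert m.nuclear_actin_sum == nuc
                assert m.total_actin_sum == tot

    @pytest.mark.parametrize("seed", range(5))
    def test_transferring_actin_into_nucleus_never_decreases_far(self, seed):
        # move intensity from a supra-threshold cytoplasmic pixel to a
        # supra-threshold nuclear pixel; masks are unchanged by construction
        rng = np.random.default_rng(seed)
        dapi = np.zeros((10, 10))
        dapi[3:7, 3:7] = 100.0
        actin = rng.integers(60, 200, (10, 10)).astype(float)
        img = make_image(dapi, actin)
        cfg = fixed_config(actin_threshold=50.0)
        roi = rect_roi(0, 0, 10, 10)
        (m0,) = fa.process_image(img, [roi], cfg)
        actin2 = actin.copy()
        amount = actin2[0, 0] - 55.0  # keep the source above threshold
        actin2[0, 0] -= amount
        actin2[4, 4] += amount
        (m1,) = fa.process_image(make_image(dapi, actin2), [roi], cfg)
        assert m1.far_percent >= m0.far_percent


class TestProcessImage:
    def test_interior_cells_unflagged_and_in_roi_order(self, default_replicate):
        image, rois, truth = default_replicate
        ms = fa.process_image(image, rois)
        assert [m.cell_id for m in ms] == [r.cell_id for r in rois]
        assert all(m.ok for m in ms)
        assert all(0.0 <= m.far_percent <= 100.0 for m in ms)

    def test_border_cell_is_flagged_but_still_reported(self):
        dapi = np.zeros((40, 80))
        actin = np.zeros((40, 80))
        dapi[18:23, 18:23] = 100.0
        actin[15:26, 15:26] = 50.0
        dapi[18:23, 58:63] = 100.0
        actin[15:26, 55:66] = 50.0
        img = make_image(dapi, actin)
        interior = rect_roi(10, 10, 30, 30, "interior")
        border = fa.CellROI(
            "border", np.array([[0, 50], [0, 70], [30, 70], [30, 50]], float)
        )
        cfg = fixed_config(exclude_border_cells=True)
        ms = fa.process_image(img, [interior, border], cfg)
        assert ms[0].ok
        assert "border" in ms[1].qc_flags
        assert len(ms) == 2

    def test_empty_roi_list_warns_and_returns_empty(self, caplog):
        img = make_image(np.ones((5, 5)), np.ones((5, 5)))
        with caplog.at_level("WARNING"):
            assert fa.process_image(img, []) == []
        assert "empty ROI list" in caplog.text

    def test_mean_far_tracks_rho_on_one_scene(self, default_replicate):
        image, rois, truth = default_replicate
        ms = fa.process_image(image, rois)
        mean_far = np.mean([m.far_percent for m in ms if m.ok])
        assert mean_far == pytest.approx(25.0, abs=3.0)
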