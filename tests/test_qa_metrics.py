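"""CNR / rCNR / HU accuracy / uniformity metric definitions."""

import numpy as np
import pytest

from decbct.exceptions import DegenerateInputError, ValidationError
from decbct.phantom import ROI, default_catphan, default_roiset
from decbct.qa_metrics import (
    ROIStats,
    build_report,
    cnr,
    hu_accuracy,
    hu_uniformity,
    rcnr,
    roi_stats,
)
from decbct.reconstruction import ReconGrid, Volume


@pytest.fixture(scope="module")
def grid():
    return ReconGrid(voxel_mm=1.75, nx=128, ny=128)


def hu_volume(values, grid):
    return Volume(values, grid, "hu")


class TestRoiStats:
    def test_constant_image(self, grid):
        v = hu_volume(np.full((128, 128), 100.0), grid)
        s = roi_stats(v, ROI("c", 0, 0, 10))
        assert s.mean_hu == 100.0 and s.sd_hu == 0.0

    def test_population_sd_convention(self, grid):
        # two-voxel ROI {0, 2}: mean 1, population sd 1 (not sample sd sqrt(2))
        vals = np.zeros((128, 128))
        vals[64, 64] = 0.0
        vals[64, 65] = 2.0
        v = hu_volume(vals, grid)
        # ROI covering exactly those two pixel centres
        s = roi_stats(v, ROI("pair", 1.75, 0.875, 1.0))
        assert s.voxel_count == 2
        assert s.mean_hu == 1.0 and s.sd_hu == 1.0

    def test_gaussian_sampling_oracle(self, grid):
        rng = np.random.default_rng(0)
        vals = rng.normal(50.0, 10.0, (128, 128))
        v = hu_volume(vals, grid)
        s = roi_stats(v, ROI("big", 0, 0, 100.0))
        n = s.voxel_count
        assert n > 9000
        assert s.mean_hu == pytest.approx(50.0, abs=3 * 10.0 / np.sqrt(n))
        assert s.sd_hu == pytest.approx(10.0, abs=3 * 10.0 / np.sqrt(2 * n))

    def test_empty_roi_rejected(self, grid):
        v = hu_volume(np.zeros((128, 128)), grid)
        with pytest.raises(DegenerateInputError):
            roi_stats(v, ROI("off", 500.0, 500.0, 0.1))

    def test_unit_tag_enforced(self, grid):
        v = Volume(np.zeros((128, 128)), grid, "mu")
        with pytest.raises(ValidationError):
            roi_stats(v, ROI("c", 0, 0, 10))


class TestCNR:
    def test_closed_form(self):
        assert cnr(ROIStats(100, 10, 5), ROIStats(0, 10, 5)) == pytest.approx(10.0)

    def test_zero_contrast(self):
        assert cnr(ROIStats(50, 3, 5), ROIStats(50, 9, 5)) == 0.0

    def test_hand_computed_example(self):
        # (50-20)/sqrt((36+64)/2) = 30/sqrt(50)
        assert cnr(ROIStats(50, 6, 5), ROIStats(20, 8, 5)) == pytest.approx(
            30.0 / np.sqrt(50.0)
        )

    def test_degenerate_rois_rejected(self):
        with pytest.raises(DegenerateInputError):
            cnr(ROIStats(1, 0, 5), ROIStats(0, 0, 5))

    def test_shift_invariance_and_positive_scaling(self, grid):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 5, (128, 128))
        vals[40:50, 40:50] += 80.0
        roi_i = ROI("i", -33.0, -33.0, 6.0)
        roi_b = ROI("b", 30.0, 30.0, 6.0)

        def compute(v):
            vol = hu_volume(v, grid)
            return cnr(roi_stats(vol, roi_i), roi_stats(vol, roi_b))

        base = compute(vals)
        assert compute(vals + 500.0) == pytest.approx(base, rel=1e-9)
        assert compute(3.0 * vals) == pytest.approx(base, rel=1e-9)


class TestRCNR:
    def test_self_reference_is_unity(self):
        c = np.array([3.0, -2.0, 7.5])
        ratios, mean, sd = rcnr(c, c)
        np.testing.assert_allclose(ratios, 1.0)
        assert mean == 1.0 and sd == 0.0

    def test_doubled_cnr(self):
        c = np.array([1.0, 2.0, 3.0])
        _, mean, sd = rcnr(2 * c, c)
        assert mean == pytest.approx(2.0) and sd == pytest.approx(0.0)

    def test_sign_preserved_on_contrast_inversion(self):
        ratios, _, _ = rcnr(np.array([-2.0]), np.array([4.0]))
        assert ratios[0] == -0.5

    def test_zero_reference_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            ratios, mean, _ = rcnr(np.array([1.0, 1.0]), np.array([2.0, 0.0]))
        assert np.isnan(ratios[1]) and mean == 0.5


class TestHUAccuracy:
    def test_theoretical_volume_has_zero_error(self, grid):
        from decbct.phantom import theoretical_hu_image

        spec = default_catphan()
        rois = default_roiset(spec)
        v = hu_volume(theoretical_hu_image(spec, grid, 60.0), grid)
        deltas, mean, sd = hu_accuracy(v, rois, 60.0)
        assert max(abs(d) for d in deltas.values()) < 1e-9

    def test_constant_offset_detected(self, grid):
        from decbct.phantom import theoretical_hu_image

        spec = default_catphan()
        rois = default_roiset(spec)
        v = hu_volume(theoretical_hu_image(spec, grid, 60.0) + 20.0, grid)
        _, mean, sd = hu_accuracy(v, rois, 60.0)
        assert mean == pytest.approx(20.0) and sd == pytest.approx(0.0, abs=1e-9)


class TestHUUniformity:
    def rois(self):
        return default_roiset(default_catphan()).uniformity_rois

    def test_uniform_image_is_zero(self, grid):
        v = hu_volume(np.full((128, 128), 7.0), grid)
        assert hu_uniformity(v, self.rois()) == 0.0

    def test_center_minus_mean_peripheral(self, grid):
        rois = self.rois()
        vals = np.full((128, 128), 0.0)
        x, y = grid.pixel_centers()
        vals[(x - 0) ** 2 + (y - 0) ** 2 <= rois[0].radius**2] = 10.0
        for r, level in zip(rois[1:], (2.0, 4.0, 6.0, 8.0)):
            vals[(x - r.cx) ** 2 + (y - r.cy) ** 2 <= r.radius**2] = level
        assert hu_uniformity(hu_volume(vals, grid), rois) == pytest.approx(5.0)

    def test_antisymmetry_under_role_swap(self, grid):
        rng = np.random.default_rng(4)
        v = hu_volume(rng.normal(0, 10, (128, 128)), grid)
        rois = self.rois()
        base = hu_uniformity(v, rois)
        # swapping centre and a "mean periphery" is modelled by negating the
        # image: uniformity must negate as well
        v2 = hu_volume(-v.values, grid)
        assert hu_uniformity(v2, rois) == pytest.approx(-base)

    def test_wrong_roi_count_rejected(self, grid):
        v = hu_volume(np.zeros((128, 128)), grid)
        with pytest.raises(ValidationError):
            hu_uniformity(v, self.rois()[:4])


class TestBuildReport:
    def test_reference_against_itself(self, grid):
        rng = np.random.default_rng(5)
        from decbct.phantom import theoretical_hu_image

        spec = default_catphan()
        rois = default_roiset(spec)
        vals = theoretical_hu_image(spec, grid, 60.0) + rng.normal(0, 3, (128, 128))
        v = hu_volume(vals, grid)
        rep = build_report(v, v, rois, 60.0, uniformity_volume=v,
                           uniformity_reference=v)
        assert rep.rcnr_mean == pytest.approx(1.0)
        assert rep.rcnr_sd == pytest.approx(0.0, abs=1e-12)
        assert rep.uniformity_hu == rep.uniformity_reference_hu

    def test_summary_recomputable_from_per_insert_values(self, grid):
        rng = np.random.default_rng(6)
        from decbct.phantom import theoretical_hu_image

        spec = default_catphan()
        rois = default_roiset(spec)
        a = hu_volume(
            theoretical_hu_image(spec, grid, 60.0) + rng.normal(0, 5, (128, 128)),
            grid,
        )
        b = hu_volume(
            theoretical_hu_image(spec, grid, 60.0) + rng.normal(0, 8, (128, 128)),
            grid,
        )
        rep = build_report(a, b, rois, 60.0)
        assert rep.rcnr_mean == pytest.approx(np.mean(rep.rcnr_per_insert))
        deltas = np.array(list(rep.delta_hu.values()))
        assert rep.delta_hu_mean == pytest.approx(deltas.mean())
        assert rep.delta_hu_sd == pytest.approx(deltas.std())
        assert all(np.isfinite(rep.cnr_vmi))

    def test_json_csv_serialization(self, grid, tmp_path):
        from decbct.phantom import theoretical_hu_image

        spec = default_catphan()
        rois = default_roiset(spec)
        rng = np.random.default_rng(7)
        v = hu_volume(
            theoretical_hu_image(spec, grid, 60.0) + rng.normal(0, 5, (128, 128)),
            grid,
        )
        rep = build_report(v, v, rois, 60.0)
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        import json
        import pandas as pd

        assert json.loads((tmp_path / "r.json").read_text())["energy"] == 60.0
        assert len(pd.read_csv(tmp_path / "r.csv")) == len(rois.insert_rois) + 1
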