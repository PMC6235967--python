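"""Flow-void metrics, spectral spacing, DRP spacing and size-scale ratios."""

import numpy as np
import pandas as pd
import pytest

from aoicg import morphometry as mm
from aoicg import synthetic as syn


def disc_image(shape, centers, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.ones(shape)
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = 0.0
    return img


class TestFrangi:
    def test_constant_image_zero_vesselness(self):
        assert np.allclose(mm.frangi_enhance(np.full((32, 32), 3.0)), 0.0)

    def test_scale_sweep_peaks_near_ridge_width(self):
        """Response at a ridge is maximized by the filter scale matching it."""
        n = 128
        yy = np.arange(n)[:, None] * np.ones((1, n))
        sigma_ridge = 4.0
        img = np.exp(-0.5 * ((yy - n / 2) / sigma_ridge) ** 2)
        responses = {}
        for scale in (2.0, 4.0, 8.0, 16.0, 32.0):
            v = mm.frangi_enhance(img, scales=[scale], pixel_scale=1.0)
            responses[scale] = v[n // 2, n // 2]
        best = max(responses, key=responses.get)
        assert best / 2.0 == pytest.approx(sigma_ridge, rel=1.1)  # within ~factor 2

    def test_rotation_isotropy(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        img = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 2.0)
        a = np.rot90(mm.frangi_enhance(img, scales=[6.0]))
        b = mm.frangi_enhance(np.rot90(img), scales=[6.0])
        # equal up to the filter's separable-convolution numerics
        assert np.allclose(a[8:-8, 8:-8], b[8:-8, 8:-8], atol=2e-3)


class TestSegmentFlowVoids:
    def test_two_discs_measured_within_discretization(self):
        r = 10.0
        img = disc_image((96, 96), [(30, 30), (60, 66)], r)
        fvs = mm.segment_flow_voids(img, img, pixel_scale=1.0, threshold=0.5, min_area=20.0)
        assert len(fvs) == 2
        for _, row in fvs.voids.iterrows():
            assert row["area_um2"] == pytest.approx(np.pi * r**2, rel=0.05)
            assert row["perimeter_um"] == pytest.approx(2 * np.pi * r, rel=0.05)
            assert row["effective_diameter_um"] == pytest.approx(2 * r, rel=0.05)

    def test_metrics_match_pixel_count_oracle(self):
        img = disc_image((64, 64), [(32, 20), (30, 48)], 7)
        s = 0.8  # µm/px
        fvs = mm.segment_flow_voids(img, img, pixel_scale=s, threshold=0.5, min_area=5.0)
        for _, row in fvs.voids.iterrows():
            px = fvs.mask == row["label"]
            assert row["area_um2"] == pytest.approx(px.sum() * s**2, rel=1e-12)
            ys, xs = np.nonzero(px)
            assert row["centroid_y_um"] == pytest.approx(ys.mean() * s, rel=1e-9)
            assert row["effective_diameter_um"] == pytest.approx(
                2 * np.sqrt(px.sum() * s**2 / np.pi), rel=1e-12
            )

    def test_empty_below_threshold_set(self):
        img = np.ones((32, 32))
        img[0, 0] = 0.0  # lone sub-threshold pixel on the border
        fvs = mm.segment_flow_voids(img, img, threshold=0.5, min_area=0.0)
        assert len(fvs) == 0

    def test_border_and_small_components_excluded(self):
        img = np.ones((64, 64))
        img[0:10, 0:10] = 0.0  # touches border
        img[30:32, 30:32] = 0.0  # 4 px, below min_area
        img[45:55, 40:50] = 0.0  # keeper
        fvs = mm.segment_flow_voids(img, img, threshold=0.5, min_area=20.0)
        assert len(fvs) == 1

    def test_scripted_edits_add_and_remove(self):
        img = disc_image((64, 64), [(20, 20), (44, 44)], 6)
        base = mm.segment_flow_voids(img, img, threshold=0.5, min_area=10.0)
        lab_at = base.mask[20, 20]
        edited = mm.segment_flow_voids(
            img, img, threshold=0.5, min_area=10.0,
            edits={"remove": [int(lab_at)], "add": [(8, 14, 50, 58)]},
        )
        assert len(edited) == 2
        assert edited.mask[20, 20] == 0
        assert edited.mask[10, 54] > 0

    def test_recovers_generated_voids(self):
        mask, voids = syn.make_choriocapillaris(31.0, 15.0, 256, 1.0, seed=9)
        fvs = mm.segment_flow_voids(mask, mask, threshold=0.5, min_area=20.0)
        from scipy.spatial import cKDTree

        tree = cKDTree(fvs.voids[["centroid_y_um", "centroid_x_um"]].to_numpy())
        d, _ = tree.query(voids[["y_um", "x_um"]].to_numpy())
        assert (d < 7.5).mean() >= 0.8

    def test_summary_statistics(self):
        img = disc_image((64, 64), [(32, 32)], 8)
        fvs = mm.segment_flow_voids(img, img, threshold=0.5)
        s = mm.flow_void_summary(fvs)
        assert s.loc["count", "area_um2"] == 1
        assert s.loc["mean", "area_um2"] == fvs.voids["area_um2"].iloc[0]
        with pytest.raises(ValueError):
            mm.flow_void_summary(
                mm.FlowVoidSet(voids=pd.DataFrame(), mask=np.zeros((4, 4), int), pixel_scale=1)
            )


class TestRadialPowerSpectrum:
    def test_sinusoidal_grating_period_recovered(self):
        n, period = 512, 30.0
        x = np.arange(n)
        img = np.sin(2 * np.pi * x / period)[None, :] * np.ones((n, 1))
        spec = mm.radial_power_spectrum(img, pixel_scale=1.0, crop=500)
        f_true = 1.0 / period
        assert abs(spec.peak_frequency - f_true) <= 1.0 / 500 + 1e-12
        assert spec.reliable

    def test_white_noise_peak_not_reproducible(self):
        peaks = []
        for seed in range(5):
            img = np.random.default_rng(seed).normal(size=(128, 128))
            spec = mm.radial_power_spectrum(img, 1.0, crop=128)
            peaks.append(round(spec.peak_frequency * 128))
        assert len(set(peaks)) > 1

    def test_image_smaller_than_crop_rejected(self):
        with pytest.raises(ValueError):
            mm.radial_power_spectrum(np.zeros((64, 64)), crop=500)

    def test_cc_void_spacing_recovered(self):
        mask, _ = syn.make_choriocapillaris(31.0, 15.0, 540, 1.0, seed=4)
        spec = mm.radial_power_spectrum(mask, 1.0, crop=500)
        assert abs(spec.row_spacing - 31.0) / 31.0 < 0.15


class TestDrpSpacing:
    def test_triangular_lattice_pitch_within_one_bin(self):
        pts = syn.triangular_lattice(14.0, (400.0, 400.0))
        res = mm.drp_spacing(pts, bin_width=1.0)
        assert abs(res.spacing - 14.0) <= 1.0 + 1e-6
        assert res.mosaic

    def test_poisson_points_flagged_non_mosaic(self):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 400, (700, 2))
            res = mm.drp_spacing(pts, bin_width=1.0)
            assert res.spacing < 3.0
            assert not res.mosaic

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        pts = syn.triangular_lattice(10.0, (300.0, 300.0), 0.05, rng)
        a = mm.drp_spacing(pts, bin_width=1.0).spacing
        b = mm.drp_spacing(2.0 * pts, bin_width=2.0).spacing
        assert b == pytest.approx(2 * a, rel=0.1)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            mm.drp_spacing(np.zeros((5, 2)), 1.0)


class TestSizeScaleRatios:
    def test_reported_magnitudes(self):
        mk = lambda s: mm.SpacingResult(spacing=s, method="drp")
        assert mm.size_scale_ratios(mk(1.0), mk(3.1), mk(3.7)) == pytest.approx((3.1, 3.7))
        assert mm.size_scale_ratios(mk(2.0), mk(2.0), mk(2.0)) == pytest.approx((1.0, 1.0))

    def test_recovered_from_synthetic_scene(self):
        """Measured layer scales reproduce the built-in 14/4 and 15/4 ratios."""
        scene = syn.make_scene(field=300, pad=4, seed=2)
        rpe = mm.drp_spacing(scene.rpe_centroids, 1.0)
        cone = mm.drp_spacing(scene.cone_centroids, 0.5)
        mask = scene.cc_vessel_mask
        fvs = mm.segment_flow_voids(mask, mask, threshold=0.5, min_area=20.0)
        cc_scale = mm.SpacingResult(
            spacing=float(fvs.voids["effective_diameter_um"].mean()), method="spectrum"
        )
        r_rpe, r_cc = mm.size_scale_ratios(cone, rpe, cc_scale)
        assert r_rpe == pytest.approx(14.0 / 4.0, rel=0.15)
        assert r_cc == pytest.approx(15.0 / 4.0, rel=0.15)
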