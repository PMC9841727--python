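"""Centerline-rotation volumetry, volume fiducials, and up-sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvloops
from pvloops import errors, volumetrics

from conftest import ellipse_contour


def _rectangle_contour(length=50.0, half_width=15.0):
    """Rectangle with the annulus chord as the top edge and the apex at the
    bottom-edge midpoint: a cylinder of revolution."""
    pts = np.array(
        [
            [-half_width, 0.0],
            [half_width, 0.0],
            [half_width, -length],
            [0.0, -length],
            [-half_width, -length],
        ]
    )
    return pvloops.LVContour(
        points=pts,
        annulus_a=np.array([-half_width, 0.0]),
        annulus_b=np.array([half_width, 0.0]),
        apex=np.array([0.0, -length]),
        frame_time=0.0,
    )


class TestCenterlineRotation:
    def test_spheroid_phantom(self):
        vol = pvloops.centerline_rotation_volume(ellipse_contour(40.0, 20.0))
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 40 * 20**2 / 1000.0, rel=0.005)

    def test_sphere_phantom(self):
        vol = pvloops.centerline_rotation_volume(ellipse_contour(20.0, 20.0))
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 20**3 / 1000.0, rel=0.005)

    def test_cylinder_phantom(self):
        vol = pvloops.centerline_rotation_volume(_rectangle_contour())
        assert vol == pytest.approx(np.pi * 15**2 * 50 / 1000.0, rel=0.005)

    @pytest.mark.parametrize("k", [0.5, 2.0, 3.0])
    def test_cubic_scaling(self, k):
        base = ellipse_contour(40.0, 20.0)
        scaled = pvloops.LVContour(
            points=k * base.points,
            annulus_a=k * base.annulus_a,
            annulus_b=k * base.annulus_b,
            apex=k * base.apex,
            frame_time=0.0,
        )
        v0 = pvloops.centerline_rotation_volume(base)
        vk = pvloops.centerline_rotation_volume(scaled)
        assert vk == pytest.approx(k**3 * v0, rel=1e-6)

    def test_rigid_motion_invariance(self):
        v0 = pvloops.centerline_rotation_volume(ellipse_contour(40.0, 20.0))
        v1 = pvloops.centerline_rotation_volume(
            ellipse_contour(40.0, 20.0, rotate=0.646, shift=(12.0, -7.0))
        )
        assert v1 == pytest.approx(v0, rel=1e-3)

    def test_slab_convergence(self):
        contour = ellipse_contour(40.0, 20.0, n=1024)
        errs = []
        for n_slabs in (25, 50, 100):
            errs.append(
                abs(
                    pvloops.centerline_rotation_volume(contour, n_slabs)
                    - pvloops.centerline_rotation_volume(contour, 2 * n_slabs)
                )
            )
        assert errs[0] > errs[1] > errs[2]

    def test_self_intersecting_polygon_rejected(self):
        pts = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], dtype=float)
        with pytest.raises(errors.GeometryError):
            pvloops.LVContour(pts, pts[0], pts[2], pts[1], frame_time=0.0)

    def test_annulus_off_polygon_rejected(self):
        base = ellipse_contour(40.0, 20.0)
        with pytest.raises(errors.GeometryError):
            pvloops.LVContour(
                points=base.points,
                annulus_a=np.array([55.0, 55.0]),
                annulus_b=base.annulus_b,
                apex=base.apex,
                frame_time=0.0,
            )


class TestVolumeTimeseries:
    def test_recovers_prescribed_sinusoid(self):
        t = np.arange(40) * 0.076
        v_true = 90 + 20 * np.sin(2 * np.pi * t / 0.8)
        contours = pvloops.contours_from_volume(v_true, t)
        series = pvloops.volume_timeseries(contours)
        np.testing.assert_allclose(series.volumes, v_true, rtol=0.01)
        assert series.temporal_resolution == pytest.approx(0.076)

    def test_single_frame_rejected(self):
        contours = pvloops.contours_from_volume([100.0], [0.0])
        with pytest.raises(errors.TimingError):
            pvloops.volume_timeseries(contours)

    def test_identical_contours_constant_series(self):
        contours = pvloops.contours_from_volume([80.0] * 5, np.arange(5) * 0.076)
        series = pvloops.volume_timeseries(contours)
        assert np.ptp(series.volumes) < 1e-9 * 80.0


class TestEdEsDetection:
    def test_sinusoid_crests_and_troughs(self):
        t = np.arange(66) * 0.076  # ~5 s, 0.8 s cycles
        v = 90 + 20 * np.sin(2 * np.pi * t / 0.8)
        series = volumetrics.VolumeSeries(t, v, 0.076)
        fids = pvloops.detect_ed_es_volume(series)
        assert fids.es_indices.size == fids.ed_indices.size - 1
        # detected EDs sit on crests, ESs on troughs
        assert np.all(v[fids.ed_indices] > 100.0)
        assert np.all(v[fids.es_indices] < 80.0)
        # one ED per 0.8 s cycle
        np.testing.assert_allclose(np.diff(t[fids.ed_indices]), 0.8, atol=0.076)

    def test_matches_per_beat_extrema_oracle(self, dataset_clean):
        """On noise-free frames, detection reproduces the brute-force
        per-beat argmax/argmin exactly."""
        rec, contours, gt = dataset_clean
        series = pvloops.volume_timeseries(contours, n_slabs=100)
        fids = pvloops.detect_ed_es_volume(series)
        onsets = gt.ed_times[(gt.ed_times >= series.frame_times[0]) & (gt.ed_times <= series.frame_times[-1])]
        assert fids.ed_indices.size == onsets.size
        t, v = series.frame_times, series.volumes
        # beats during the occlusion maneuver proper (the balloon-release
        # recovery raises volume faster than the near-empty heart ejects,
        # so those transition beats have no meaningful interior extrema)
        p = gt.params
        occ = t[fids.ed_indices] < p.t_occ + p.t_release - 1.0
        for a, b in zip(fids.ed_indices[:-1][occ[:-1]], fids.ed_indices[1:][occ[:-1]]):
            es_expected = a + 1 + np.argmin(v[a + 1 : b])
            assert es_expected in fids.es_indices
        for k in range(1, fids.ed_indices.size - 1):
            if not occ[k]:
                continue
            lo, hi = fids.es_indices[k - 1], fids.es_indices[k]
            assert v[fids.ed_indices[k]] == np.max(v[lo : hi + 1])

    def test_ed_volume_never_below_es_volume(self, dataset_clean):
        _, contours, gt = dataset_clean
        series = pvloops.volume_timeseries(contours, n_slabs=100)
        fids = pvloops.detect_ed_es_volume(series)
        v, t = series.volumes, series.frame_times
        p = gt.params
        for k, es in enumerate(fids.es_indices):
            if t[fids.ed_indices[k]] >= p.t_occ + p.t_release - 1.0:
                continue
            assert v[fids.ed_indices[k]] >= v[es]
            assert v[fids.ed_indices[k + 1]] >= v[es]

    def test_monotone_series_rejected(self):
        t = np.arange(60) * 0.076
        series = volumetrics.VolumeSeries(t, 100.0 - t, 0.076)
        with pytest.raises(errors.DetectionError):
            pvloops.detect_ed_es_volume(series)


class TestUpsample:
    def test_linear_midpoint(self):
        series = volumetrics.VolumeSeries([0.0, 0.076], [100.0, 108.0], 0.076)
        up = pvloops.upsample_volume(series, 250.0)
        assert float(np.interp(0.038, up.frame_times, up.volumes)) == pytest.approx(104.0)

    def test_nodes_reproduced_exactly(self):
        t = np.arange(20) * 0.076
        v = 90 + 20 * np.sin(2 * np.pi * t / 0.8)
        series = volumetrics.VolumeSeries(t, v, 0.076)
        up = pvloops.upsample_volume(series, 250.0)
        # 76 ms = 19 x 4 ms: original frame times lie on the new grid
        np.testing.assert_allclose(np.interp(t, up.frame_times, up.volumes), v, atol=1e-9)
        assert len(up) == pytest.approx(19 * (len(series) - 1) + 1, abs=1)

    def test_rate_below_native_rejected(self):
        series = volumetrics.VolumeSeries([0.0, 0.076], [100.0, 108.0], 0.076)
        with pytest.raises(errors.ArgumentError):
            pvloops.upsample_volume(series, 10.0)


class TestContourIO:
    def test_roundtrip(self, tmp_path):
        t = np.arange(4) * 0.076
        contours = pvloops.contours_from_volume([60, 55, 50, 58], t)
        path = pvloops.write_contours(contours, tmp_path / "c.json")
        back = pvloops.read_contours(path)
        assert len(back) == 4
        np.testing.assert_allclose(back[1].points, contours[1].points, atol=1e-5)
        assert back[2].frame_time == pytest.approx(t[2])

    def test_pixel_converter(self):
        base = ellipse_contour(40.0, 20.0)
        spacing = 2.3
        converted = volumetrics.contour_from_pixels(
            base.points / spacing,
            base.annulus_a / spacing,
            base.annulus_b / spacing,
            base.apex / spacing,
            pixel_spacing_mm=spacing,
            frame_time=0.0,
        )
        np.testing.assert_allclose(converted.points, base.points, atol=1e-9)

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text('{"format": "something-else", "version": 1, "frames": []}')
        with pytest.raises(errors.GeometryError):
            pvloops.read_contours(path)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    volume=st.floats(min_value=20.0, max_value=280.0),
    a=st.floats(min_value=25.0, max_value=60.0),
)
def test_contour_volume_roundtrip_property(volume, a):
    """contours_from_volume inverts the centerline-rotation measurement."""
    contour = pvloops.contours_from_volume([volume], [0.0], a=a)[0]
    assert pvloops.centerline_rotation_volume(contour) == pytest.approx(volume, rel=0.01)
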