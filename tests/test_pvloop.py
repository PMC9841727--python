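"""PV-loop pairing, ESPVR/EDPVR fits, hemodynamic summaries."""

import numpy as np
import pandas as pd
import pytest

import pvloops
from pvloops import errors, pvloop


ES_POINTS = np.array([[50.0, 18.0], [60.0, 24.0], [70.0, 30.0]])  # P = 0.6 (V - 20)
ED_POINTS = np.array([[100.0, 8.0], [110.0, 10.0], [120.0, 12.0]])  # P = 0.2 V - 12


class TestFits:
    def test_espvr_exact_line(self):
        fit = pvloops.fit_espvr(ES_POINTS)
        assert fit.slope == pytest.approx(0.600, abs=1e-12)
        assert fit.v0 == pytest.approx(20.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.derived_metric == fit.slope
        assert fit.kind == "espvr"

    def test_edpvr_exact_line(self):
        fit = pvloops.fit_edpvr(ED_POINTS)
        assert fit.slope == pytest.approx(0.200, abs=1e-12)
        assert fit.derived_metric == pytest.approx(5.00, abs=1e-9)
        assert fit.kind == "edpvr"

    def test_two_points_insufficient(self):
        with pytest.raises(errors.InsufficientPointsError):
            pvloops.fit_espvr(ES_POINTS[:2])

    def test_zero_volume_variance_degenerate(self):
        pts = np.array([[60.0, 10.0], [60.0, 20.0], [60.0, 30.0]])
        with pytest.raises(errors.DegenerateFitError):
            pvloops.fit_espvr(pts)

    def test_negative_edpvr_slope_is_nonphysiological(self):
        pts = np.array([[100.0, 12.0], [110.0, 11.0], [120.0, 10.0]])  # slope -0.1
        with pytest.raises(errors.NonPhysiologicalFitError):
            pvloops.fit_edpvr(pts)

    def test_noise_perturbation_mean_slope(self):
        """Perturbing one collinear point by N(0, 0.5 mmHg) leaves the mean
        OLS slope within 2% of the true 0.6 mmHg/ml over 1000 seeds."""
        rng = np.random.default_rng(7)
        slopes = []
        for _ in range(1000):
            pts = ES_POINTS.copy()
            pts[1, 1] += rng.normal(0.0, 0.5)
            slopes.append(pvloops.fit_espvr(pts).slope)
        assert np.mean(slopes) == pytest.approx(0.6, rel=0.02)

    def test_fit_invariant_to_point_order(self):
        rng = np.random.default_rng(3)
        pts = ES_POINTS + rng.normal(0, 0.3, ES_POINTS.shape)
        a = pvloops.fit_espvr(pts)
        b = pvloops.fit_espvr(pts[::-1])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)


def _beat(edv=100.0, esv=60.0, hr=75.0, edp=8.0, esp=30.0, peak=80.0):
    t = np.linspace(0.0, 60.0 / hr, 50)
    return pvloop.PairedBeat(
        beat_index=0,
        time=t,
        volume=np.linspace(edv, esv, 50),
        pressure=np.linspace(edp, esp, 50),
        ed_point=(edv, edp),
        es_point=(esv, esp),
        ed_end_point=(edv, edp),
        rr=60.0 / hr,
        peak_lvp=peak,
    )


class TestHemoSummary:
    def test_arithmetic(self):
        s = pvloops.hemodynamic_summary(_beat())
        assert s.sv == pytest.approx(40.0)
        assert s.ef == pytest.approx(40.0)
        assert s.co == pytest.approx(3.00, abs=1e-9)
        assert s.hr == pytest.approx(75.0)

    def test_degenerate_zero_ejection(self):
        s = pvloops.hemodynamic_summary(_beat(edv=80.0, esv=80.0))
        assert s.ef == 0.0

    def test_missing_fiducial_raises(self):
        beat = _beat()
        beat.es_point = (float("nan"), 30.0)
        with pytest.raises(errors.IncompleteBeatError):
            pvloops.hemodynamic_summary(beat)


class TestOcclusionResponse:
    def test_percent_change_arithmetic(self):
        first = _beat(peak=80.0, esv=60.0, hr=75.0)
        last = _beat(peak=65.6, esv=42.0, hr=76.0)
        loops = pvloop.PVLoopSet(beats=[first, last], sample_rate=250.0)
        resp = pvloops.occlusion_response(loops)
        assert resp.peak_lvp_reduction_pct == pytest.approx(18.0)
        assert resp.esv_reduction_pct == pytest.approx(30.0)
        assert resp.hr_increase_pct == pytest.approx(100 * (76 / 75 - 1))

    def test_constant_signals_zero_change(self):
        loops = pvloop.PVLoopSet(beats=[_beat(), _beat()], sample_rate=250.0)
        resp = pvloops.occlusion_response(loops)
        assert resp.peak_lvp_reduction_pct == 0.0
        assert resp.esv_reduction_pct == 0.0
        assert resp.hr_increase_pct == 0.0


class TestPairing:
    def test_beat_count_mismatch_raises(self, result_clean, dataset_clean):
        rec, contours, gt = dataset_clean
        fids = result_clean.pressure_fids
        vfids = result_clean.volume_fids
        # drop one volume-side beat -> counts disagree
        import dataclasses

        broken = dataclasses.replace(
            vfids,
            ed_indices=vfids.ed_indices[:-1],
            es_indices=vfids.es_indices[:-1],
            ed_times=vfids.ed_times[:-1],
            es_times=vfids.es_times[:-1],
            ed_volumes=vfids.ed_volumes[:-1],
            es_volumes=vfids.es_volumes[:-1],
        )
        with pytest.raises(errors.PairingError, match="beats"):
            pvloops.pair_pv(
                fids,
                result_clean.beat_table,
                result_clean.volume_series.frame_times,
                result_clean.volume_series.volumes,
                broken,
                result_clean.volume_series,
                onset=result_clean.onset,
            )

    def test_ten_loops_returned(self, result_clean):
        assert result_clean.loops.n_beats == 10

    def test_es_point_matches_true_simultaneous_state(self, result_clean, gt_clean):
        """Noise-free pairing: each ES point sits within (1 ml, 1 mmHg) of
        the true simultaneous state at the true end-systolic time."""
        es_true = gt_clean.es_points()
        table = result_clean.beat_table
        for beat in result_clean.loops.beats:
            k_global = int(np.argmin(np.abs(gt_clean.ed_times - table.loc[beat.beat_index, "ed_start_s"])))
            v_true, p_true = es_true[k_global]
            assert abs(beat.es_point[0] - v_true) < 1.0
            assert abs(beat.es_point[1] - p_true) < 1.0

    def test_loop_orientation_positive_area(self, result_clean):
        for beat in result_clean.loops.beats:
            assert beat.signed_area > 0.0

    def test_ed_points_lie_on_trajectory(self, result_clean):
        # the ED time is sub-sample refined, so the first grid sample of the
        # trajectory sits within one 4 ms step of the ED point
        for beat in result_clean.loops.beats:
            step = np.max(np.abs(np.diff(beat.volume[:5]))) + 1e-9
            assert abs(beat.ed_point[0] - beat.volume[0]) <= step

    def test_espvr_reorder_invariance(self, result_clean):
        pts = result_clean.loops.es_points
        a = pvloops.fit_espvr(pts)
        b = pvloops.fit_espvr(pts[::-1])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
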