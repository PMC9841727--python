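"""Recording I/O, gradient-fiducial window detection, and resampling."""

import numpy as np
import pandas as pd
import pytest

import pvloops
from pvloops import errors, physio_io

from conftest import clean_params


def _small_recording(n=1000, fs=1000.0):
    t = np.arange(n) / fs
    return pvloops.PhysioRecording(
        sample_rate=fs,
        time=t,
        ecg=np.sin(2 * np.pi * 1.3 * t),
        lvp=20 + 10 * np.sin(2 * np.pi * 1.3 * t),
        aop=30 + 5 * np.cos(2 * np.pi * 1.3 * t),
        gradient=np.vstack([np.cos(2 * np.pi * 50 * t), np.zeros(n)]),
    )


class TestReadWrite:
    def test_roundtrip_reproduces_samples(self, tmp_path):
        rec = _small_recording()
        path = physio_io.write_recording(rec, tmp_path / "rec.csv")
        back = physio_io.read_recording(path)
        assert back.sample_rate == pytest.approx(1000.0)
        assert len(back) == len(rec)
        for a, b in ((rec.lvp, back.lvp), (rec.ecg[0], back.ecg[0]), (rec.aop, back.aop)):
            np.testing.assert_allclose(a, b, atol=1e-9, rtol=1e-9)

    def test_minimal_four_column_file(self, tmp_path):
        n = 1000
        df = pd.DataFrame(
            {
                "time_s": np.arange(n) / 1000.0,
                "ecg_i": np.zeros(n),
                "lvp_mmhg": np.ones(n),
                "grad_x": np.zeros(n),
            }
        )
        path = tmp_path / "min.csv"
        df.to_csv(path, index=False)
        rec = physio_io.read_recording(path)
        assert len(rec) == 1000
        assert rec.sample_rate == pytest.approx(1000.0)
        assert rec.aop is None

    def test_missing_required_column_raises(self, tmp_path):
        df = pd.DataFrame({"time_s": [0, 0.001], "ecg_i": [0, 0], "grad_x": [0, 0]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(errors.FormatError, match="lvp_mmhg"):
            physio_io.read_recording(path)

    def test_nonuniform_timestamps_rejected(self):
        t = np.arange(100) / 1000.0
        t[50] += 0.0005
        with pytest.raises(errors.TimingError):
            pvloops.PhysioRecording(
                sample_rate=1000.0, time=t, ecg=np.zeros(100), lvp=np.zeros(100),
                gradient=np.zeros(100),
            )


class TestImagingWindow:
    def test_recovers_burst_edges_within_one_sample(self, dataset_clean):
        rec, _, gt = dataset_clean
        win = physio_io.detect_imaging_window(rec)
        true = pvloops.synth.DEFAULT_IMAGING_WINDOW
        assert abs(win.start - true.start) <= 1.0 / rec.sample_rate + 1e-9
        assert abs(win.end - true.end) <= 2.0 / rec.sample_rate + 1e-9

    def test_invariant_to_sign_and_scale(self, dataset_clean):
        rec, _, _ = dataset_clean
        ref = physio_io.detect_imaging_window(rec)
        flipped = pvloops.PhysioRecording(
            sample_rate=rec.sample_rate, time=rec.time, ecg=rec.ecg, lvp=rec.lvp,
            aop=rec.aop, gradient=-7.3 * rec.gradient,
        )
        win = physio_io.detect_imaging_window(flipped)
        assert win.start == pytest.approx(ref.start, abs=1e-9)
        assert win.end == pytest.approx(ref.end, abs=1e-9)

    def test_zero_gradient_raises(self):
        rec = _small_recording()
        rec.gradient[:] = 0.0
        with pytest.raises(errors.NoWindowError):
            physio_io.detect_imaging_window(rec)


class TestExtractWindow:
    def test_crop_sample_count(self):
        rec = _small_recording(n=10001)
        out = physio_io.extract_window(rec, pvloops.TimeInterval(2.0, 8.0))
        assert len(out) == 6001
        assert out.time[0] == pytest.approx(2.0)
        assert out.sample_rate == rec.sample_rate

    def test_full_range_is_identity(self):
        rec = _small_recording()
        out = physio_io.extract_window(rec, pvloops.TimeInterval(rec.time[0], rec.time[-1]))
        np.testing.assert_array_equal(out.lvp, rec.lvp)

    def test_out_of_range_raises(self):
        rec = _small_recording()
        with pytest.raises(errors.BoundsError):
            physio_io.extract_window(rec, pvloops.TimeInterval(0.5, 2.0))


class TestDownsample:
    def test_fourfold_1khz_to_250hz(self):
        rec = _small_recording(n=4000)
        out = physio_io.downsample(rec, 4)
        assert out.sample_rate == pytest.approx(250.0)
        assert len(out) == 1000
        # duration preserved within one output sample
        assert abs(out.duration - rec.duration) <= 1.0 / out.sample_rate

    def test_factor_one_identity(self):
        rec = _small_recording()
        out = physio_io.downsample(rec, 1)
        np.testing.assert_array_equal(out.lvp, rec.lvp)

    def test_dc_preserved(self):
        rec = _small_recording(n=4000)
        rec.lvp[:] = 7.0
        out = physio_io.downsample(rec, 4)
        np.testing.assert_allclose(out.lvp, 7.0, atol=1e-9)

    def test_sinusoid_amplitude_preserved(self):
        fs, n = 1000.0, 8000
        t = np.arange(n) / fs
        f = 250.0 / 4  # output-Nyquist/2 after fourfold decimation
        rec = pvloops.PhysioRecording(
            sample_rate=fs, time=t, ecg=np.zeros(n), lvp=np.sin(2 * np.pi * f * t),
            gradient=np.zeros(n),
        )
        out = physio_io.downsample(rec, 4)
        interior = out.lvp[100:-100]
        assert np.max(np.abs(interior)) == pytest.approx(1.0, rel=0.01)

    def test_non_integer_factor_rejected(self):
        rec = _small_recording()
        with pytest.raises(errors.ArgumentError):
            physio_io.downsample(rec, 2.5)
        with pytest.raises(errors.ArgumentError):
            physio_io.downsample(rec, 0)

    def test_crop_downsample_commute_on_bandlimited_signal(self):
        fs, n = 1000.0, 12000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * 5 * t) + 0.5 * np.sin(2 * np.pi * 17 * t)
        rec = pvloops.PhysioRecording(
            sample_rate=fs, time=t, ecg=np.zeros(n), lvp=x, gradient=np.zeros(n)
        )
        win = pvloops.TimeInterval(2.0, 10.0)
        a = physio_io.downsample(physio_io.extract_window(rec, win), 4)
        b = physio_io.extract_window(physio_io.downsample(rec, 4), win)
        m = min(len(a), len(b))
        # compare away from the crop edges, where the zero-phase filter
        # transients of the two orderings differ
        sl = slice(50, m - 50)
        dev = np.max(np.abs(a.lvp[sl] - b.lvp[sl])) / np.ptp(x)
        assert dev < 1e-6
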