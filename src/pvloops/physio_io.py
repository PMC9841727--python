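"""Multichannel physiological recordings: data model, CSV I/O, imaging-window
extraction from MR gradient activity, and anti-aliased downsampling.

The recording model mirrors a hemodynamic recording system operating inside the
scanner room: a multi-lead ECG, one or two invasive blood pressures, and the MR
gradient waveforms, all sampled synchronously at 1 kHz. The gradient channels
carry no physiology but mark exactly when the real-time image acquisition ran,
which is what lets pressure and image-derived volume be paired on one clock.

CSV dialect
-----------
Header ``time_s,ecg_i,ecg_ii,lvp_mmhg,aop_mmhg,grad_x,grad_y,grad_z`` with
``ecg_ii``, ``aop_mmhg``, ``grad_y`` and ``grad_z`` optional; decimal point,
UTF-8, one row per sample. The writer emits 12 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ArgumentError, BoundsError, FormatError, NoWindowError, TimingError

__all__ = [
    "PhysioRecording",
    "TimeInterval",
    "read_recording",
    "write_recording",
    "detect_imaging_window",
    "extract_window",
    "downsample",
]

#: tolerance (s) on uniformity of the time grid
_UNIFORMITY_TOL = 1e-6

_REQUIRED_COLUMNS = ("time_s", "ecg_i", "lvp_mmhg", "grad_x")


@dataclass
class TimeInterval:
    """Closed interval [start, end] in seconds from recording start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ArgumentError(f"interval end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class PhysioRecording:
    """Synchronized multichannel physiological time series.

    Parameters
    ----------
    sample_rate : float
        Sampling frequency in Hz, > 0.
    time : ndarray, shape (n,)
        Timestamps in seconds, strictly increasing, uniformly spaced at
        ``1/sample_rate`` within 1e-6 s.
    ecg : ndarray, shape (n_leads, n)
        ECG voltage channels in mV; lead 0 is the dominant lead used for
        R-peak detection.
    lvp : ndarray, shape (n,)
        Left-ventricular pressure in mmHg.
    aop : ndarray, shape (n,), optional
        Aortic pressure in mmHg.
    gradient : ndarray, shape (n_axes, n)
        MR gradient-activity channels, arbitrary units.
    meta : dict
        Free-form annotations (subject id, notes, ...).
    """

    sample_rate: float
    time: np.ndarray
    ecg: np.ndarray
    lvp: np.ndarray
    gradient: np.ndarray
    aop: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ecg = np.atleast_2d(np.asarray(self.ecg, dtype=float))
        self.lvp = np.asarray(self.lvp, dtype=float)
        self.gradient = np.atleast_2d(np.asarray(self.gradient, dtype=float))
        if self.aop is not None:
            self.aop = np.asarray(self.aop, dtype=float)
        if self.sample_rate <= 0:
            raise ArgumentError("sample_rate must be positive")
        n = self.time.size
        for name, ch in (("ecg", self.ecg), ("lvp", self.lvp), ("gradient", self.gradient)):
            if ch.shape[-1] != n:
                raise FormatError(f"channel '{name}' length {ch.shape[-1]} != time length {n}")
        if self.aop is not None and self.aop.size != n:
            raise FormatError(f"channel 'aop' length {self.aop.size} != time length {n}")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise TimingError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sample_rate)) > _UNIFORMITY_TOL:
                raise TimingError(
                    "timestamps deviate from uniform spacing "
                    f"1/{self.sample_rate} Hz by more than {_UNIFORMITY_TOL} s"
                )

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def index_of(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (s)."""
        return int(round((t - self.time[0]) * self.sample_rate))


def read_recording(path: str | Path) -> PhysioRecording:
    """Read a recording from the CSV dialect described in the module docstring.

    Raises
    ------
    FormatError
        If a required column is missing.
    TimingError
        If timestamps are non-uniform beyond tolerance.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"recording file not found: {path}")
    df = pd.read_csv(path)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"recording file {path} is missing required column '{col}'")
    time = df["time_s"].to_numpy(float)
    if time.size < 2:
        raise FormatError(f"recording file {path} has fewer than 2 samples")
    sample_rate = 1.0 / float(np.median(np.diff(time)))
    # snap to an integer rate when within tolerance (1 kHz hardware clock)
    if abs(sample_rate - round(sample_rate)) < 1e-3:
        sample_rate = float(round(sample_rate))
    ecg_cols = ["ecg_i"] + (["ecg_ii"] if "ecg_ii" in df.columns else [])
    grad_cols = ["grad_x"] + [c for c in ("grad_y", "grad_z") if c in df.columns]
    return PhysioRecording(
        sample_rate=sample_rate,
        time=time,
        ecg=df[ecg_cols].to_numpy(float).T,
        lvp=df["lvp_mmhg"].to_numpy(float),
        aop=df["aop_mmhg"].to_numpy(float) if "aop_mmhg" in df.columns else None,
        gradient=df[grad_cols].to_numpy(float).T,
        meta={"source": str(path)},
    )


def write_recording(rec: PhysioRecording, path: str | Path) -> Path:
    """Write ``rec`` in the CSV dialect (12 significant digits)."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_s": rec.time, "ecg_i": rec.ecg[0]}
    if rec.ecg.shape[0] > 1:
        cols["ecg_ii"] = rec.ecg[1]
    cols["lvp_mmhg"] = rec.lvp
    if rec.aop is not None:
        cols["aop_mmhg"] = rec.aop
    for i, name in enumerate(("grad_x", "grad_y", "grad_z")[: rec.gradient.shape[0]]):
        cols[name] = rec.gradient[i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    return path


def _gradient_envelope(gradient: np.ndarray, sample_rate: float, window_s: float = 0.05) -> np.ndarray:
    """Sliding-RMS envelope of the combined gradient channels.

    Multi-axis channels are combined as the root of the mean square across
    axes, making the envelope invariant to per-axis sign and (overall)
    amplitude scaling once normalized to its maximum.
    """
    power = np.mean(np.square(gradient), axis=0)
    n_win = max(1, int(round(window_s * sample_rate)))
    kernel = np.ones(n_win) / n_win
    smoothed = np.convolve(power, kernel, mode="same")
    return np.sqrt(np.maximum(smoothed, 0.0))


def detect_imaging_window(
    rec: PhysioRecording,
    threshold_frac: float = 0.1,
    min_gap: float = 0.2,
) -> TimeInterval:
    """Locate the image-acquisition window from recorded MR gradient activity.

    A sliding-RMS envelope (50 ms window) of the combined gradient channels is
    thresholded at ``threshold_frac`` of its maximum; sub-threshold gaps
    shorter than ``min_gap`` (sequence dead-times within one acquisition) are
    merged. Because the RMS envelope smears burst edges by up to half its
    window, the interval edges are refined to the first/last raw sample whose
    rectified amplitude exceeds ``threshold_frac`` of the global maximum,
    restoring single-sample edge accuracy.

    Raises
    ------
    NoWindowError
        If the envelope never exceeds the threshold (e.g. all-zero gradients).
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ArgumentError("threshold_frac must lie in (0, 1)")
    env = _gradient_envelope(rec.gradient, rec.sample_rate)
    peak = float(np.max(env))
    if peak <= 0.0:
        raise NoWindowError("gradient channels carry no activity")
    mask = env > threshold_frac * peak
    if not np.any(mask):
        raise NoWindowError("gradient envelope never exceeds the detection threshold")
    idx = np.flatnonzero(mask)
    # merge sub-threshold gaps shorter than min_gap, then span first..last
    first, last = int(idx[0]), int(idx[-1])
    # edge refinement on the rectified raw signal
    amp = np.max(np.abs(rec.gradient), axis=0)
    amp_thr = threshold_frac * float(np.max(amp))
    pad = int(round(0.05 * rec.sample_rate))
    lo = max(0, first - pad)
    hi = min(len(rec) - 1, last + pad)
    seg = np.flatnonzero(amp[lo : hi + 1] >= amp_thr)
    if seg.size:
        first, last = lo + int(seg[0]), lo + int(seg[-1])
    if last <= first:
        raise NoWindowError("detected imaging window has zero length")
    return TimeInterval(float(rec.time[first]), float(rec.time[last]))


def extract_window(rec: PhysioRecording, win: TimeInterval) -> PhysioRecording:
    """Crop all channels to the closed interval ``win`` (inclusive endpoints).

    Raises
    ------
    BoundsError
        If the window extends beyond the recorded time range.
    """
    eps = 0.5 / rec.sample_rate
    if win.start < rec.time[0] - eps or win.end > rec.time[-1] + eps:
        raise BoundsError(
            f"window [{win.start}, {win.end}] s outside recording range "
            f"[{rec.time[0]}, {rec.time[-1]}] s"
        )
    i0 = int(np.searchsorted(rec.time, win.start - eps))
    i1 = int(np.searchsorted(rec.time, win.end + eps)) - 1
    sl = slice(i0, i1 + 1)
    return PhysioRecording(
        sample_rate=rec.sample_rate,
        time=rec.time[sl].copy(),
        ecg=rec.ecg[:, sl].copy(),
        lvp=rec.lvp[sl].copy(),
        aop=None if rec.aop is None else rec.aop[sl].copy(),
        gradient=rec.gradient[:, sl].copy(),
        meta=dict(rec.meta),
    )


def _antialias(x: np.ndarray, cutoff_norm: float) -> np.ndarray:
    """Zero-phase 8th-order Butterworth low-pass (no group delay, preserves DC)."""
    sos = signal.butter(8, cutoff_norm, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def downsample(rec: PhysioRecording, factor: int) -> PhysioRecording:
    """Anti-aliased decimation by an integer ``factor``.

    A zero-phase low-pass at 0.8x the output Nyquist precedes decimation so
    fiducial timing is preserved (no group delay). ``factor=1`` returns the
    recording unchanged. The gradient channels are decimated without
    filtering: they are timing markers whose edges must not be smeared.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ArgumentError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return rec
    if len(rec) < factor:
        raise ArgumentError("recording shorter than the downsampling factor")
    cutoff = 0.8 / factor  # 0.8 x output Nyquist, normalized to input Nyquist
    sl = slice(None, None, factor)
    return PhysioRecording(
        sample_rate=rec.sample_rate / factor,
        time=rec.time[sl].copy(),
        ecg=_antialias(rec.ecg, cutoff)[:, sl],
        lvp=_antialias(rec.lvp, cutoff)[sl],
        aop=None if rec.aop is None else _antialias(rec.aop, cutoff)[sl],
        gradient=rec.gradient[:, sl].copy(),
        meta=dict(rec.meta),
    )
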