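"""Per-beat fiducials: end-diastole from ECG R-peaks, end-systole from the LV
pressure waveform, and occlusion-onset identification.

End-diastole is taken at the ECG R-peak (ventricular activation onset); the
detections are then populated onto the synchronously sampled LV pressure.
End-systole is operationalized as the minimum of the smoothed pressure
derivative dP/dt — the standard hemodynamic surrogate for the onset of
isovolumic relaxation, when the aortic valve has just closed and pressure
starts its (near-exponential) decay at constant volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import (
    ArgumentError,
    DetectionError,
    InsufficientDataError,
    OnsetNotFoundError,
)
from .physio_io import PhysioRecording

__all__ = [
    "FiducialSet",
    "detect_r_peaks",
    "detect_es_pressure",
    "populate_pressure_fiducials",
    "find_occlusion_onset",
    "BEAT_TABLE_COLUMNS",
]

BEAT_TABLE_COLUMNS = [
    "beat",
    "ed_start_s",
    "es_s",
    "ed_end_s",
    "peak_lvp_mmhg",
    "edp_mmhg",
    "esp_mmhg",
    "rr_s",
    "flag",
]

#: shortest physiologically admissible beat (s)
_MIN_BEAT = 0.2
#: ES search starts this long after ED, past the QRS-coincident upstroke (s)
_ES_BLANK = 0.1


@dataclass
class FiducialSet:
    """Per-beat end-diastole / end-systole timestamps for one modality.

    ``ed_times`` are strictly increasing; each ``es_times[k]`` lies strictly
    inside ``(ed_times[k], ed_times[k+1])`` (NaN marks a rejected beat), so
    ``len(es_times) = len(ed_times) - 1``.
    """

    ed_times: np.ndarray
    es_times: np.ndarray
    source: str  # "pressure" | "volume"

    def __post_init__(self) -> None:
        self.ed_times = np.asarray(self.ed_times, dtype=float)
        self.es_times = np.asarray(self.es_times, dtype=float)
        if np.any(np.diff(self.ed_times) <= 0):
            raise ArgumentError("ed_times must be strictly increasing")
        if self.es_times.size != self.ed_times.size - 1:
            raise ArgumentError("need exactly one es per complete beat (len(ed) - 1)")
        ok = ~np.isnan(self.es_times)
        inside = (self.es_times > self.ed_times[:-1]) & (self.es_times < self.ed_times[1:])
        if not np.all(inside[ok]):
            raise ArgumentError("each es time must lie strictly inside its beat")

    @property
    def n_beats(self) -> int:
        return self.es_times.size


def _parabolic_peak(y: np.ndarray, i: int, dt: float) -> float:
    """Sub-sample offset (s) of the parabola vertex through y[i-1:i+2]."""
    if i <= 0 or i >= y.size - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-300:
        return 0.0
    return float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -0.5, 0.5)) * dt


def detect_r_peaks(
    ecg: np.ndarray,
    sample_rate: float,
    refractory: float = 0.2,
) -> np.ndarray:
    """R-peak timestamps from one ECG lead.

    Pipeline: zero-phase band-pass 5-25 Hz, squaring, adaptive threshold at
    0.4x the rolling 2 s maximum of the squared signal, one peak per
    supra-threshold region, greedy refractory enforcement, and parabolic
    sub-sample refinement. Detections are invariant to amplitude scaling of
    the input (the threshold is relative).

    Raises
    ------
    DetectionError
        If the lead is flat or no peak survives.
    """
    ecg = np.asarray(ecg, dtype=float)
    if refractory <= 0:
        raise ArgumentError("refractory must be positive")
    if ecg.size < sample_rate:
        raise InsufficientDataError("need at least 1 s of ECG")
    if np.ptp(ecg) == 0:
        raise DetectionError("flat-line ECG: no R-peaks")

    sos = signal.butter(3, [5.0, 25.0], btype="bandpass", fs=sample_rate, output="sos")
    filt = signal.sosfiltfilt(sos, ecg)
    sq = filt**2
    win = max(3, int(round(2.0 * sample_rate)))
    rolling_max = ndimage.maximum_filter1d(sq, size=win, mode="nearest")
    mask = sq >= 0.4 * rolling_max
    # one candidate per contiguous supra-threshold region
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise DetectionError("no R-peak candidates above threshold")
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    regions = np.split(idx, splits)
    candidates = [int(r[np.argmax(sq[r])]) for r in regions]

    dt = 1.0 / sample_rate
    peaks: list[float] = []
    for i in candidates:
        t = i * dt + _parabolic_peak(sq, i, dt)
        if peaks and t - peaks[-1] < refractory:
            continue
        peaks.append(t)
    if not peaks:
        raise DetectionError("no R-peaks after refractory enforcement")
    return np.asarray(peaks)


def _relaxation_onset(
    phases: np.ndarray, p_ens: np.ndarray, acc: np.ndarray, j: int
) -> float | None:
    """Changepoint refinement of the pooled end-systolic phase.

    Once isovolumic relaxation starts, ventricular pressure decays
    (near-)exponentially, so around end-systole the ensemble-averaged
    pressure is a gently curving systolic shoulder that breaks into an
    exponential fall. The break point — the onset of isovolumic relaxation
    proper — is recovered by least-squares fitting the two-piece model

        p(phi) = a + b*(phi-phi0) + e*(phi-phi0)^2        phi <= phi0
                 c + (a - c) * exp(-(phi-phi0)/tau)       phi >  phi0

    to the ensemble pressure near the dP/dt trough. Fitting the pressure
    (noise-averaged across beats) instead of chasing the smoothed dP/dt
    argmin removes the lateness that symmetric smoothing imposes on a
    one-sided trough. The model is linear in (a, b, e, c) given
    (phi0, tau), so those two are scanned on a grid — a global, exactly
    reproducible fit with no risk of a local minimum.

    The refinement engages only when the fitted model exhibits a material
    derivative discontinuity at the break point (initial decay rate well
    above the shoulder slope) and beats a smooth quadratic: fitting a
    smooth waveform (say a sinusoidal pressure) yields near-continuous
    derivatives and self-rejects, leaving such signals to the plain argmin.
    """
    dt = phases[1] - phases[0]
    # anchor on a heavily smoothed trough: its own lateness is harmless
    # because the changepoint is refit, while noise dips average away
    acc_w = ndimage.uniform_filter1d(acc, size=9, mode="nearest")
    jw = int(np.argmin(acc_w))
    anchor_w = float(phases[jw])
    lo = max(0, int(round((anchor_w - phases[0] - 0.10) / dt)))
    hi = min(acc.size, int(round((anchor_w - phases[0] + 0.05) / dt)))
    x, y = phases[lo:hi], p_ens[lo:hi]
    if x.size < 12:
        return None

    phi0_grid = x[(x >= anchor_w - 0.055) & (x <= anchor_w + 0.005 + 1e-12)]
    if phi0_grid.size < 3:
        return None
    tau_grid = np.geomspace(0.03, 0.4, 10)
    rss_curve = np.full(phi0_grid.size, np.inf)
    best_kink = np.zeros(phi0_grid.size)
    for i, phi0 in enumerate(phi0_grid):
        rel = x - phi0
        shoulder = rel <= 0.0
        for tau in tau_grid:
            decay = np.exp(-np.clip(rel, 0.0, None) / tau)
            col_a = np.where(shoulder, 1.0, decay)
            col_b = np.where(shoulder, rel, 0.0)
            col_e = np.where(shoulder, rel**2, 0.0)
            col_c = np.where(shoulder, 0.0, 1.0 - decay)
            design = np.column_stack([col_a, col_b, col_e, col_c])
            coef, rss, _, _ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(rss[0]) if rss.size else float(np.sum((design @ coef - y) ** 2))
            if rss < rss_curve[i]:
                rss_curve[i] = rss
                a, b, _, c = coef
                decay_rate = (a - c) / tau  # slope magnitude entering the decay
                best_kink[i] = decay_rate / max(abs(b), 1e-9)
    ib = int(np.argmin(rss_curve))
    phi0 = float(phi0_grid[ib]) + _parabolic_peak(rss_curve, ib, dt)
    rmse = np.sqrt(rss_curve[ib] / x.size)
    rmse_quad = float(np.sqrt(np.mean((np.polyval(np.polyfit(x, y, 2), x) - y) ** 2)))
    if best_kink[ib] < 2.5:  # derivative nearly continuous: no real corner
        return None
    if not (rmse < rmse_quad and phases[0] < phi0):
        return None
    return phi0


def detect_es_pressure(
    lvp: np.ndarray,
    sample_rate: float,
    ed_times: np.ndarray,
    smooth_ms: float = 20.0,
    pool_phase: bool = True,
    guard: float = 0.006,
) -> np.ndarray:
    """End-systole per beat: minimum of the smoothed dP/dt.

    dP/dt is estimated with a zero-phase Savitzky-Golay derivative (local
    quadratic over a ``smooth_ms`` window), which is far less noisy than
    differencing at the same bandwidth. The window is kept short because
    the dP/dt trough sits at the foot of a one-sided exponential pressure
    decay, which wide symmetric smoothing drags late. The search window for
    beat k is (ed_k + 0.1 s, ed_{k+1}): the first 100 ms are blanked to
    skip the QRS-coincident upstroke, and argmins are refined to sub-sample
    precision with a parabola.

    With ``pool_phase`` (default), the beats are ensemble-averaged: the
    electromechanical ED-to-ES interval is stable across beats of a steady
    rhythm, so the beat-synchronously averaged dP/dt locates the common ES
    phase with the noise suppressed by the square root of the beat count;
    the trough position is further refined by a changepoint fit of its
    steep flank and exponential tail (see :func:`_relaxation_corner`). The
    pooled phase is then populated to every beat — mirroring how the
    ECG-derived end-diastoles are populated to the pressure signal — and a
    beat is flagged when its own dP/dt shows no relaxation within
    ``+- guard`` seconds of that phase. Without pooling each beat is
    searched over its full window independently.

    Returns one timestamp per complete beat; beats shorter than 0.2 s or
    with a non-negative dP/dt minimum (no relaxation) are flagged NaN with a
    warning rather than silently dropped.
    """
    lvp = np.asarray(lvp, dtype=float)
    ed_times = np.asarray(ed_times, dtype=float)
    if ed_times.size < 2:
        raise InsufficientDataError("need at least 2 end-diastole times")
    dt = 1.0 / sample_rate
    n_win = max(5, int(round(smooth_ms * 1e-3 * sample_rate)) | 1)  # odd
    dpdt_s = signal.savgol_filter(lvp, n_win, polyorder=2, deriv=1, delta=dt, mode="nearest")
    t_axis = np.arange(lvp.size) * dt

    valid = [
        k
        for k in range(ed_times.size - 1)
        if ed_times[k + 1] - ed_times[k] >= _MIN_BEAT
    ]
    for k in range(ed_times.size - 1):
        if k not in valid:
            warnings.warn(f"beat {k} shorter than {_MIN_BEAT} s; rejected", stacklevel=2)

    phase_star = None
    if pool_phase and len(valid) >= 3:
        # beat-synchronous ensemble average of dP/dt on a common phase grid,
        # weighted by each beat's dP/dt-trough depth so beats with a deep,
        # unambiguous relaxation set the phase
        rr_min = min(ed_times[k + 1] - ed_times[k] for k in valid)
        phases = np.arange(_ES_BLANK, rr_min - dt, dt)
        segs = np.array([np.interp(ed_times[k] + phases, t_axis, dpdt_s) for k in valid])
        p_segs = np.array([np.interp(ed_times[k] + phases, t_axis, lvp) for k in valid])
        depths = np.maximum(-segs.min(axis=1), 0.0)
        w = np.where(depths >= 0.5 * depths.max(), depths, 0.0)
        if w.sum() <= 0:
            w = depths
        if w.sum() > 0:
            acc = (w[:, None] * segs).sum(axis=0) / w.sum()
            # single-beat noise dips are 1-3 samples wide while the true
            # trough is broad: a short moving average suppresses the former
            acc = ndimage.uniform_filter1d(acc, size=5, mode="nearest")
            # amplitude-normalized ensemble pressure for onset refinement,
            # restricted to the strongest beats (homogeneous preload, least
            # relative noise)
            w_p = w
            span = np.maximum(p_segs.max(axis=1) - p_segs.min(axis=1), 1e-12)
            p_norm = (p_segs - p_segs.min(axis=1, keepdims=True)) / span[:, None]
            p_ens = (w_p[:, None] * p_norm).sum(axis=0) / w_p.sum()
            j = int(np.argmin(acc))
            if acc[j] < 0:
                phase_star = phases[j] + _parabolic_peak(acc, j, dt)
                onset = _relaxation_onset(phases, p_ens, acc, j)
                if onset is not None:
                    phase_star = onset

    es = np.full(ed_times.size - 1, np.nan)
    for k in valid:
        t0, t1 = ed_times[k], ed_times[k + 1]
        if phase_star is not None:
            # populate the pooled phase; flag beats without local relaxation
            t_es = t0 + phase_star
            i0 = max(int(np.floor((t_es - guard) / dt)), 0)
            i1 = min(int(np.ceil((t_es + guard) / dt)), lvp.size - 1)
            if i1 <= i0 or np.min(dpdt_s[i0 : i1 + 1]) >= 0:
                warnings.warn(
                    f"beat {k} has no usable pressure relaxation near the pooled "
                    "end-systolic phase; flagged",
                    stacklevel=2,
                )
                continue
            if t0 < t_es < t1:
                es[k] = t_es
            continue
        i0 = max(int(np.ceil((t0 + _ES_BLANK) / dt)), 0)
        i1 = min(int(np.floor(t1 / dt)), lvp.size - 1)
        if i1 - i0 < 1:
            warnings.warn(f"beat {k} search window too short; rejected", stacklevel=2)
            continue
        seg = dpdt_s[i0 : i1 + 1]
        j = int(np.argmin(seg))
        if seg[j] >= 0:
            warnings.warn(
                f"beat {k} has no usable pressure relaxation (dP/dt min >= 0); flagged",
                stacklevel=2,
            )
            continue
        t_es = (i0 + j) * dt + _parabolic_peak(seg, j, dt)
        if t0 < t_es < t1:
            es[k] = t_es
    return es


def populate_pressure_fiducials(
    rec: PhysioRecording,
    refractory: float = 0.2,
    exclude: tuple[int, ...] = (),
) -> tuple[FiducialSet, pd.DataFrame]:
    """ECG-derived ED times populated onto the LV pressure, plus a beat table.

    Returns the pressure-side :class:`FiducialSet` and a per-beat table with
    columns ``beat, ed_start_s, es_s, ed_end_s, peak_lvp_mmhg, edp_mmhg,
    esp_mmhg, rr_s, flag``. EDP is read at the ED sample index; ESP is
    linearly interpolated at the (sub-sample) ES time. Beats listed in
    ``exclude`` (manual-correction list) or failing detection are flagged,
    never dropped from the table.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 R-peaks are found.
    """
    t0 = rec.time[0]
    ed_rel = detect_r_peaks(rec.ecg[0], rec.sample_rate, refractory)
    if ed_rel.size < 3:
        raise InsufficientDataError(f"only {ed_rel.size} beats detected; need at least 3")
    es_rel = detect_es_pressure(rec.lvp - 0.0, rec.sample_rate, ed_rel)
    ed = ed_rel + t0
    es = es_rel + t0

    rows = []
    for k in range(ed.size - 1):
        ed_start, ed_end, es_k = ed[k], ed[k + 1], es[k]
        i_start = rec.index_of(ed_start)
        i_end = rec.index_of(ed_end)
        seg = rec.lvp[i_start : i_end + 1]
        flag = ""
        if k in exclude:
            flag = "excluded"
        elif np.isnan(es_k):
            flag = "rejected"
        rows.append(
            {
                "beat": k,
                "ed_start_s": ed_start,
                "es_s": es_k,
                "ed_end_s": ed_end,
                "peak_lvp_mmhg": float(np.max(seg)),
                "edp_mmhg": float(rec.lvp[i_start]),
                "esp_mmhg": float(np.interp(es_k, rec.time, rec.lvp)) if not np.isnan(es_k) else np.nan,
                "rr_s": ed_end - ed_start,
                "flag": flag,
            }
        )
    table = pd.DataFrame(rows, columns=BEAT_TABLE_COLUMNS)
    return FiducialSet(ed_times=ed, es_times=es, source="pressure"), table


def find_occlusion_onset(beats: pd.DataFrame, config_time: float | None = None) -> int:
    """Index of the first beat after balloon inflation.

    With ``config_time`` given: the first beat whose ED start is at or after
    that time. Otherwise auto-detection: the first beat whose peak LV
    pressure falls below (baseline mean - 2 x baseline SD), the baseline
    being the first 3 beats.

    Raises
    ------
    InsufficientDataError
        If fewer than 12 beats are available.
    OnsetNotFoundError
        If auto-detection finds no qualifying beat.
    """
    if len(beats) < 12:
        raise InsufficientDataError(f"need >= 12 beats to locate the occlusion, got {len(beats)}")
    if config_time is not None:
        qualifying = np.flatnonzero(beats["ed_start_s"].to_numpy() >= config_time)
        if qualifying.size == 0:
            raise OnsetNotFoundError(f"no beat starts at or after t = {config_time} s")
        return int(qualifying[0])
    peaks = beats["peak_lvp_mmhg"].to_numpy(float)
    baseline = peaks[:3]
    threshold = float(np.mean(baseline) - 2.0 * np.std(baseline, ddof=1))
    below = np.flatnonzero(peaks[3:] < threshold)
    if below.size == 0:
        raise OnsetNotFoundError(
            "no beat falls below the baseline pressure threshold; "
            "supply the occlusion time in the configuration"
        )
    return int(below[0] + 3)
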