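"""Lumped-parameter cardiovascular simulator with IVC-occlusion preload decay.

The left ventricle follows a time-varying elastance law

    P_lv(t) = E(t) * (V(t) - V0),      E(t) = Emin + (Emax - Emin) * e_hat(t)

with a normalized activation ``e_hat`` that rises as a double-Hill function,
sustains peak elastance over a short plateau, and relaxes exponentially.
The exponential relaxation matters: in a real ventricle pressure decays
(near-)exponentially from the onset of isovolumic relaxation, which is
exactly why the dP/dt minimum marks end-systole. A sigmoidal (pure
double-Hill) descent would instead place the dP/dt minimum mid-relaxation,
making the detected end-systolic pressure an arbitrary fraction of the true
end-systolic elastance line.

Filling and ejection are resistive valve flows against a venous source and
a two-element windkessel:

    dV/dt     = (P_ven - P_lv)/r_mv   while P_ven > P_lv        (filling)
                -(P_lv - P_ao)/r_av   while P_lv > P_ao         (ejection)
    dP_ao/dt  = (Q_out - P_ao/r_per) / c_ao

The venous pressure models the inferior-vena-cava balloon protocol: it sits
at ``p_ven0`` until the occlusion at ``t_occ``, decays exponentially with
``tau_occ`` while the balloon is inflated, and recovers toward baseline
with ``tau_rec`` once the balloon is deflated ``t_release`` seconds later
(the maneuver lasts 15-20 s in practice). Ground truth carries the per-beat
true ED (activation onset) and true ES (peak-elastance plateau end) times;
true ES states lie on P = Emax*(V - V0) by construction, so the full
pipeline can be scored by parameter recovery.

Rendering converts ground truth into measurement-like signals: an ECG
template train with R-peaks at activation onsets, pressures with optional
second-order fluid-filled-catheter damping and Gaussian noise, trapezoidal
MR gradient bursts confined to the imaging window, and long-axis contour
sequences whose centerline-rotation volume realizes the (noisy) volume
trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, model_validator
from scipy import signal as _signal

from .errors import BoundsError, ConfigurationError
from .physio_io import PhysioRecording, TimeInterval, write_recording
from .volumetrics import LVContour, write_contours

__all__ = [
    "ElastanceParams",
    "GroundTruth",
    "DEFAULT_IMAGING_WINDOW",
    "simulate",
    "render_recording",
    "render_volume_frames",
    "contours_from_volume",
    "make_fixture",
]

#: default image-acquisition window: 326 timeframes at 76 ms starting 2 s in
DEFAULT_IMAGING_WINDOW = TimeInterval(2.0, 2.0 + 326 * 0.076)

#: real-time cine frame period (s)
FRAME_PERIOD = 0.076


class ElastanceParams(BaseModel):
    """Simulator ground-truth parameters.

    Defaults are scale-matched to a healthy juvenile porcine ventricle as a
    design choice (heart rate 77 bpm; end-systolic elastance 0.6 mmHg/ml and
    passive stiffness 0.2 mmHg/ml, i.e. compliance 5 ml/mmHg), so recovered
    contractility/compliance are magnitude-comparable with in-vivo reports.
    """

    emax: float = 0.6  # end-systolic elastance (mmHg/ml)
    emin: float = 0.2  # passive stiffness (mmHg/ml)
    v0: float = 10.0  # unstressed volume (ml)
    hr: float = 77.0  # heart rate (bpm)
    tau1: float | None = None  # activation rise time constant (s); default 0.215*T
    tau2: float | None = None  # Hill descent time constant (s); default 0.362*T
    n1: float = 1.32  # rise Hill exponent
    n2: float = 21.9  # descent Hill exponent
    tau_rel: float = 0.12  # exponential relaxation time constant (s)
    t_plateau: float = 0.03  # duration of sustained peak elastance (s)
    r_mv: float = 0.05  # mitral (filling) resistance (mmHg*s/ml)
    r_av: float = 0.008  # aortic (ejection) resistance (mmHg*s/ml)
    r_per: float = 0.9  # peripheral resistance (mmHg*s/ml)
    c_ao: float = 0.8  # arterial compliance (ml/mmHg)
    p_ven0: float = 10.0  # baseline venous pressure (mmHg)
    t_occ: float = 5.0  # occlusion time (s)
    tau_occ: float = 5.0  # preload decay constant (s)
    t_release: float = 16.0  # occlusion duration before balloon deflation (s)
    tau_rec: float = 1.0  # venous-return recovery constant after deflation (s)
    noise_p: float = 1.0  # pressure noise SD (mmHg)
    noise_v: float = 2.0  # volume noise SD (ml)
    noise_ecg: float = 0.02  # ECG noise SD (mV)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ElastanceParams":
        if not self.emax > self.emin > 0:
            raise ConfigurationError("need emax > emin > 0")
        positive = {
            "hr": self.hr,
            "n1": self.n1,
            "n2": self.n2,
            "tau_rel": self.tau_rel,
            "r_mv": self.r_mv,
            "r_av": self.r_av,
            "r_per": self.r_per,
            "c_ao": self.c_ao,
            "p_ven0": self.p_ven0,
            "tau_occ": self.tau_occ,
            "t_release": self.t_release,
            "tau_rec": self.tau_rec,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.t_plateau < 0:
            raise ConfigurationError("t_plateau must be non-negative")
        for name, value in (("noise_p", self.noise_p), ("noise_v", self.noise_v)):
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        return self

    @property
    def period(self) -> float:
        """Beat period T (s)."""
        return 60.0 / self.hr


class _Activation:
    """Normalized activation e_hat(phase).

    The contraction rises as a double-Hill function, sustains peak
    elastance over a short plateau (``t_plateau``; the ejecting ventricle
    stays near maximal stiffness for tens of milliseconds, during which the
    aortic valve closes), and then relaxes exponentially with time constant
    ``tau_rel``, the way ventricular pressure decays from the onset of
    isovolumic relaxation. End-systole is the plateau end — the last
    instant of maximal elastance. The junctions are rounded with a short
    circular Gaussian (2 ms) so the waveform is smooth, and the profile is
    renormalized to unit peak so the true end-systolic elastance equals
    Emax. The profile is precomputed on a dense phase grid and evaluated by
    interpolation.
    """

    _GRID_STEP = 2.5e-4  # s
    _SMOOTH_SD = 2e-3  # s

    def __init__(self, p: ElastanceParams):
        T = p.period
        self.T = T
        self.tau1 = p.tau1 if p.tau1 is not None else 0.215 * T
        self.tau2 = p.tau2 if p.tau2 is not None else 0.362 * T
        self.n1, self.n2 = p.n1, p.n2
        self.tau_rel = p.tau_rel

        n = int(round(T / self._GRID_STEP))
        dphi = T / n
        phi = np.arange(n) * dphi
        h = self._hill(np.maximum(phi, 1e-12))
        ip = int(np.argmax(h))
        tp_raw = float(phi[ip])
        t_es = tp_raw + p.t_plateau  # end of the peak-elastance plateau
        prof = h / h[ip]
        prof = np.where((phi >= tp_raw) & (phi <= t_es), 1.0, prof)
        decay = np.exp(-(phi - t_es) / self.tau_rel)
        prof = np.where(phi > t_es, decay, prof)
        # residual relaxation tail wrapped into the next beat keeps E continuous
        prof = np.maximum(prof, np.exp(-((phi + T) - t_es) / self.tau_rel))
        # smooth the junctions (circular, so the wrap stays continuous)
        m = int(round(4 * self._SMOOTH_SD / dphi))
        kern = np.exp(-0.5 * (np.arange(-m, m + 1) * dphi / self._SMOOTH_SD) ** 2)
        kern /= kern.sum()
        prof = np.convolve(np.tile(prof, 3), kern, mode="same")[n : 2 * n]
        prof /= prof.max()
        self.t_peak = t_es
        self._phi = phi
        self._prof = prof

    def _hill(self, phi: np.ndarray) -> np.ndarray:
        x1 = (phi / self.tau1) ** self.n1
        with np.errstate(over="ignore"):
            x2 = (phi / self.tau2) ** self.n2
        return (x1 / (1.0 + x1)) / (1.0 + x2)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate e_hat at absolute times ``t`` (beats start at k*T)."""
        phi = np.mod(t, self.T)
        return np.interp(phi, self._phi, self._prof, period=self.T)


@dataclass
class GroundTruth:
    """Continuous (fine-grid) simulator output plus true fiducials."""

    time: np.ndarray
    p_lv: np.ndarray
    volume: np.ndarray
    p_ao: np.ndarray
    p_ven: np.ndarray
    q_in: np.ndarray
    q_out: np.ndarray
    fine_rate: float
    ed_times: np.ndarray  # activation onsets (true end-diastole)
    es_times: np.ndarray  # peak-elastance times (true end-systole), one per complete beat
    occlusion_beat: int  # index of first beat starting at/after t_occ
    params: ElastanceParams
    meta: dict = field(default_factory=dict)

    @property
    def espvr_slope(self) -> float:
        """True ESPVR slope (contractility) = Emax."""
        return self.params.emax

    @property
    def compliance(self) -> float:
        """True compliance = 1/Emin."""
        return 1.0 / self.params.emin

    def sample(self, channel: str, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.time, getattr(self, channel))

    def es_points(self) -> np.ndarray:
        """True per-beat end-systolic (V, P) states; collinear on P = Emax*(V-V0)."""
        v = self.sample("volume", self.es_times)
        p = self.sample("p_lv", self.es_times)
        return np.column_stack([v, p])

    def ed_points(self) -> np.ndarray:
        """True per-beat end-diastolic (V, P) states at activation onsets."""
        ed = self.ed_times[: len(self.es_times)]
        return np.column_stack([self.sample("volume", ed), self.sample("p_lv", ed)])


def simulate(
    params: ElastanceParams | None = None,
    duration: float = 30.0,
    fine_rate: float = 2000.0,
) -> GroundTruth:
    """Integrate the elastance-windkessel model with fixed-step RK4.

    A steady-state warm-up (four beats at baseline preload, discarded) sets
    the initial condition, so pre-occlusion beats are periodic from t = 0.

    Raises
    ------
    ConfigurationError
        If the duration does not cover >= 5 beats before and >= 12 beats
        after the occlusion, or fine_rate < 2 kHz.
    """
    p = params or ElastanceParams()
    T = p.period
    if fine_rate < 2000.0:
        raise ConfigurationError("fine_rate must be at least 2 kHz")
    if p.t_occ < 5 * T - 1e-9:
        raise ConfigurationError(f"t_occ={p.t_occ} covers fewer than 5 beats before occlusion")
    if duration - p.t_occ < 12 * T - 1e-9:
        raise ConfigurationError("duration covers fewer than 12 beats after occlusion")

    act = _Activation(p)
    dt = 1.0 / fine_rate
    n = int(round(duration * fine_rate))
    # elastance and venous pressure on the half-step grid for RK4
    t_half = np.arange(2 * n + 1) * (0.5 * dt)
    e_half = p.emin + (p.emax - p.emin) * act(t_half)
    pv_half = np.where(
        t_half < p.t_occ, p.p_ven0, p.p_ven0 * np.exp(-np.maximum(t_half - p.t_occ, 0.0) / p.tau_occ)
    )
    # balloon deflation: venous return recovers toward baseline
    t_rel = p.t_occ + p.t_release
    pv_at_rel = p.p_ven0 * np.exp(-p.t_release / p.tau_occ)
    recovery = p.p_ven0 + (pv_at_rel - p.p_ven0) * np.exp(-np.maximum(t_half - t_rel, 0.0) / p.tau_rec)
    pv_half = np.where(t_half >= t_rel, recovery, pv_half)

    def rhs(v: float, pao: float, e: float, pven: float) -> tuple[float, float]:
        plv = e * (v - p.v0)
        q_in = (pven - plv) / p.r_mv if pven > plv else 0.0
        q_out = (plv - pao) / p.r_av if plv > pao else 0.0
        return q_in - q_out, (q_out - pao / p.r_per) / p.c_ao

    def rk4(v: float, pao: float, e0: float, e1: float, e2: float, pv0: float, pv1: float, pv2: float):
        k1v, k1a = rhs(v, pao, e0, pv0)
        k2v, k2a = rhs(v + 0.5 * dt * k1v, pao + 0.5 * dt * k1a, e1, pv1)
        k3v, k3a = rhs(v + 0.5 * dt * k2v, pao + 0.5 * dt * k2a, e1, pv1)
        k4v, k4a = rhs(v + dt * k3v, pao + dt * k3a, e2, pv2)
        return (
            v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v),
            pao + dt / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a),
        )

    # warm-up to periodic steady state at baseline preload
    n_warm = int(round(4 * T * fine_rate))
    t_warm = np.arange(2 * n_warm + 1) * (0.5 * dt)
    e_warm = p.emin + (p.emax - p.emin) * act(t_warm)
    v, pao = p.v0 + p.p_ven0 / p.emin, 2.0 * p.p_ven0
    for i in range(n_warm):
        v, pao = rk4(v, pao, e_warm[2 * i], e_warm[2 * i + 1], e_warm[2 * i + 2], p.p_ven0, p.p_ven0, p.p_ven0)
    # realign warm-up end to an activation onset: 4*T is an exact beat boundary

    vol = np.empty(n + 1)
    pao_arr = np.empty(n + 1)
    vol[0], pao_arr[0] = v, pao
    for i in range(n):
        v, pao = rk4(
            v, pao,
            e_half[2 * i], e_half[2 * i + 1], e_half[2 * i + 2],
            pv_half[2 * i], pv_half[2 * i + 1], pv_half[2 * i + 2],
        )
        vol[i + 1], pao_arr[i + 1] = v, pao

    time = np.arange(n + 1) * dt
    e_t = e_half[::2]
    p_ven = pv_half[::2]
    p_lv = e_t * (vol - p.v0)
    q_in = np.where(p_ven > p_lv, (p_ven - p_lv) / p.r_mv, 0.0)
    q_out = np.where(p_lv > pao_arr, (p_lv - pao_arr) / p.r_av, 0.0)

    n_beats = int(np.floor(duration / T + 1e-9))
    ed_times = np.arange(n_beats + 1) * T
    ed_times = ed_times[ed_times <= duration + 1e-9]
    es_times = ed_times[:-1] + act.t_peak
    occ_beat = int(np.searchsorted(ed_times, p.t_occ - 1e-9))
    return GroundTruth(
        time=time,
        p_lv=p_lv,
        volume=vol,
        p_ao=pao_arr,
        p_ven=p_ven,
        q_in=q_in,
        q_out=q_out,
        fine_rate=fine_rate,
        ed_times=ed_times,
        es_times=es_times,
        occlusion_beat=occ_beat,
        params=p,
        meta={"t_peak": act.t_peak},
    )


def _gaussian_train(t: np.ndarray, centers: np.ndarray, amp: float, sigma: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        lo = np.searchsorted(t, c - 6 * sigma)
        hi = np.searchsorted(t, c + 6 * sigma)
        out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return out


def _ecg_lead(t: np.ndarray, onsets: np.ndarray, T: float, t_peak: float) -> np.ndarray:
    """Unit-R Gaussian template train: P and T waves plus the dominant R."""
    ecg = _gaussian_train(t, onsets, 1.0, 0.012)  # R at activation onset
    ecg += _gaussian_train(t, onsets - 0.17 * T, 0.12, 0.025)  # P wave
    ecg += _gaussian_train(t, onsets + t_peak + 0.10 * T, 0.25, 0.045)  # T wave
    return ecg


def _trapezoid_pulse(phase: np.ndarray, ramp: float, plateau: float) -> np.ndarray:
    """Single trapezoid centred at phase 0: plateau +-plateau/2, ramps beyond."""
    a = np.abs(phase)
    half = 0.5 * plateau
    return np.clip(1.0 - (a - half) / ramp, 0.0, 1.0) * (a < half + ramp)


def _gradient_channels(t: np.ndarray, window: TimeInterval) -> np.ndarray:
    """Three-axis trapezoidal burst train, exactly zero outside the window.

    Pulses repeat every 20 ms with channel phase offsets of one third period,
    so at any instant inside the window at least one channel is above 10% of
    the maximum: the window edges stay recoverable to single-sample accuracy.
    """
    period, ramp, plateau = 0.02, 0.002, 0.008
    amps = (1.0, 0.8, 0.9)
    inside = (t >= window.start - 1e-12) & (t <= window.end + 1e-12)
    psi = t - window.start
    out = np.zeros((3, t.size))
    for c in range(3):
        ph = np.mod(psi - c * period / 3.0 + period / 2.0, period) - period / 2.0
        out[c] = amps[c] * _trapezoid_pulse(ph, ramp, plateau) * inside
    return out


def render_recording(
    gt: GroundTruth,
    params: ElastanceParams | None = None,
    sample_rate: float = 1000.0,
    imaging_window: TimeInterval | None = None,
    damping: tuple[float, float] | None = None,
) -> PhysioRecording:
    """Render measurement-like 1 kHz channels from ground truth.

    ``damping`` is an optional fluid-filled-catheter model ``(fn, zeta)``: a
    causal second-order low-pass with natural frequency ``fn`` (Hz) and
    damping ratio ``zeta`` applied to the LV pressure (underdamped zeta < 1
    produces the systolic overshoot seen with air bubbles in the line).
    Gaussian noise SDs come from ``params`` (``noise_p``, ``noise_ecg``);
    set them to 0 for noise-free signals.
    """
    p = params or gt.params
    window = imaging_window or DEFAULT_IMAGING_WINDOW
    if sample_rate > gt.fine_rate:
        raise ConfigurationError("sample_rate cannot exceed the simulation fine_rate")
    if window.start < gt.time[0] - 1e-9 or window.end > gt.time[-1] + 1e-9:
        raise BoundsError("imaging window lies outside the simulated time span")

    n = int(np.floor(gt.time[-1] * sample_rate + 1e-9)) + 1
    t = np.arange(n) / sample_rate

    lvp_fine = gt.p_lv
    if damping is not None:
        fn, zeta = damping
        wn = 2.0 * np.pi * fn
        b, a = _signal.bilinear([wn**2], [1.0, 2.0 * zeta * wn, wn**2], fs=gt.fine_rate)
        zi = _signal.lfilter_zi(b, a) * lvp_fine[0]
        lvp_fine, _ = _signal.lfilter(b, a, lvp_fine, zi=zi)
    lvp = np.interp(t, gt.time, lvp_fine)
    aop = np.interp(t, gt.time, gt.p_ao)

    T = p.period
    onsets = gt.ed_times
    ecg_i = _ecg_lead(t, onsets, T, gt.meta.get("t_peak", 0.3 * T))
    ecg_ii = 0.8 * ecg_i

    rng = np.random.default_rng([int(p.seed), 7])
    if p.noise_p > 0:
        lvp = lvp + rng.normal(0.0, p.noise_p, lvp.size)
        aop = aop + rng.normal(0.0, p.noise_p, aop.size)
    if p.noise_ecg > 0:
        ecg_i = ecg_i + rng.normal(0.0, p.noise_ecg, ecg_i.size)
        ecg_ii = ecg_ii + rng.normal(0.0, p.noise_ecg, ecg_ii.size)

    return PhysioRecording(
        sample_rate=sample_rate,
        time=t,
        ecg=np.vstack([ecg_i, ecg_ii]),
        lvp=lvp,
        aop=aop,
        gradient=_gradient_channels(t, window),
        meta={"synthetic": True, "seed": p.seed, "imaging_window": [window.start, window.end]},
    )


def render_volume_frames(
    gt: GroundTruth,
    params: ElastanceParams | None = None,
    imaging_window: TimeInterval | None = None,
    frame_period: float = FRAME_PERIOD,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame times and (noisy) frame volumes inside the imaging window."""
    p = params or gt.params
    window = imaging_window or DEFAULT_IMAGING_WINDOW
    n_frames = int(np.floor(window.duration / frame_period + 1e-9)) + 1
    frame_times = window.start + np.arange(n_frames) * frame_period
    vols = gt.sample("volume", frame_times)
    if p.noise_v > 0:
        rng = np.random.default_rng([int(p.seed), 11])
        vols = vols + rng.normal(0.0, p.noise_v, vols.size)
    return frame_times, np.maximum(vols, 1.0)


def contours_from_volume(
    volumes: np.ndarray,
    frame_times: np.ndarray,
    a: float = 40.0,
    n_points: int = 128,
) -> list[LVContour]:
    """Full-ellipse contours whose centerline-rotation volume equals ``volumes``.

    Each frame is an ellipse with long semi-axis ``a`` (mm, along the
    centerline) and short semi-axis ``b = sqrt(3000*V/(4*pi*a))`` (V in ml),
    the inversion of the prolate-spheroid volume 4/3*pi*a*b^2. The annulus
    chord degenerates to the basal vertex and the apex is the opposite
    vertex, so the centerline is the full long axis.
    """
    volumes = np.asarray(volumes, dtype=float)
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(volumes <= 0) or a <= 0:
        raise ConfigurationError("volumes and semi-axis a must be positive")
    n_points = max(int(n_points), 128)
    n_points += (-n_points) % 4  # multiple of 4: both vertices land on the polygon
    theta = np.pi / 2 + 2.0 * np.pi * np.arange(n_points) / n_points
    contours = []
    for v_ml, ft in zip(volumes, frame_times):
        b = np.sqrt(3000.0 * v_ml / (4.0 * np.pi * a))
        pts = np.column_stack([b * np.cos(theta), a * np.sin(theta)])
        basal = np.array([0.0, a])
        apex = np.array([0.0, -a])
        pts[0] = basal  # exact vertices despite floating-point cos/sin
        pts[n_points // 2] = apex
        contours.append(
            LVContour(points=pts, annulus_a=basal, annulus_b=basal, apex=apex, frame_time=float(ft))
        )
    return contours


def make_fixture(
    outdir: str | Path,
    params: ElastanceParams | None = None,
    duration: float = 30.0,
    imaging_window: TimeInterval | None = None,
    damping: tuple[float, float] | None = None,
) -> dict[str, Path]:
    """Emit a complete matched dataset: recording CSV + contour file + ground-truth sidecar."""
    p = params or ElastanceParams()
    window = imaging_window or DEFAULT_IMAGING_WINDOW
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gt = simulate(p, duration=duration)
    rec = render_recording(gt, p, imaging_window=window, damping=damping)
    frame_times, vols = render_volume_frames(gt, p, imaging_window=window)
    contours = contours_from_volume(vols, frame_times)

    paths = {
        "recording": outdir / "recording.csv",
        "contours": outdir / "contours.json",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_recording(rec, paths["recording"])
    write_contours(contours, paths["contours"])
    sidecar = {
        "params": p.model_dump(),
        "true_contractility_mmhg_per_ml": gt.espvr_slope,
        "true_compliance_ml_per_mmhg": gt.compliance,
        "true_v0_ml": p.v0,
        "ed_times_s": gt.ed_times.tolist(),
        "es_times_s": gt.es_times.tolist(),
        "occlusion_beat": gt.occlusion_beat,
        "imaging_window_s": [window.start, window.end],
        "duration_s": duration,
    }
    paths["ground_truth"].write_text(json.dumps(sidecar, indent=1))
    return paths
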