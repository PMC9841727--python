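"""Pairing pressure and volume into per-beat PV loops, ESPVR/EDPVR fitting,
and hemodynamic summaries.

During an IVC occlusion the venous return falls beat by beat, sweeping the
end-systolic and end-diastolic working points across the PV plane. A linear
fit of the end-systolic points is the end-systolic pressure-volume
relationship (ESPVR), whose slope is the load-independent contractility
index (mmHg/ml); a linear fit of the end-diastolic points is the EDPVR,
whose inverse slope is compliance (ml/mmHg). Only the first beats after
balloon inflation are used (default 10) so the sympathetic response to the
preload drop does not change inotropy mid-fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ArgumentError,
    DegenerateFitError,
    IncompleteBeatError,
    InsufficientDataError,
    InsufficientPointsError,
    NonPhysiologicalFitError,
    PairingError,
)
from .beat_detection import FiducialSet
from .volumetrics import VolumeFiducials, VolumeSeries

__all__ = [
    "PairedBeat",
    "PVLoopSet",
    "PVRFit",
    "HemoSummary",
    "OcclusionResponse",
    "pair_pv",
    "fit_espvr",
    "fit_edpvr",
    "hemodynamic_summary",
    "occlusion_response",
]

#: warn when heart rate rises more than this across the included beats
_HR_DRIFT_WARN = 0.05


@dataclass
class PairedBeat:
    """One cardiac cycle as a paired (volume, pressure) trajectory."""

    beat_index: int  # index in the beat table
    time: np.ndarray  # pressure-grid timestamps (s)
    volume: np.ndarray  # warped volume on that grid (ml)
    pressure: np.ndarray  # LV pressure (mmHg)
    ed_point: tuple[float, float]  # (V, P) at beat-start end-diastole
    es_point: tuple[float, float]  # (V, P) at end-systole
    ed_end_point: tuple[float, float]  # (V, P) at next end-diastole
    rr: float
    peak_lvp: float

    @property
    def signed_area(self) -> float:
        """Loop area via the shoelace rule; positive when ejection runs at
        higher pressure than filling (counter-clockwise in the (V, P) plane
        traversed in time)."""
        v, p = self.volume, self.pressure
        return 0.5 * float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


@dataclass
class PVLoopSet:
    """Per-beat PV loops over the analysis window."""

    beats: list[PairedBeat]
    sample_rate: float
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    @property
    def ed_points(self) -> np.ndarray:
        return np.array([b.ed_point for b in self.beats])

    @property
    def es_points(self) -> np.ndarray:
        return np.array([b.es_point for b in self.beats])


@dataclass
class PVRFit:
    """Linear pressure-volume relationship fit.

    ``derived_metric`` is the contractility (= slope, mmHg/ml) for an ESPVR
    fit and the compliance (= 1/slope, ml/mmHg) for an EDPVR fit. ``v0`` is
    the volume-axis intercept when the slope is positive.
    """

    slope: float
    intercept: float
    v0: float
    r2: float
    n_points: int
    kind: str  # "espvr" | "edpvr"
    derived_metric: float


@dataclass
class HemoSummary:
    """Single-beat hemodynamic summary (conventionally the first recorded
    heartbeat before the occlusion)."""

    edv: float  # ml
    esv: float  # ml
    sv: float  # ml
    ef: float  # %
    co: float  # l/min
    hr: float  # bpm
    edp: float  # mmHg
    esp: float  # mmHg
    peak_lvp: float  # mmHg


@dataclass
class OcclusionResponse:
    """Percent changes from the first to the last included beat."""

    peak_lvp_reduction_pct: float
    esv_reduction_pct: float
    hr_increase_pct: float
    n_beats: int


def _check_points(points: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ArgumentError(f"{kind} points must be an (n, 2) array of (V, P)")
    if pts.shape[0] < 3:
        raise InsufficientPointsError(f"{kind} fit needs at least 3 points, got {pts.shape[0]}")
    v, p = pts[:, 0], pts[:, 1]
    if np.ptp(v) == 0:
        raise DegenerateFitError(f"{kind} fit is degenerate: all volumes equal")
    return v, p


def fit_espvr(es_points: np.ndarray) -> PVRFit:
    """Ordinary least squares of P on V through the end-systolic points.

    The slope is the contractility (end-systolic elastance, mmHg/ml);
    ``v0 = -intercept/slope`` is reported for positive slopes.
    """
    v, p = _check_points(es_points, "ESPVR")
    res = stats.linregress(v, p)
    slope, intercept = float(res.slope), float(res.intercept)
    v0 = -intercept / slope if slope > 0 else float("nan")
    return PVRFit(
        slope=slope,
        intercept=intercept,
        v0=v0,
        r2=float(res.rvalue) ** 2,
        n_points=len(v),
        kind="espvr",
        derived_metric=slope,
    )


def fit_edpvr(ed_points: np.ndarray) -> PVRFit:
    """Ordinary least squares of P on V through the end-diastolic points.

    Compliance is the inverse slope (ml/mmHg). The EDPVR is treated as
    linear over the occlusion's operating range; a non-positive fitted slope
    is non-physiological and raised as an error rather than clamped.
    """
    v, p = _check_points(ed_points, "EDPVR")
    res = stats.linregress(v, p)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise NonPhysiologicalFitError(
            f"EDPVR slope {slope:.4g} mmHg/ml is non-positive; compliance undefined"
        )
    return PVRFit(
        slope=slope,
        intercept=intercept,
        v0=-intercept / slope,
        r2=float(res.rvalue) ** 2,
        n_points=len(v),
        kind="edpvr",
        derived_metric=1.0 / slope,
    )


def pair_pv(
    pressure_fids: FiducialSet,
    beat_table: pd.DataFrame,
    pressure_time: np.ndarray,
    pressure: np.ndarray,
    volume_fids: VolumeFiducials,
    volume_series: VolumeSeries,
    onset: int,
    n_beats: int = 10,
    exclude: tuple[int, ...] = (),
) -> PVLoopSet:
    """Pair and align pressure and volume into per-beat PV loops.

    The pressure- and volume-side beat counts must agree (they are detected
    independently; a mismatch means a fiducial error, reported with both
    counts). For each included beat the volume timeline is piecewise-
    linearly warped so its ED_k, ES_k, ED_{k+1} land on the pressure-side
    fiducials, then evaluated on the pressure sampling grid. Up to
    ``n_beats`` unflagged beats starting at ``onset`` are returned; flagged
    or excluded beats are skipped and later beats take their place.

    Raises
    ------
    PairingError
        If pressure- and volume-side beat counts differ.
    InsufficientDataError
        If fewer than 3 usable beats remain.
    """
    if n_beats < 3:
        raise ArgumentError("n_beats must be at least 3")
    n_p = pressure_fids.ed_times.size
    n_v = volume_fids.ed_indices.size
    if n_p != n_v:
        raise PairingError(
            f"pressure side detected {n_p} beats but volume side {n_v}; "
            "check fiducial detections before pairing"
        )

    sample_rate = 1.0 / float(np.median(np.diff(pressure_time)))
    beats: list[PairedBeat] = []
    rows = beat_table.set_index("beat")
    for k in range(onset, n_p - 1):
        if len(beats) >= n_beats:
            break
        row = rows.loc[k]
        if row["flag"] != "" or k in exclude or np.isnan(row["es_s"]):
            continue
        ped0, pes, ped1 = row["ed_start_s"], row["es_s"], row["ed_end_s"]
        ved0, ves, ved1 = (
            float(volume_fids.ed_times[k]),
            float(volume_fids.es_times[k]),
            float(volume_fids.ed_times[k + 1]),
        )
        i0, i1 = np.searchsorted(pressure_time, [ped0, ped1])
        i1 = min(i1, pressure_time.size - 1)
        t_grid = pressure_time[i0:i1]
        # piecewise-linear time warp anchored at ED, ES, next ED
        t_vol = np.interp(t_grid, [ped0, pes, ped1], [ved0, ves, ved1])
        v_grid = volume_series.at(t_vol)
        p_grid = pressure[i0:i1]
        es_v = float(volume_series.at(ves))
        beats.append(
            PairedBeat(
                beat_index=int(k),
                time=t_grid,
                volume=np.asarray(v_grid),
                pressure=p_grid,
                ed_point=(float(volume_series.at(ved0)), float(row["edp_mmhg"])),
                es_point=(es_v, float(row["esp_mmhg"])),
                ed_end_point=(float(volume_series.at(ved1)), float(np.interp(ped1, pressure_time, pressure))),
                rr=float(row["rr_s"]),
                peak_lvp=float(row["peak_lvp_mmhg"]),
            )
        )
    if len(beats) < 3:
        raise InsufficientDataError(f"only {len(beats)} usable beats after onset; need >= 3")

    hr = 60.0 / np.array([b.rr for b in beats])
    if hr[-1] > (1.0 + _HR_DRIFT_WARN) * hr[0]:
        warnings.warn(
            f"heart rate rose {100 * (hr[-1] / hr[0] - 1):.1f}% across the included beats; "
            "inotropy may have changed (autonomic response)",
            stacklevel=2,
        )
    return PVLoopSet(beats=beats, sample_rate=sample_rate, meta={"onset": onset, "n_requested": n_beats})


def hemodynamic_summary(beat: PairedBeat) -> HemoSummary:
    """Single-beat summary: EDV/ESV from the volume fiducials, SV = EDV-ESV,
    EF = 100*SV/EDV, CO = SV*HR/1000, pressures from the beat table.

    Raises
    ------
    IncompleteBeatError
        If a fiducial is missing (NaN).
    """
    edv, edp = beat.ed_point
    esv, esp = beat.es_point
    values = [edv, esv, edp, esp, beat.rr, beat.peak_lvp]
    if any(np.isnan(v) for v in values):
        raise IncompleteBeatError(f"beat {beat.beat_index} is missing a fiducial")
    sv = edv - esv
    ef = 100.0 * sv / edv if edv > 0 else float("nan")
    hr = 60.0 / beat.rr
    return HemoSummary(
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ef,
        co=sv * hr / 1000.0,
        hr=hr,
        edp=edp,
        esp=esp,
        peak_lvp=beat.peak_lvp,
    )


def occlusion_response(loops: PVLoopSet) -> OcclusionResponse:
    """Percent change from the first to the last included beat.

    Reductions are reported as ``100*(x_first - x_last)/x_first`` for peak
    LV pressure and end-systolic volume; the heart-rate change is
    sign-flipped so a positive number is an increase.
    """
    if loops.n_beats < 2:
        raise InsufficientDataError("need at least 2 loops for an occlusion response")
    first, last = loops.beats[0], loops.beats[-1]
    peak_red = 100.0 * (first.peak_lvp - last.peak_lvp) / first.peak_lvp
    esv_red = 100.0 * (first.es_point[0] - last.es_point[0]) / first.es_point[0]
    hr_inc = 100.0 * (60.0 / last.rr - 60.0 / first.rr) / (60.0 / first.rr)
    return OcclusionResponse(
        peak_lvp_reduction_pct=peak_red,
        esv_reduction_pct=esv_red,
        hr_increase_pct=hr_inc,
        n_beats=loops.n_beats,
    )
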