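"""End-to-end orchestration of the PV-loop derivation pipeline.

Stages mirror the acquisition chain: (1) extract the portion of the
physiological recording acquired simultaneously with imaging, using the MR
gradient fiducial, and down-sample it fourfold; (2) detect end-diastole
from the ECG and end-systole from the LV pressure; (3+4) derive per-frame
volumes from the long-axis contours by centerline rotation and detect the
per-beat volume extrema; (5) pair pressure and volume into PV loops over
the first beats after the occlusion; (6+7) fit the ESPVR and EDPVR to
quantify contractility and compliance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import beat_detection, physio_io, pvloop, volumetrics
from .errors import PVLoopsError
from .physio_io import PhysioRecording, TimeInterval
from .volumetrics import LVContour

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "export_results"]


@dataclass
class PipelineConfig:
    """Analysis configuration; all fields have the conventional defaults."""

    occlusion_time: float | None = None  # None -> automatic onset detection
    n_beats: int = 10
    exclude_beats: tuple[int, ...] = ()
    downsample_factor: int = 4
    n_slabs: int = 200
    gradient_threshold: float = 0.1
    seed: int = 0


@dataclass
class PipelineResult:
    imaging_window: TimeInterval
    beat_table: pd.DataFrame
    pressure_fids: beat_detection.FiducialSet
    volume_series: volumetrics.VolumeSeries
    volume_fids: volumetrics.VolumeFiducials
    onset: int
    loops: pvloop.PVLoopSet
    espvr: pvloop.PVRFit
    edpvr: pvloop.PVRFit
    baseline: pvloop.HemoSummary
    response: pvloop.OcclusionResponse
    config: PipelineConfig
    stage_log: list[str] = field(default_factory=list)

    @property
    def contractility(self) -> float:
        """ESPVR slope (mmHg/ml)."""
        return self.espvr.derived_metric

    @property
    def compliance(self) -> float:
        """Inverse EDPVR slope (ml/mmHg)."""
        return self.edpvr.derived_metric


def run_pipeline(
    rec: PhysioRecording,
    contours: list[LVContour],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full derivation on one recording + contour sequence."""
    cfg = config or PipelineConfig()
    log: list[str] = []

    window = physio_io.detect_imaging_window(rec, threshold_frac=cfg.gradient_threshold)
    log.append(f"imaging window [{window.start:.3f}, {window.end:.3f}] s")
    rec_w = physio_io.extract_window(rec, window)
    rec_d = physio_io.downsample(rec_w, cfg.downsample_factor)
    log.append(f"down-sampled {rec.sample_rate:.0f} -> {rec_d.sample_rate:.0f} Hz")

    fids, table = beat_detection.populate_pressure_fiducials(rec_d, exclude=cfg.exclude_beats)
    log.append(f"{fids.ed_times.size} pressure-side ED detections")

    in_window = [c for c in contours if window.start - 1e-6 <= c.frame_time <= window.end + 1e-6]
    vseries = volumetrics.volume_timeseries(in_window, n_slabs=cfg.n_slabs)
    vfids = volumetrics.detect_ed_es_volume(vseries)
    log.append(f"{vfids.ed_indices.size} volume-side ED detections")
    vseries_up = volumetrics.upsample_volume(vseries, rec_d.sample_rate)

    onset = beat_detection.find_occlusion_onset(table, config_time=cfg.occlusion_time)
    log.append(f"occlusion onset at beat {onset}")
    loops = pvloop.pair_pv(
        fids,
        table,
        rec_d.time,
        rec_d.lvp,
        vfids,
        vseries_up,
        onset=onset,
        n_beats=cfg.n_beats,
        exclude=cfg.exclude_beats,
    )
    espvr = pvloop.fit_espvr(loops.es_points)
    edpvr = pvloop.fit_edpvr(loops.ed_points)
    log.append(
        f"contractility {espvr.derived_metric:.3f} mmHg/ml, "
        f"compliance {edpvr.derived_metric:.3f} ml/mmHg over {loops.n_beats} beats"
    )

    # baseline summary: first usable recorded heartbeat before the occlusion
    baseline_loops = pvloop.pair_pv(
        fids, table, rec_d.time, rec_d.lvp, vfids, vseries_up,
        onset=0, n_beats=max(3, onset), exclude=cfg.exclude_beats,
    )
    baseline = pvloop.hemodynamic_summary(baseline_loops.beats[0])
    response = pvloop.occlusion_response(loops)
    return PipelineResult(
        imaging_window=window,
        beat_table=table,
        pressure_fids=fids,
        volume_series=vseries,
        volume_fids=vfids,
        onset=onset,
        loops=loops,
        espvr=espvr,
        edpvr=edpvr,
        baseline=baseline,
        response=response,
        config=cfg,
        stage_log=log,
    )


def export_results(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the beat table, per-beat PV fiducial points, and a JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["beat_table"] = outdir / "beat_table.csv"
    result.beat_table.to_csv(paths["beat_table"], index=False, float_format="%.9g")

    pts = pd.DataFrame(
        {
            "beat": [b.beat_index for b in result.loops.beats],
            "ed_volume_ml": result.loops.ed_points[:, 0],
            "ed_pressure_mmhg": result.loops.ed_points[:, 1],
            "es_volume_ml": result.loops.es_points[:, 0],
            "es_pressure_mmhg": result.loops.es_points[:, 1],
        }
    )
    paths["pv_points"] = outdir / "pv_points.csv"
    pts.to_csv(paths["pv_points"], index=False, float_format="%.9g")

    report = {
        "imaging_window_s": [result.imaging_window.start, result.imaging_window.end],
        "onset_beat": result.onset,
        "n_loops": result.loops.n_beats,
        "espvr": asdict(result.espvr),
        "edpvr": asdict(result.edpvr),
        "contractility_mmhg_per_ml": result.contractility,
        "compliance_ml_per_mmhg": result.compliance,
        "baseline": asdict(result.baseline),
        "occlusion_response": asdict(result.response),
        "config": {**asdict(result.config), "exclude_beats": list(result.config.exclude_beats)},
    }
    paths["report"] = outdir / "report.json"
    paths["report"].write_text(json.dumps(report, indent=1, sort_keys=True))
    return paths


def stage_hint(err: PVLoopsError) -> str:
    """Human-readable remedial hint for a pipeline error."""
    from . import errors as E

    hints = {
        E.NoWindowError: "check the gradient channels or pass an explicit window",
        E.PairingError: "inspect beat_table.csv and the volume trace; exclude ectopic beats",
        E.OnsetNotFoundError: "set occlusion_time in the configuration",
        E.InsufficientDataError: "the recording covers too few beats for this analysis",
    }
    for klass, hint in hints.items():
        if isinstance(err, klass):
            return hint
    return "see the error message above"
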