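"""Shared fixtures: simulator ground truth and rendered datasets.

Session-scoped because the fixed-step integration is the expensive part;
every fixture is deterministic (fixed parameters and seeds).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import pvloops
from pvloops import pipeline


def clean_params(**overrides) -> pvloops.ElastanceParams:
    """Noise-free simulator parameters (defaults otherwise)."""
    kw = dict(noise_p=0.0, noise_v=0.0, noise_ecg=0.0)
    kw.update(overrides)
    return pvloops.ElastanceParams(**kw)


def render_dataset(params: pvloops.ElastanceParams, duration: float = 30.0):
    """Simulate + render a matched (recording, contours, ground-truth) set."""
    gt = pvloops.simulate(params, duration=duration)
    rec = pvloops.render_recording(gt, params)
    frame_times, vols = pvloops.render_volume_frames(gt, params)
    contours = pvloops.contours_from_volume(vols, frame_times)
    return rec, contours, gt


def run_recovery(seed: int, noise: bool = True) -> tuple[pipeline.PipelineResult, pvloops.GroundTruth]:
    """Full pipeline on a simulator fixture; returns result + ground truth."""
    params = pvloops.ElastanceParams(seed=seed) if noise else clean_params(seed=seed)
    rec, contours, gt = render_dataset(params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pipeline.run_pipeline(
            rec, contours, pipeline.PipelineConfig(occlusion_time=params.t_occ)
        )
    return result, gt


@pytest.fixture(scope="session")
def gt_clean() -> pvloops.GroundTruth:
    return pvloops.simulate(clean_params())


@pytest.fixture(scope="session")
def dataset_clean(gt_clean):
    params = clean_params()
    rec = pvloops.render_recording(gt_clean, params)
    frame_times, vols = pvloops.render_volume_frames(gt_clean, params)
    contours = pvloops.contours_from_volume(vols, frame_times)
    return rec, contours, gt_clean


@pytest.fixture(scope="session")
def result_clean(dataset_clean):
    rec, contours, gt = dataset_clean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_pipeline(
            rec, contours, pipeline.PipelineConfig(occlusion_time=gt.params.t_occ)
        )


def ellipse_contour(a: float = 40.0, b: float = 20.0, n: int = 256, frame_time: float = 0.0,
                    rotate: float = 0.0, shift=(0.0, 0.0)) -> pvloops.LVContour:
    """Full-ellipse phantom with the basal vertex as degenerate annulus."""
    theta = np.pi / 2 + 2 * np.pi * np.arange(n) / n
    pts = np.column_stack([b * np.cos(theta), a * np.sin(theta)])
    basal = np.array([0.0, a])
    apex = np.array([0.0, -a])
    pts[0], pts[n // 2] = basal, apex
    c, s = np.cos(rotate), np.sin(rotate)
    rot = np.array([[c, -s], [s, c]])
    shift = np.asarray(shift, dtype=float)
    return pvloops.LVContour(
        points=pts @ rot.T + shift,
        annulus_a=rot @ basal + shift,
        annulus_b=rot @ basal + shift,
        apex=rot @ apex + shift,
        frame_time=frame_time,
    )
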