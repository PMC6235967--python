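"""Seeded end-to-end recovery experiments on synthetic acquisitions.

Each function builds ground-truthed inputs with the generator, runs the
relevant slice of the pipeline, and reports how well the known truth is
recovered.  They are the package's standing validation experiments: the test
suite asserts on their outputs and the acceptance script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ccimage, dynamics, morphometry, normalization, preprocess, synthetic
from .validation import half_spacing_threshold, match_centroids


def _pearson(a, b) -> float:
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])


def _front_half(stacks):
    """Blink rejection → registration (nonfluorescent channel) → normalization."""
    msl = stacks["multiply_scattered"]
    preprocess.detect_blinks(msl, 0.5)
    reg = preprocess.register_translation(msl)
    icg = preprocess.apply_shifts(stacks["icg"], reg)
    chan = normalization.channel_normalize(icg, reg)
    return reg, icg, chan


def recirculation_recovery(
    seed: int = 0,
    n_videos: int = 20,
    delay_range: tuple[float, float] = (14.0, 24.0),
    field: int = 64,
    n_frames: int = 700,
    frame_rate: float = 16.7,
    noise_scale: float = 0.05,
    motion_amplitude: int = 4,
) -> dict:
    """Recover a drawn recirculation delay from seeded noisy, moving videos.

    Returns the per-video table plus the median absolute error (seconds), the
    truth–estimate correlation, and the frame interval the error is judged
    against.
    """
    rows = []
    for i in range(n_videos):
        rng = np.random.default_rng(seed * 1000 + i)
        delay = rng.uniform(*delay_range)
        kinetics = synthetic.DyeKinetics(recirc_delay=delay)
        scene = synthetic.make_scene(field=field, pad=8, seed=seed * 1000 + i)
        acq = synthetic.AcquisitionModel(
            frame_rate=frame_rate,
            n_frames=n_frames,
            motion_amplitude=motion_amplitude,
            noise_scale=noise_scale,
            seed=seed * 1000 + i + 1,
            blink_schedule=[(80, 90), (n_frames - 100, n_frames - 90)],
        )
        stacks, _ = synthetic.render_video(scene, kinetics, acq)
        _, icg, chan = _front_half(stacks)
        trace = dynamics.IntensityTrace(icg.times, chan.trace, chan.stack.valid)
        smoothed = dynamics.smooth_trace(trace, 15)
        peaks = dynamics.detect_peaks(smoothed, 0.05, 5.0)
        est = dynamics.recirculation_time(peaks)
        rows.append({"truth_s": delay, "estimate_s": est, "abs_error_s": abs(est - delay)})
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "median_abs_error_s": float(table["abs_error_s"].median()),
        "correlation": _pearson(table["truth_s"], table["estimate_s"]),
        "frame_interval_s": 1.0 / frame_rate,
        "n": n_videos,
    }


def stage_subtraction_efficacy(
    seed: int = 0,
    field: int = 96,
    n_frames: int = 1250,
    noise_scale: float = 0.0,
    motion_amplitude: int = 0,
) -> dict:
    """Correlation of the stage-subtraction image with the true vessel mask,
    against the raw stage-1 mean image as the baseline."""
    scene = synthetic.make_scene(field=field, pad=8, seed=seed)
    acq = synthetic.AcquisitionModel(
        n_frames=n_frames,
        motion_amplitude=motion_amplitude,
        noise_scale=noise_scale,
        seed=seed + 50,
    )
    stacks, truth = synthetic.render_video(scene, synthetic.DyeKinetics(), acq)
    reg, icg, chan = _front_half(stacks)
    trace = dynamics.IntensityTrace(icg.times, chan.trace, chan.stack.valid)
    smoothed = dynamics.smooth_trace(trace, 15)
    peaks = dynamics.detect_peaks(smoothed, 0.05, 5.0)
    stages = dynamics.define_stages(smoothed, peaks)
    auto = normalization.autonormalize(icg, 0.02)
    img1 = ccimage.stage_mean_image(auto.stack, stages.stage1_rising)
    img3 = ccimage.stage_mean_image(auto.stack, stages.stage3)
    sub = ccimage.subtract_stages(img1, img3)
    off = tuple(truth.motion[reg.reference_index])
    sy, sx = reg.roi.slices()
    mask = scene.crop_at(off, "cc_mask")[sy, sx]
    return {
        "r_subtracted": _pearson(sub.pixels, mask),
        "r_raw_stage1": _pearson(img1, mask),
        "n": field * field,
    }


def gain_normalization_recovery(seed: int = 0, field: int = 96, n_frames: int = 500) -> dict:
    """Channel normalization under an imposed per-frame illumination gain.

    Reports the correlation of the recovered factors with the true gain and
    of the normalized trace with the true kinetic signal (noiseless video).
    """
    rng = np.random.default_rng(seed)
    g = np.clip(
        1.0 + 0.3 * np.sin(np.arange(n_frames) / 9.0) + 0.05 * rng.standard_normal(n_frames),
        0.4,
        None,
    )
    scene = synthetic.make_scene(field=field, pad=8, seed=seed + 3)
    acq = synthetic.AcquisitionModel(
        n_frames=n_frames, motion_amplitude=0, noise_scale=0.0,
        seed=seed + 4, illumination_gain=g,
    )
    stacks, truth = synthetic.render_video(scene, synthetic.DyeKinetics(), acq)
    reg = preprocess.register_translation(stacks["multiply_scattered"])
    icg = preprocess.apply_shifts(stacks["icg"], reg)
    chan = normalization.channel_normalize(icg, reg)
    s_true = np.array([truth.composite_frame(t).mean() for t in range(n_frames)])
    valid = chan.stack.valid
    return {
        "r_gain_factors": _pearson(chan.factors[valid], g[valid]),
        "r_kinetic_trace": _pearson(chan.trace[valid], s_true[valid]),
        "n": n_frames,
    }


def spacing_recovery(seed: int = 0) -> dict:
    """Spectral and DRP spacing estimators against built-in truths."""
    # sinusoidal grating: exact Fourier pair
    n, period = 512, 30.0
    x = np.arange(n)
    grating = np.sin(2 * np.pi * x / period)[None, :] * np.ones((n, 1))
    g_spec = morphometry.radial_power_spectrum(grating, 1.0, crop=500)

    # choriocapillaris pattern at the anatomical 31 µm void spacing
    mask, _ = synthetic.make_choriocapillaris(31.0, 15.0, 540, 1.0, seed=seed)
    cc_spec = morphometry.radial_power_spectrum(mask, 1.0, crop=500)

    # mosaics: perfect lattice and CSR control
    lattice = synthetic.triangular_lattice(14.0, (400.0, 400.0))
    drp_lattice = morphometry.drp_spacing(lattice, 1.0)
    rng = np.random.default_rng(seed)
    poisson = rng.uniform(0, 400, (700, 2))
    drp_poisson = morphometry.drp_spacing(poisson, 1.0)
    return {
        "grating_period_um": 1.0 / g_spec.peak_frequency,
        "grating_abs_error_um": abs(1.0 / g_spec.peak_frequency - period),
        "cc_row_spacing_um": cc_spec.row_spacing,
        "cc_rel_error_vs_void_spacing": abs(cc_spec.row_spacing - 31.0) / 31.0,
        "drp_lattice_spacing_um": drp_lattice.spacing,
        "drp_poisson_spacing_um": drp_poisson.spacing,
        "drp_poisson_mosaic_flag": bool(drp_poisson.mosaic),
    }


def disc_phantom_morphometrics(radius_px: float = 10.0, pixel_scale: float = 1.0) -> dict:
    """Flow-void metrics of circular phantoms against the analytic circle."""
    shape = (96, 96)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.ones(shape)
    for cy, cx in ((30, 30), (60, 66)):
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2] = 0.0
    fvs = morphometry.segment_flow_voids(
        img, img, pixel_scale=pixel_scale, threshold=0.5, min_area=20.0
    )
    area_true = np.pi * (radius_px * pixel_scale) ** 2
    perim_true = 2 * np.pi * radius_px * pixel_scale
    areas = fvs.voids["area_um2"].to_numpy()
    perims = fvs.voids["perimeter_um"].to_numpy()
    return {
        "n_voids": len(fvs),
        "area_rel_error": float(np.abs(areas - area_true).max() / area_true),
        "perimeter_rel_error": float(np.abs(perims - perim_true).max() / perim_true),
        "mean_area_um2": float(areas.mean()),
        "mean_perimeter_um": float(perims.mean()),
    }


def mosaic_match_recovery(seed: int = 0, dropout: float = 0.09) -> dict:
    """Cross-modality RPE matching with a known deterministic dropout."""
    pts, _ = synthetic.make_rpe_mosaic(14.0, 300, 1.0, jitter=0.05, seed=seed)
    rng = np.random.default_rng(seed + 1)
    keep = rng.random(len(pts)) >= dropout
    spacing = morphometry.drp_spacing(pts, 1.0)
    thr = half_spacing_threshold(spacing)
    res = match_centroids(pts[keep], pts, thr)
    return {
        "recall": res.recall,
        "precision": res.precision,
        "expected_recall": float(keep.mean()),
        "threshold_um": thr,
        "n_cells": len(pts),
    }


def registration_recovery(seed: int = 0, field: int = 96, n_frames: int = 60) -> dict:
    """Exact shift recovery on a noiseless known-motion video."""
    scene = synthetic.make_scene(field=field, pad=10, seed=seed)
    acq = synthetic.AcquisitionModel(
        n_frames=n_frames, motion_amplitude=6, noise_scale=0.0, seed=seed + 2
    )
    stacks, truth = synthetic.render_video(scene, synthetic.DyeKinetics(), acq)
    reg = preprocess.register_translation(stacks["multiply_scattered"])
    expected = truth.motion - truth.motion[reg.reference_index]
    n_exact = int(np.all(reg.shifts == expected, axis=1).sum())
    return {"n_frames": n_frames, "n_exact": n_exact, "all_exact": n_exact == n_frames}
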