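"""Shared fixtures: small ground-truthed synthetic acquisitions.

Everything is generated at test time from seeds; module-scoped fixtures keep
the rendered videos cheap to share across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from aoicg import dynamics as dy
from aoicg import normalization as nm
from aoicg import preprocess as pp
from aoicg import synthetic as syn


def analyze_video(stacks, blink_threshold=0.5, smoothing_window=15):
    """Standard front half of the pipeline: blinks → register → normalize → smooth."""
    msl = stacks["multiply_scattered"]
    pp.detect_blinks(msl, blink_threshold)
    reg = pp.register_translation(msl)
    icg = pp.apply_shifts(stacks["icg"], reg)
    chan = nm.channel_normalize(icg, reg)
    trace = dy.IntensityTrace(icg.times, chan.trace, chan.stack.valid)
    smoothed = dy.smooth_trace(trace, smoothing_window)
    return {"reg": reg, "icg": icg, "chan": chan, "trace": trace, "smoothed": smoothed}


@pytest.fixture(scope="session")
def scene():
    return syn.make_scene(field=96, pad=8, seed=11)


@pytest.fixture(scope="session")
def noiseless_video(scene):
    """Noise-free, motion-free acquisition long enough to contain stage 3."""
    acq = syn.AcquisitionModel(n_frames=1250, motion_amplitude=0, noise_scale=0.0, seed=21)
    stacks, truth = syn.render_video(scene, syn.DyeKinetics(), acq)
    return stacks, truth


@pytest.fixture(scope="session")
def noisy_video(scene):
    """Moderate noise + motion + two blinks, away from the bolus peaks."""
    acq = syn.AcquisitionModel(
        n_frames=1250,
        motion_amplitude=4,
        noise_scale=0.05,
        seed=22,
        blink_schedule=[(30, 45), (1100, 1120)],
    )
    stacks, truth = syn.render_video(scene, syn.DyeKinetics(), acq)
    return stacks, truth


@pytest.fixture(scope="session")
def analyzed_noiseless(noiseless_video):
    stacks, truth = noiseless_video
    return analyze_video(stacks), truth


@pytest.fixture(scope="session")
def analyzed_noisy(noisy_video):
    stacks, truth = noisy_video
    return analyze_video(stacks), truth


def truth_mask_in_roi(truth, reg):
    """Ground-truth vessel mask expressed in registered (reference) coordinates."""
    off = tuple(truth.motion[reg.reference_index])
    mask = truth.scene.crop_at(off, "cc_mask")
    sy, sx = reg.roi.slices()
    return mask[sy, sx]


def pearson(a, b):
    return float(np.corrcoef(np.ravel(a), np.ravel(b))[0, 1])
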