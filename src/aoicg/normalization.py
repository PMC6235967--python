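"""Per-frame intensity normalization of registered AO-ICG video.

Fluorescence intensity fluctuates frame to frame for reasons unrelated to dye
concentration (tear film, pupil wander, source power).  Two schemes remove
this:

* **autonormalization** — the darkest choriocapillaris flow voids carry no
  dye and act as an indirect background probe; each frame is divided by the
  mean intensity over a fixed set of the most hypofluorescent pixels.  Used
  before stage subtraction, where absolute frame-to-frame comparability
  matters.
* **channel normalization** — a simultaneously acquired nonfluorescent
  multiply-scattered-light channel sees the same illumination but no dye;
  each fluorescence frame is divided by that channel's per-frame mean
  (itself normalized around one), and the resulting trace is rescaled to
  [0, 1].  Used for dye-transit timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import RegisteredStack

__all__ = ["NormalizationResult", "DegenerateBackgroundError", "autonormalize", "channel_normalize"]


class DegenerateBackgroundError(RuntimeError):
    """Background estimate non-positive or non-finite; cannot normalize."""


@dataclass
class NormalizationResult:
    """Outcome of a normalization pass.

    ``factors`` holds the strictly positive per-frame divisor actually applied
    (NaN on invalid frames); ``stack`` is the normalized registered stack;
    ``trace`` (channel method, or on request) is the per-frame spatial-mean
    trace over the common ROI after normalization.
    """

    method: str
    factors: np.ndarray
    stack: RegisteredStack | None = None
    trace: np.ndarray | None = None


def autonormalize(
    rs: RegisteredStack,
    dark_fraction: float = 0.02,
    smooth_sigma_px: float = 2.0,
) -> NormalizationResult:
    """Normalize each frame to its own darkest flow-void pixels.

    The dark-pixel set is the darkest ``dark_fraction`` of common-ROI pixels
    of the (mildly smoothed) temporal-mean image, held fixed across frames;
    each valid frame is divided by its mean over that set.
    """
    if not 0 < dark_fraction <= 0.1:
        raise ValueError("dark_fraction must lie in (0, 0.1]")
    if rs.roi.empty:
        raise ValueError("common ROI is empty")
    sy, sx = rs.roi.slices()
    roi_stack = rs.pixels[rs.valid][:, sy, sx]
    mean_img = ndimage.gaussian_filter(roi_stack.mean(axis=0), smooth_sigma_px)
    n_dark = max(1, int(round(dark_fraction * mean_img.size)))
    flat = mean_img.ravel()
    dark_idx = np.argpartition(flat, n_dark - 1)[:n_dark]
    dark_mask = np.zeros(mean_img.shape, dtype=bool)
    dark_mask.ravel()[dark_idx] = True

    factors = np.full(rs.n_frames, np.nan)
    out = np.array(rs.pixels, copy=True)
    for t in range(rs.n_frames):
        if not rs.valid[t]:
            continue
        f = float(rs.pixels[t, sy, sx][dark_mask].mean())
        if not np.isfinite(f) or f <= 0:
            raise DegenerateBackgroundError(f"frame {t}: background factor {f!r}")
        factors[t] = f
        out[t] = rs.pixels[t] / f
    norm = RegisteredStack(
        pixels=out,
        channel=rs.channel,
        times=rs.times,
        pixel_scale=rs.pixel_scale,
        valid=rs.valid.copy(),
        shifts=rs.shifts.copy(),
        reference_index=rs.reference_index,
        roi=rs.roi,
    )
    return NormalizationResult(method="auto", factors=factors, stack=norm)


def channel_normalize(
    icg: RegisteredStack,
    msl: RegisteredStack,
    rescale: bool = True,
) -> NormalizationResult:
    """Divide the fluorescence stack by the nonfluorescent channel's gain.

    The multiply-scattered channel's per-frame spatial means (over the common
    ROI) are first normalized around one by their temporal mean over valid
    frames; each fluorescence frame is divided by its frame's normalized
    value.  The per-frame mean trace is then affinely rescaled to [0, 1] over
    valid frames (skippable via ``rescale=False`` when absolute differences
    matter downstream).  Frames in which the nonfluorescent channel is
    near-zero (blinks that slipped through) are marked invalid.
    """
    if icg.n_frames != msl.n_frames or not np.allclose(icg.times, msl.times):
        raise ValueError("stacks must be frame-aligned")
    if icg.roi.empty:
        raise ValueError("common ROI is empty")
    sy, sx = icg.roi.slices()
    valid = icg.valid & msl.valid
    msl_means = msl.pixels[:, sy, sx].mean(axis=(1, 2))
    ref = msl_means[valid].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        g = msl_means / ref
    degenerate = ~np.isfinite(g) | (g <= 1e-6)
    valid = valid & ~degenerate

    out = np.array(icg.pixels, copy=True)
    factors = np.full(icg.n_frames, np.nan)
    for t in np.flatnonzero(valid):
        factors[t] = g[t]
        out[t] = icg.pixels[t] / g[t]
    trace = np.full(icg.n_frames, np.nan)
    trace[valid] = out[valid][:, sy, sx].mean(axis=(1, 2))
    if rescale:
        lo = np.nanmin(trace[valid])
        hi = np.nanmax(trace[valid])
        if hi > lo:
            trace = (trace - lo) / (hi - lo)
        else:
            trace = np.where(np.isfinite(trace), 0.0, np.nan)
    norm = RegisteredStack(
        pixels=out,
        channel=icg.channel,
        times=icg.times,
        pixel_scale=icg.pixel_scale,
        valid=valid,
        shifts=icg.shifts.copy(),
        reference_index=icg.reference_index,
        roi=icg.roi,
    )
    return NormalizationResult(method="channel", factors=factors, stack=norm, trace=trace)
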