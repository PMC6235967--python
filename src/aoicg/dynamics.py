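"""Dye-transit dynamics: intensity trace, bolus peaks, stages, recirculation.

The mean fluorescence of an AO-ICG video traces the passage of the injected
dye bolus: a sharp primary peak as the bolus enters and exits the ocular
circulation (stage 1), a broadened secondary peak ~18 s later as it
recirculates (stage 2), and a stable plateau once dye taken up by the RPE
dominates (stage 3).  The time between the two peaks — the recirculation
time — is a candidate biomarker of systemic vascular perfusion; healthy
normative values are 18.31 ± 2.98 s, against which a patient's value can be
expressed as a z-score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .preprocess import Rect, RegisteredStack

__all__ = [
    "IntensityTrace",
    "PeakSet",
    "StageWindows",
    "NotMeasurableError",
    "extract_trace",
    "smooth_trace",
    "detect_peaks",
    "define_stages",
    "recirculation_time",
    "zscore",
]

NORMATIVE_RECIRC_MEAN_S = 18.31
NORMATIVE_RECIRC_SD_S = 2.98


class NotMeasurableError(RuntimeError):
    """The trace does not support the requested measurement (e.g. blinks at a peak)."""


@dataclass
class IntensityTrace:
    """Per-frame mean fluorescence vs. time with per-sample validity."""

    times: np.ndarray
    values: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not len(self.times) == len(self.values) == len(self.valid):
            raise ValueError("times, values, valid must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def frame_interval(self) -> float:
        """Median sampling interval of the valid samples, seconds."""
        return float(np.median(np.diff(self.times[self.valid])))


@dataclass
class PeakSet:
    """Detected bolus-passage peaks, in time order."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if len(self.peak_times) > 1 and not np.all(np.diff(self.peak_times) > 0):
            raise ValueError("peaks must be time-ordered")
        if np.any(np.asarray(self.prominences) <= 0):
            raise ValueError("prominences must be positive")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class StageWindows:
    """Time intervals (seconds) for stage 1, its rising phase, and stage 3.

    ``stage3`` is None when no sufficiently stable post-peak window exists
    before the end of the recording (flagged by ``stage3_found``).
    """

    stage1: tuple[float, float]
    stage1_rising: tuple[float, float]
    stage3: tuple[float, float] | None

    @property
    def stage3_found(self) -> bool:
        return self.stage3 is not None


def extract_trace(rs: RegisteredStack, roi: Rect | None = None) -> IntensityTrace:
    """Spatial-mean trace over an ROI of a registered stack.

    ``roi`` defaults to the stack's common-coverage rectangle and must be
    contained in it.  Invalid frames are carried as invalid samples (NaN).
    """
    if roi is None:
        roi = rs.roi
    if roi.empty:
        raise ValueError("roi is empty")
    if not rs.roi.contains(roi):
        raise ValueError("roi must be contained in the common ROI")
    sy, sx = roi.slices()
    values = np.full(rs.n_frames, np.nan)
    values[rs.valid] = rs.pixels[rs.valid][:, sy, sx].mean(axis=(1, 2))
    return IntensityTrace(times=rs.times.copy(), values=values, valid=rs.valid.copy())


def smooth_trace(trace: IntensityTrace, window: int = 15) -> IntensityTrace:
    """Gaussian temporal smoothing with a truncated, validity-aware kernel.

    The kernel has support ``window`` samples (must be odd) and σ = window/6
    (the ±3σ support convention).  Invalid samples carry zero weight and each
    output sample's weights are renormalized, so endpoints and blink gaps use
    truncated kernels.  ``window=1`` is the identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return IntensityTrace(trace.times.copy(), trace.values.copy(), trace.valid.copy())
    half = window // 2
    sigma = window / 6.0
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    w = trace.valid.astype(float)
    v = np.where(trace.valid, trace.values, 0.0)
    num = np.convolve(v * w, kernel, mode="same")
    den = np.convolve(w, kernel, mode="same")
    out = np.full_like(trace.values, np.nan)
    ok = trace.valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return IntensityTrace(trace.times.copy(), out, trace.valid.copy())


def detect_peaks(
    trace: IntensityTrace,
    min_prominence_frac: float = 0.05,
    min_separation: float = 5.0,
    refine: bool = True,
) -> PeakSet:
    """Local maxima of a (smoothed) trace with prominence and spacing floors.

    Prominence is measured relative to the trace's full valid range; peaks
    closer together than ``min_separation`` seconds are merged by scipy's
    distance rule.  With ``refine`` (default) each peak time is localized to
    sub-sample precision by a least-squares parabola fitted to the trace
    around the detected maximum — bolus peaks are much broader than the frame
    interval, so the vertex of the local quadratic is a far steadier estimate
    of the transit extremum than the single highest sample.  Raises
    :class:`NotMeasurableError` when no peak qualifies.
    """
    if not 0 < min_prominence_frac < 1:
        raise ValueError("min_prominence_frac must lie in (0, 1)")
    v = trace.values[trace.valid]
    t = trace.times[trace.valid]
    if len(v) < 3:
        raise NotMeasurableError("too few valid samples")
    span = float(np.max(v) - np.min(v))
    if span <= 0:
        raise NotMeasurableError("flat trace")
    dt = float(np.median(np.diff(t)))
    idx, props = find_peaks(
        v,
        prominence=min_prominence_frac * span,
        distance=max(1, int(np.ceil(min_separation / dt))),
    )
    if len(idx) == 0:
        raise NotMeasurableError("no qualifying peak")
    peak_times = t[idx].astype(float)
    peak_values = v[idx].astype(float)
    if refine:
        half = 1.0  # s; quadratic approximation holds within ~σ/2 of a bolus peak
        for k, i in enumerate(idx):
            sel = np.abs(t - t[i]) <= half
            if sel.sum() >= 5:
                a, b, c = np.polyfit(t[sel] - t[i], v[sel], 2)
                if a < 0:
                    vertex = -b / (2 * a)
                    # trust the fit only within the fitted neighbourhood
                    if abs(vertex) <= half:
                        peak_times[k] = t[i] + vertex
                        peak_values[k] = c - b**2 / (4 * a)
    order = np.argsort(peak_times)
    return PeakSet(
        peak_times=peak_times[order],
        peak_values=peak_values[order],
        prominences=props["prominences"][order],
    )


def _valid_series(trace: IntensityTrace) -> tuple[np.ndarray, np.ndarray]:
    return trace.times[trace.valid], trace.values[trace.valid]


def define_stages(
    trace: IntensityTrace,
    peaks: PeakSet,
    stability_tol: float = 0.005,
    stability_span: float = 10.0,
) -> StageWindows:
    """Stage windows from a smoothed trace and its detected peaks.

    * stage 1 rising phase: from the first time the trace exceeds the
      pre-arrival baseline by 10% of the peak-1 rise, up to the peak-1 time.
    * stage 1: interval symmetric about peak 1, bounded by the minimum
      between peak 1 and the next peak (or the post-peak minimum if single).
    * stage 3: earliest window after the *last* detected peak, of length at
      least ``stability_span`` seconds, in which the absolute temporal
      derivative stays below ``stability_tol`` × (peak-1 rise) per second;
      extended to the end of the trace.  None if no such window exists.

    The pre-arrival baseline is the median of samples before the trace first
    reaches 20% of the peak-1 rise above its minimum.
    """
    if len(peaks) < 1:
        raise ValueError("at least one peak required")
    t, v = _valid_series(trace)
    t_peak1 = peaks.peak_times[0]
    i_peak1 = int(np.argmin(np.abs(t - t_peak1)))
    peak1_val = v[i_peak1]
    vmin = float(np.min(v))
    cross20 = np.flatnonzero(v >= vmin + 0.2 * (peak1_val - vmin))
    i20 = cross20[0] if len(cross20) else 0
    baseline = float(np.median(v[:i20])) if i20 > 0 else vmin
    rise = peak1_val - baseline
    if rise <= 0:
        raise NotMeasurableError("peak does not rise above baseline")

    pre = np.flatnonzero(v[: i_peak1 + 1] >= baseline + 0.1 * rise)
    t_rise_start = t[pre[0]] if len(pre) else t[0]
    stage1_rising = (float(t_rise_start), float(t_peak1))

    if len(peaks) >= 2:
        in_between = (t > t_peak1) & (t < peaks.peak_times[1])
    else:
        in_between = t > t_peak1
    if in_between.any():
        seg = np.flatnonzero(in_between)
        t_min = t[seg[np.argmin(v[seg])]]
    else:
        t_min = t[-1]
    half = t_min - t_peak1
    stage1 = (float(t_peak1 - half), float(t_min))

    t_last = peaks.peak_times[-1]
    deriv = np.gradient(v, t)
    stable = np.abs(deriv) <= stability_tol * rise
    stage3 = None
    candidates = np.flatnonzero((t > t_last) & stable)
    for i in candidates:
        t_end_window = t[i] + stability_span
        if t_end_window > t[-1]:
            break
        in_win = (t >= t[i]) & (t <= t_end_window)
        if stable[in_win].all():
            stage3 = (float(t[i]), float(t[-1]))
            break
    return StageWindows(stage1=stage1, stage1_rising=stage1_rising, stage3=stage3)


def recirculation_time(peaks: PeakSet) -> float:
    """Time between the primary and secondary bolus peaks, seconds."""
    if len(peaks) < 2:
        raise NotMeasurableError("recirculation time needs two peaks")
    return float(peaks.peak_times[1] - peaks.peak_times[0])


def zscore(
    x: float,
    mu: float = NORMATIVE_RECIRC_MEAN_S,
    sigma: float = NORMATIVE_RECIRC_SD_S,
) -> float:
    """Standard score of a measurement against a normative mean and SD."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return (x - mu) / sigma
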