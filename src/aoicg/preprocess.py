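"""Frame-stack containers, blink rejection, and rigid motion correction.

AOSLO video of a small retinal patch is acquired as a stream of frames that
wander with eye motion and are interrupted by blinks.  Downstream arithmetic
(normalization, stage averaging, stage subtraction) requires every frame to be
expressed in the coordinates of a single reference frame, and requires knowing
which pixels were actually observed in *every* usable frame.  This module
provides that: per-frame blink flags, whole-frame integer-pixel translation
registration by cross-correlation, and the maximal rectangle covered by all
valid registered frames.

Registration here is deliberately rigid (one translation per frame).  Raster
AO systems additionally suffer intra-frame distortion; correcting that is out
of scope and noted as a fidelity limit in the methods documentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "FrameStack",
    "RegisteredStack",
    "Rect",
    "UnusableAcquisitionError",
    "detect_blinks",
    "register_translation",
    "common_roi",
]

CHANNELS = ("icg", "multiply_scattered", "confocal", "darkfield")


class UnusableAcquisitionError(RuntimeError):
    """Raised when no frame of an acquisition is usable."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle with half-open pixel intervals [y0, y1) x [x0, x1)."""

    y0: int
    y1: int
    x0: int
    x1: int

    @property
    def height(self) -> int:
        return max(0, self.y1 - self.y0)

    @property
    def width(self) -> int:
        return max(0, self.x1 - self.x0)

    @property
    def empty(self) -> bool:
        return self.height == 0 or self.width == 0

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def contains(self, other: "Rect") -> bool:
        return (
            self.y0 <= other.y0
            and self.x0 <= other.x0
            and self.y1 >= other.y1
            and self.x1 >= other.x1
        )


@dataclass
class FrameStack:
    """Timestamped single-channel image stack with per-frame validity.

    Parameters
    ----------
    pixels : (T, H, W) float array
        Frame intensities.
    channel : str
        One of ``icg``, ``multiply_scattered``, ``confocal``, ``darkfield``.
    times : (T,) array
        Acquisition time of each frame in seconds; strictly increasing.
    pixel_scale : float
        Sampling in micrometres per pixel.
    valid : (T,) bool array, optional
        Per-frame usability flag; defaults to all valid.
    """

    pixels: np.ndarray
    channel: str
    times: np.ndarray
    pixel_scale: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be a (T, H, W) array")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if len(self.times) != self.n_frames:
            raise ValueError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive (µm/px)")
        if self.valid is None:
            self.valid = np.ones(self.n_frames, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if len(self.valid) != self.n_frames:
                raise ValueError("valid must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    def frame_means(self) -> np.ndarray:
        """Spatial mean of every frame (valid or not)."""
        return self.pixels.mean(axis=(1, 2))


@dataclass
class RegisteredStack(FrameStack):
    """A FrameStack resampled onto reference-frame coordinates.

    Adds per-frame integer shifts (dy, dx) applied to move each frame onto the
    reference, the reference frame index, and the common-coverage rectangle in
    which every valid frame contributed an observed (in-bounds) pixel.
    """

    shifts: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference_index: int = 0
    roi: Rect = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.shifts is None:
            self.shifts = np.zeros((self.n_frames, 2), dtype=int)
        self.shifts = np.asarray(self.shifts, dtype=int)
        if self.shifts.shape != (self.n_frames, 2):
            raise ValueError("shifts must be (T, 2)")
        if tuple(self.shifts[self.reference_index]) != (0, 0):
            raise ValueError("reference frame must have zero shift")
        if self.roi is None:
            self.roi = common_roi_from_shifts(self.shifts, self.valid, self.shape)

    def roi_pixels(self) -> np.ndarray:
        """Stack cropped to the common ROI."""
        sy, sx = self.roi.slices()
        return self.pixels[:, sy, sx]


def detect_blinks(stack: FrameStack, rel_threshold: float = 0.5) -> np.ndarray:
    """Flag blink frames by their collapsed mean intensity.

    A frame is invalid iff its spatial mean falls below ``rel_threshold``
    times the median of all per-frame spatial means.  The flags are combined
    (AND) with any pre-existing validity on the stack and recorded on it.

    Returns the new validity array.  Raises :class:`UnusableAcquisitionError`
    if every frame is flagged.
    """
    if not 0 < rel_threshold < 1:
        raise ValueError("rel_threshold must lie in (0, 1)")
    means = stack.frame_means()
    ok = (means > 0) & (means >= rel_threshold * np.median(means))
    stack.valid = stack.valid & ok
    if not stack.valid.any():
        raise UnusableAcquisitionError("all frames flagged as blinks")
    return stack.valid


def pick_reference_frame(stack: FrameStack) -> int:
    """Default reference: the valid frame with the highest spatial mean."""
    means = np.where(stack.valid, stack.frame_means(), -np.inf)
    return int(np.argmax(means))


def register_translation(
    stack: FrameStack, reference_index: int | None = None
) -> RegisteredStack:
    """Register every frame to a reference frame by integer-pixel translation.

    The shift for each valid frame maximizes the cross-correlation with the
    reference (computed by phase correlation, rounded to whole pixels — no
    subpixel resampling, so subtraction downstream never sees interpolation
    blur).  Invalid frames are passed through unshifted and stay invalid.
    A frame whose correlation peak is indeterminate (e.g. flat) is marked
    invalid.
    """
    if reference_index is None:
        reference_index = pick_reference_frame(stack)
    if not stack.valid[reference_index]:
        raise ValueError("reference frame must be valid")
    ref = stack.pixels[reference_index]
    out = np.array(stack.pixels, copy=True)
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    valid = stack.valid.copy()
    for t in range(stack.n_frames):
        if not valid[t] or t == reference_index:
            continue
        frame = stack.pixels[t]
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            valid[t] = False
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=1, normalization=None
        )
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        shifts[t] = (dy, dx)
        out[t] = ndimage.shift(frame, (dy, dx), order=0, mode="constant", cval=0.0)
    rs = RegisteredStack(
        pixels=out,
        channel=stack.channel,
        times=stack.times,
        pixel_scale=stack.pixel_scale,
        valid=valid,
        shifts=shifts,
        reference_index=reference_index,
    )
    return rs


def apply_shifts(stack: FrameStack, registered: RegisteredStack) -> RegisteredStack:
    """Re-use shifts computed on one channel for a simultaneously acquired one.

    Mirrors the acquisition reality that eye motion is common to all channels;
    registration is computed once (configurable channel) and applied everywhere.
    """
    if stack.n_frames != registered.n_frames:
        raise ValueError("stacks must be frame-aligned")
    out = np.array(stack.pixels, copy=True)
    for t in range(stack.n_frames):
        dy, dx = registered.shifts[t]
        if (dy, dx) != (0, 0):
            out[t] = ndimage.shift(
                stack.pixels[t], (dy, dx), order=0, mode="constant", cval=0.0
            )
    return RegisteredStack(
        pixels=out,
        channel=stack.channel,
        times=stack.times,
        pixel_scale=stack.pixel_scale,
        valid=registered.valid.copy(),
        shifts=registered.shifts.copy(),
        reference_index=registered.reference_index,
        roi=registered.roi,
    )


def common_roi_from_shifts(
    shifts: np.ndarray, valid: np.ndarray, shape: tuple[int, int]
) -> Rect:
    """Maximal rectangle observed in-bounds by every valid shifted frame.

    A frame shifted by (dy, dx) onto reference coordinates covers
    [max(0, dy), H + min(0, dy)) x [max(0, dx), W + min(0, dx)); the common
    ROI is the intersection over valid frames.  May be empty.
    """
    H, W = shape
    if not np.any(valid):
        return Rect(0, 0, 0, 0)
    y0 = x0 = 0
    y1, x1 = H, W
    for t in np.flatnonzero(valid):
        dy, dx = int(shifts[t, 0]), int(shifts[t, 1])
        y0 = max(y0, dy)
        y1 = min(y1, H + dy)
        x0 = max(x0, dx)
        x1 = min(x1, W + dx)
    if y1 <= y0 or x1 <= x0:
        return Rect(0, 0, 0, 0)
    return Rect(y0, y1, x0, x1)


def common_roi(rs: RegisteredStack) -> Rect:
    """Common-coverage rectangle of a registered stack (see module docstring)."""
    return common_roi_from_shifts(rs.shifts, rs.valid, rs.shape)
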