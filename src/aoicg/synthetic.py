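"""Ground-truthed synthetic AO-ICG scenes and videos.

The generator emulates the statistical structure a cellular-resolution
ophthalmic angiography pipeline assumes, so that every downstream stage can be
tested against a known truth:

* an RPE mosaic — a jittered triangular lattice of ~13–15 µm cells rendered as
  a Voronoi partition (bright interiors, dark boundaries);
* a cone mosaic — bright Gaussian spots at ~3–9 µm spacing on the same kind of
  lattice (confocal reflectance look);
* a choriocapillaris pattern — a perfused-vessel mask whose complement is a
  set of roughly elliptical flow voids on a jittered lattice (~15–30 µm
  features, ~31 µm void-to-void spacing), with true per-void morphometrics;
* dye kinetics — a primary bolus peak, a broadened and weakened recirculation
  peak ~18 s later, and fast uptake of dye into the RPE rising to a plateau,
  on top of a constant near-infrared autofluorescence baseline;
* acquisition artifacts — rigid eye motion (clipped random walk), blinks,
  per-frame illumination gain, and Poisson-like shot noise.

All randomness flows from explicit integer seeds; identical parameters and
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .preprocess import FrameStack

__all__ = [
    "SceneGroundTruth",
    "DyeKinetics",
    "AcquisitionModel",
    "VideoGroundTruth",
    "triangular_lattice",
    "make_rpe_mosaic",
    "make_cone_mosaic",
    "make_choriocapillaris",
    "make_scene",
    "simulate_component_traces",
    "render_video",
]


# ---------------------------------------------------------------------------
# point patterns


def triangular_lattice(
    spacing: float,
    extent: tuple[float, float],
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Jittered triangular (hexagonal) lattice of points.

    Parameters
    ----------
    spacing : float
        Nearest-neighbour pitch in µm.
    extent : (height, width)
        Region covered, in µm; points are generated over [0, h) x [0, w).
    jitter : float
        Uniform displacement amplitude as a fraction of ``spacing`` (each
        coordinate perturbed by U(-j·s, +j·s)); must lie in [0, 0.5).

    Returns (N, 2) array of (y, x) µm coordinates, row-major order.  With
    ``jitter=0`` no random numbers are consumed and output is seed-free.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must lie in [0, 0.5)")
    h, w = extent
    row_pitch = spacing * np.sqrt(3) / 2
    ys = np.arange(0.0, h, row_pitch)
    pts = []
    for i, y in enumerate(ys):
        x0 = (spacing / 2) if (i % 2) else 0.0
        xs = np.arange(x0, w, spacing)
        pts.append(np.column_stack([np.full_like(xs, y), xs]))
    points = np.concatenate(pts, axis=0)
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        points = points + rng.uniform(-jitter * spacing, jitter * spacing, points.shape)
        keep = (
            (points[:, 0] >= 0)
            & (points[:, 0] < h)
            & (points[:, 1] >= 0)
            & (points[:, 1] < w)
        )
        points = points[keep]
    return points


def _label_by_nearest(points_px: np.ndarray, field: int) -> np.ndarray:
    """Voronoi partition of the field as a label image (1-based labels)."""
    yy, xx = np.mgrid[0:field, 0:field]
    grid = np.column_stack([yy.ravel() + 0.5, xx.ravel() + 0.5])
    _, idx = cKDTree(points_px).query(grid, k=1)
    return (idx + 1).reshape(field, field)


def make_rpe_mosaic(
    spacing: float,
    field: int,
    pixel_scale: float,
    jitter: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """RPE cell mosaic: jittered triangular lattice + Voronoi label image.

    ``spacing`` is the cell-to-cell pitch in µm (healthy human RPE ≈ 13–15 µm);
    ``field`` is the image side in px.  Returns ``(centroids_um, labels)``
    where centroids are (N, 2) (y, x) µm inside the field and ``labels`` is
    the (field, field) Voronoi partition of the centroids.
    """
    if spacing <= 2 * pixel_scale:
        raise ValueError("spacing not resolvable at this pixel scale")
    rng = np.random.default_rng(seed)
    extent = (field * pixel_scale, field * pixel_scale)
    centroids = triangular_lattice(spacing, extent, jitter, rng)
    labels = _label_by_nearest(centroids / pixel_scale, field)
    return centroids, labels


def render_cell_pattern(
    labels: np.ndarray,
    seed: int = 0,
    interior: float = 1.0,
    boundary: float = 0.3,
    brightness_cv: float = 0.08,
) -> np.ndarray:
    """Render a label image as bright cell interiors with dark boundaries.

    Per-cell brightness varies mildly (coefficient of variation
    ``brightness_cv``) to mimic uneven dye uptake.
    """
    rng = np.random.default_rng(seed)
    n = labels.max()
    bright = interior * (1.0 + brightness_cv * rng.standard_normal(n + 1))
    img = bright[labels]
    edges = np.zeros_like(labels, dtype=bool)
    edges[:-1, :] |= labels[:-1, :] != labels[1:, :]
    edges[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    edges = ndimage.binary_dilation(edges)
    img[edges] = boundary
    return np.clip(img, 0.0, None)


def make_cone_mosaic(
    spacing: float,
    field: int,
    pixel_scale: float,
    jitter: float = 0.1,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cone photoreceptor mosaic: centroids + bright-spot image.

    Cones appear as punctate Gaussian spots (σ ≈ spacing/5) of varying
    intensity on a dim background.
    """
    if spacing <= 2 * pixel_scale:
        raise ValueError("spacing not resolvable at this pixel scale")
    rng = np.random.default_rng(seed)
    extent = (field * pixel_scale, field * pixel_scale)
    centroids = triangular_lattice(spacing, extent, jitter, rng)
    img = np.zeros((field, field))
    px = centroids / pixel_scale
    iy = np.clip(np.round(px[:, 0]).astype(int), 0, field - 1)
    ix = np.clip(np.round(px[:, 1]).astype(int), 0, field - 1)
    amps = 1.0 + 0.2 * rng.standard_normal(len(px))
    np.add.at(img, (iy, ix), np.clip(amps, 0.2, None))
    img = ndimage.gaussian_filter(img, sigma=max(spacing / 5 / pixel_scale, 0.6))
    img = img / img.max() if img.max() > 0 else img
    return centroids, img + 0.05


def make_choriocapillaris(
    void_spacing: float,
    void_diameter_mean: float,
    field: int,
    pixel_scale: float,
    seed: int = 0,
    jitter: float = 0.08,
    diameter_cv: float = 0.12,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Choriocapillaris vessel mask with elliptical flow voids on a lattice.

    Voids (non-perfused gaps) are ellipses of mean effective diameter
    ``void_diameter_mean`` µm centred on a jittered triangular lattice of
    pitch ``void_spacing`` µm.  Returns ``(mask, voids)`` where ``mask`` is
    (field, field) float in {0, 1} with 1 = perfused vessel, 0 = flow void,
    and ``voids`` is a table of the true morphometrics (analytic ellipse
    area, Ramanujan perimeter, effective diameter; µm) for every void fully
    inside the field.
    """
    if void_diameter_mean >= void_spacing:
        raise ValueError("voids would overlap: diameter must be < spacing")
    rng = np.random.default_rng(seed)
    extent = (field * pixel_scale, field * pixel_scale)
    centres = triangular_lattice(void_spacing, extent, jitter, rng)
    yy, xx = np.mgrid[0:field, 0:field]
    yy = (yy + 0.5) * pixel_scale
    xx = (xx + 0.5) * pixel_scale
    void = np.zeros((field, field), dtype=bool)
    rows = []
    for cy, cx in centres:
        ecc = rng.uniform(1.0, 1.0 + 2 * 0.15)
        d = void_diameter_mean * max(0.3, 1.0 + diameter_cv * rng.standard_normal())
        a = d / 2 * ecc  # semi-major, µm
        b = d / 2 / ecc  # semi-minor; a·b = (d/2)², area preserved
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        void |= inside
        fully_inside = (
            cy - a >= 0 and cy + a < extent[0] and cx - a >= 0 and cx + a < extent[1]
        )
        if fully_inside:
            # Ramanujan's second approximation for the ellipse perimeter
            h = ((a - b) / (a + b)) ** 2
            perim = np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
            area = np.pi * a * b
            rows.append(
                {
                    "y_um": cy,
                    "x_um": cx,
                    "area_um2": area,
                    "perimeter_um": perim,
                    "effective_diameter_um": 2 * np.sqrt(area / np.pi),
                }
            )
    mask = (~void).astype(float)
    return mask, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scene assembly


@dataclass
class SceneGroundTruth:
    """Static truth for one retinal patch.

    Coordinates are µm with origin at the field's top-left corner; images are
    (field, field).  Patterns are also kept on a motion-padded canvas so a
    video renderer can translate a viewing window over them; ``crop_at``
    extracts the field seen at a given integer motion offset.
    """

    rpe_centroids: np.ndarray
    cone_centroids: np.ndarray
    cc_vessel_mask: np.ndarray
    flow_voids_true: pd.DataFrame
    pixel_scale: float
    field: int
    pad: int = 0
    canvas: dict[str, np.ndarray] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        lim = self.field * self.pixel_scale
        for pts in (self.rpe_centroids, self.cone_centroids):
            if len(pts) and (pts.min() < 0 or pts.max() >= lim):
                raise ValueError("centroids must lie inside the field")
        vals = np.unique(self.cc_vessel_mask)
        if not (0.0 in vals and 1.0 in vals):
            raise ValueError("cc_vessel_mask must contain both classes")

    def crop_at(self, offset: tuple[int, int], key: str) -> np.ndarray:
        """Canvas pattern as seen by a window displaced by integer (dy, dx)."""
        dy, dx = offset
        if abs(dy) > self.pad or abs(dx) > self.pad:
            raise ValueError("offset exceeds canvas padding")
        y0, x0 = self.pad + dy, self.pad + dx
        return self.canvas[key][y0 : y0 + self.field, x0 : x0 + self.field]


def make_scene(
    field: int = 200,
    pixel_scale: float = 1.0,
    rpe_spacing: float = 14.0,
    cone_spacing: float = 4.0,
    cc_void_spacing: float = 31.0,
    cc_void_diameter: float = 15.0,
    jitter: float = 0.05,
    cc_jitter: float = 0.08,
    pad: int = 16,
    seed: int = 0,
) -> SceneGroundTruth:
    """Assemble a full scene (RPE + cones + choriocapillaris) with padding.

    Defaults reflect healthy foveal anatomy: 14 µm RPE cells, 4 µm foveal
    cones, 31 µm void-to-void choriocapillaris spacing with ~15 µm voids,
    sampled at 1 µm/px.  Cell mosaics (``jitter``) are kept more ordered than
    the vascular lattice (``cc_jitter``), as in real tissue.
    """
    rng = np.random.default_rng(seed)
    big = field + 2 * pad
    sub = [int(s) for s in rng.integers(0, 2**31 - 1, size=4)]
    rpe_c, rpe_labels = make_rpe_mosaic(rpe_spacing, big, pixel_scale, jitter, sub[0])
    cone_c, cone_img = make_cone_mosaic(cone_spacing, big, pixel_scale, jitter, sub[1])
    cc_mask_big, voids_big = make_choriocapillaris(
        cc_void_spacing, cc_void_diameter, big, pixel_scale, sub[2], cc_jitter
    )
    rpe_pattern = render_cell_pattern(rpe_labels, seed=sub[3])
    # static texture for the nonfluorescent multiply-scattered channel
    msl = 0.6 + 0.4 * ndimage.gaussian_filter(
        rng.standard_normal((big, big)), sigma=3.0
    )
    msl = np.clip(msl, 0.1, None)

    pad_um = pad * pixel_scale
    lim = field * pixel_scale

    def recenter(pts: np.ndarray) -> np.ndarray:
        pts = pts - pad_um
        keep = (pts >= 0).all(axis=1) & (pts < lim).all(axis=1)
        return pts[keep]

    # per-void truth re-expressed in central-field coordinates
    voids = voids_big.copy()
    voids["y_um"] -= pad_um
    voids["x_um"] -= pad_um
    inside = (
        (voids["y_um"] >= 0)
        & (voids["y_um"] < lim)
        & (voids["x_um"] >= 0)
        & (voids["x_um"] < lim)
    )
    voids = voids[inside].reset_index(drop=True)

    canvas = {
        "rpe": rpe_pattern,
        "cone": cone_img,
        "cc_mask": cc_mask_big,
        "msl": msl,
    }
    centre = (slice(pad, pad + field), slice(pad, pad + field))
    return SceneGroundTruth(
        rpe_centroids=recenter(rpe_c),
        cone_centroids=recenter(cone_c),
        cc_vessel_mask=cc_mask_big[centre],
        flow_voids_true=voids,
        pixel_scale=pixel_scale,
        field=field,
        pad=pad,
        canvas=canvas,
    )


# ---------------------------------------------------------------------------
# dye kinetics


@dataclass
class DyeKinetics:
    """Parameters of the post-injection fluorescence time course.

    The intravascular (choriocapillaris) component is the sum of a primary
    Gaussian bolus passage and a delayed, broadened, weaker recirculation
    passage; the RPE component is a saturating exponential uptake toward a
    plateau starting at dye arrival; a constant near-infrared
    autofluorescence baseline underlies everything.

    Units: times/widths in seconds, rates in 1/s, amplitudes in the arbitrary
    intensity units of the rendered video.
    """

    t_arrival: float = 8.0
    t_peak1: float = 13.0
    peak1_width: float = 2.0
    recirc_delay: float = 18.3
    recirc_amp_ratio: float = 0.35
    recirc_width: float = 5.0
    rpe_uptake_rate: float = 1.2
    rpe_plateau: float = 1.0
    baseline_autofluorescence: float = 0.12
    bolus_amp: float = 1.5

    def __post_init__(self) -> None:
        if not self.t_arrival < self.t_peak1:
            raise ValueError("dye must arrive before the first peak")
        if self.recirc_delay <= 0:
            raise ValueError("recirc_delay must be positive")
        if not 0 <= self.recirc_amp_ratio < 1:
            raise ValueError("recirc_amp_ratio must lie in [0, 1)")
        if self.recirc_amp_ratio > 0 and self.recirc_width <= self.peak1_width:
            raise ValueError("recirculation peak must be broader than the primary")


def simulate_component_traces(
    kinetics: DyeKinetics, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-structure amplitude traces ``(a_cc(t), a_rpe(t))``.

    ``a_cc`` carries the two bolus passages (vascular dye), ``a_rpe`` the
    uptake into the epithelium.  Both are nonnegative; the autofluorescence
    baseline is *not* included here (it is added to the rendered total).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or (len(t) > 1 and not np.all(np.diff(t) > 0)):
        raise ValueError("times must be a 1-D increasing vector")
    k = kinetics
    a_cc = k.bolus_amp * (
        np.exp(-0.5 * ((t - k.t_peak1) / k.peak1_width) ** 2)
        + k.recirc_amp_ratio
        * np.exp(-0.5 * ((t - k.t_peak1 - k.recirc_delay) / k.recirc_width) ** 2)
    )
    a_rpe = k.rpe_plateau * (
        1.0 - np.exp(-k.rpe_uptake_rate * np.maximum(0.0, t - k.t_arrival))
    )
    return a_cc, a_rpe


# ---------------------------------------------------------------------------
# video rendering


@dataclass
class AcquisitionModel:
    """Instrument/subject artifacts applied when rendering a video.

    ``blink_schedule`` is a list of half-open frame intervals [a, b) during
    which the eye is shut; ``illumination_gain`` is an optional per-frame
    positive multiplicative factor (default: all ones); ``noise_scale``
    scales Poisson-like noise with variance proportional to the mean signal.
    Motion is an integer random walk clipped to ±``motion_amplitude`` px.
    """

    frame_rate: float = 16.7
    n_frames: int = 800
    motion_amplitude: int = 5
    motion_step: float = 1.2
    blink_schedule: list[tuple[int, int]] = dc_field(default_factory=list)
    illumination_gain: np.ndarray | None = None
    noise_scale: float = 0.0
    seed: int = 0
    motion_seed: int | None = None  # defaults to seed + 1

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for a, b in self.blink_schedule:
            if not (0 <= a < b <= self.n_frames):
                raise ValueError("blink intervals must lie within [0, n_frames)")
        if self.illumination_gain is not None:
            self.illumination_gain = np.asarray(self.illumination_gain, dtype=float)
            if self.illumination_gain.shape != (self.n_frames,):
                raise ValueError("illumination_gain must have one entry per frame")
            if np.any(self.illumination_gain <= 0):
                raise ValueError("illumination_gain must be strictly positive")

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def blink_mask(self) -> np.ndarray:
        m = np.zeros(self.n_frames, dtype=bool)
        for a, b in self.blink_schedule:
            m[a:b] = True
        return m


@dataclass
class VideoGroundTruth:
    """Everything the renderer knew: motion, gains, blinks, kinetics, traces."""

    scene: SceneGroundTruth
    kinetics: DyeKinetics
    acq: AcquisitionModel
    motion: np.ndarray  # (T, 2) int (dy, dx) window offsets
    gains: np.ndarray  # (T,)
    blinks: np.ndarray  # (T,) bool
    a_cc: np.ndarray
    a_rpe: np.ndarray

    def composite_frame(self, t_index: int) -> np.ndarray:
        """Noise-free, gain-free ICG composite for one timestamp at its offset."""
        dy, dx = self.motion[t_index]
        rpe = self.scene.crop_at((dy, dx), "rpe")
        cc = self.scene.crop_at((dy, dx), "cc_mask")
        k = self.kinetics
        return (
            self.a_rpe[t_index] * rpe
            + self.a_cc[t_index] * cc
            + k.baseline_autofluorescence
        )


def _random_walk(
    n: int, amplitude: int, step: float, rng: np.random.Generator
) -> np.ndarray:
    if amplitude == 0:
        return np.zeros((n, 2), dtype=int)
    steps = rng.normal(0.0, step, size=(n, 2))
    walk = np.cumsum(steps, axis=0)
    walk = np.clip(np.round(walk), -amplitude, amplitude).astype(int)
    walk[0] = 0
    return walk


def render_video(
    scene: SceneGroundTruth,
    kinetics: DyeKinetics,
    acq: AcquisitionModel,
) -> tuple[dict[str, FrameStack], VideoGroundTruth]:
    """Render a multi-channel AO-ICG acquisition of a scene.

    Channels returned: ``icg`` (fluorescence: dye in vessels + RPE uptake +
    autofluorescence baseline), ``multiply_scattered`` (nonfluorescent static
    texture that tracks illumination gain only) and ``confocal`` (static cone
    mosaic).  Every channel sees the same motion, gain, blinks and noise
    statistics.  Blink frames are rendered near-zero.  Returns the stacks and
    the full ground truth.
    """
    if acq.motion_amplitude > scene.pad:
        raise ValueError("motion shifts exceed the scene's padded canvas")
    rng = np.random.default_rng(acq.seed)
    motion_rng = np.random.default_rng(
        acq.seed + 1 if acq.motion_seed is None else acq.motion_seed
    )
    times = acq.times()
    a_cc, a_rpe = simulate_component_traces(kinetics, times)
    motion = _random_walk(acq.n_frames, acq.motion_amplitude, acq.motion_step, motion_rng)
    gains = (
        np.ones(acq.n_frames)
        if acq.illumination_gain is None
        else acq.illumination_gain.copy()
    )
    blinks = acq.blink_mask()

    H = W = scene.field
    chans = {
        "icg": np.empty((acq.n_frames, H, W)),
        "multiply_scattered": np.empty((acq.n_frames, H, W)),
        "confocal": np.empty((acq.n_frames, H, W)),
    }
    k = kinetics
    for t in range(acq.n_frames):
        dy, dx = motion[t]
        rpe = scene.crop_at((dy, dx), "rpe")
        cc = scene.crop_at((dy, dx), "cc_mask")
        msl = scene.crop_at((dy, dx), "msl")
        cone = scene.crop_at((dy, dx), "cone")
        icg = gains[t] * (a_rpe[t] * rpe + a_cc[t] * cc + k.baseline_autofluorescence)
        ms = gains[t] * msl
        cf = gains[t] * cone
        if blinks[t]:
            icg, ms, cf = 0.01 * icg, 0.01 * ms, 0.01 * cf
        if acq.noise_scale > 0:
            for name, img in (("icg", icg), ("multiply_scattered", ms), ("confocal", cf)):
                noisy = img + acq.noise_scale * np.sqrt(np.maximum(img, 0)) * (
                    rng.standard_normal((H, W))
                )
                chans[name][t] = np.clip(noisy, 0.0, None)
        else:
            chans["icg"][t] = icg
            chans["multiply_scattered"][t] = ms
            chans["confocal"][t] = cf

    stacks = {
        name: FrameStack(
            pixels=chans[name],
            channel=name,
            times=times,
            pixel_scale=scene.pixel_scale,
        )
        for name in chans
    }
    truth = VideoGroundTruth(
        scene=scene,
        kinetics=kinetics,
        acq=acq,
        motion=motion,
        gains=gains,
        blinks=blinks,
        a_cc=a_cc,
        a_rpe=a_rpe,
    )
    return stacks, truth
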