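"""End-to-end orchestration: simulate → register → normalize → stage → quantify.

A :class:`PipelineConfig` gathers every tunable parameter behind one seed and
round-trips losslessly through YAML; :func:`run_pipeline` executes the stages
in order, writes each intermediate artifact (TIFF stacks, CSV tables, PNG
plot) into an output directory, and returns a machine-readable summary with
the headline quantities: recirculation time and its z-score, stage windows,
flow-void morphometrics, layer spacings and size-scale ratios, and the
cross-modality match metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import ccimage, dynamics, io, morphometry, normalization, preprocess, synthetic
from .validation import half_spacing_threshold, match_centroids

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """A configuration field is outside its permitted range."""


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with physiologically grounded defaults."""

    seed: int = 0
    # scene
    field: int = 200
    pixel_scale: float = 1.0  # µm/px
    rpe_spacing: float = 14.0  # µm
    cone_spacing: float = 4.0  # µm
    cc_void_spacing: float = 31.0  # µm
    cc_void_diameter: float = 15.0  # µm
    # kinetics (seconds / 1/s)
    t_arrival: float = 8.0
    t_peak1: float = 13.0
    peak1_width: float = 2.0
    recirc_delay: float = 18.3
    recirc_amp_ratio: float = 0.35
    recirc_width: float = 5.0
    rpe_uptake_rate: float = 1.2
    # acquisition
    frame_rate: float = 16.7
    n_frames: int = 1250
    motion_amplitude: int = 5
    noise_scale: float = 0.05
    blink_schedule: list = dc_field(default_factory=list)
    # preprocessing / normalization
    registration_channel: str = "multiply_scattered"
    blink_rel_threshold: float = 0.5
    dark_fraction: float = 0.02
    # dynamics
    smoothing_window: int = 15
    min_prominence_frac: float = 0.05
    min_separation_s: float = 5.0
    stability_tol: float = 0.005
    stability_span_s: float = 10.0
    # morphometry
    frangi_scales: list = dc_field(default_factory=lambda: [5.0, 8.0, 12.0, 16.0, 20.0])
    void_threshold: object = "otsu"
    min_void_area_um2: float = 20.0
    drp_bin_width: float = 1.0
    spectrum_crop: int = 0  # 0 → full common ROI (capped at 500)
    # validation
    rpe_dropout: float = 0.09
    centroid_jitter_um: float = 1.0

    def validate(self) -> None:
        checks = [
            ("pixel_scale", self.pixel_scale > 0),
            ("field", self.field >= 32),
            ("rpe_spacing", self.rpe_spacing > 2 * self.pixel_scale),
            ("cone_spacing", self.cone_spacing > 2 * self.pixel_scale),
            ("cc_void_diameter", 0 < self.cc_void_diameter < self.cc_void_spacing),
            ("t_arrival", 0 <= self.t_arrival < self.t_peak1),
            ("recirc_delay", self.recirc_delay > 0),
            ("recirc_amp_ratio", 0 <= self.recirc_amp_ratio < 1),
            ("frame_rate", self.frame_rate > 0),
            ("n_frames", self.n_frames > 1),
            ("blink_rel_threshold", 0 < self.blink_rel_threshold < 1),
            ("dark_fraction", 0 < self.dark_fraction <= 0.1),
            ("smoothing_window", self.smoothing_window >= 1 and self.smoothing_window % 2 == 1),
            ("min_prominence_frac", 0 < self.min_prominence_frac < 1),
            ("rpe_dropout", 0 <= self.rpe_dropout < 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigError(f"invalid value for field '{name}': {getattr(self, name)!r}")

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def kinetics(self) -> synthetic.DyeKinetics:
        return synthetic.DyeKinetics(
            t_arrival=self.t_arrival,
            t_peak1=self.t_peak1,
            peak1_width=self.peak1_width,
            recirc_delay=self.recirc_delay,
            recirc_amp_ratio=self.recirc_amp_ratio,
            recirc_width=self.recirc_width,
            rpe_uptake_rate=self.rpe_uptake_rate,
        )

    def acquisition(self) -> synthetic.AcquisitionModel:
        return synthetic.AcquisitionModel(
            frame_rate=self.frame_rate,
            n_frames=self.n_frames,
            motion_amplitude=self.motion_amplitude,
            blink_schedule=[tuple(b) for b in self.blink_schedule],
            noise_scale=self.noise_scale,
            seed=self.seed + 100,
        )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic acquisition + analysis chain.

    Pure function of the config (identical config + seed → identical
    summary).  When ``outdir`` is given, intermediates and a ``summary.json``
    are written there.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    # -- simulate -----------------------------------------------------------
    scene = synthetic.make_scene(
        field=config.field,
        pixel_scale=config.pixel_scale,
        rpe_spacing=config.rpe_spacing,
        cone_spacing=config.cone_spacing,
        cc_void_spacing=config.cc_void_spacing,
        cc_void_diameter=config.cc_void_diameter,
        pad=max(16, config.motion_amplitude + 2),
        seed=config.seed,
    )
    stacks, truth = synthetic.render_video(scene, config.kinetics(), config.acquisition())

    # -- preprocess ---------------------------------------------------------
    reg_src = stacks[config.registration_channel]
    preprocess.detect_blinks(reg_src, config.blink_rel_threshold)
    registered_src = preprocess.register_translation(reg_src)
    icg = preprocess.apply_shifts(stacks["icg"], registered_src)
    msl = (
        registered_src
        if config.registration_channel == "multiply_scattered"
        else preprocess.apply_shifts(stacks["multiply_scattered"], registered_src)
    )

    # -- normalize + dynamics ----------------------------------------------
    chan = normalization.channel_normalize(icg, msl)
    trace = dynamics.IntensityTrace(icg.times, chan.trace, chan.stack.valid)
    smoothed = dynamics.smooth_trace(trace, config.smoothing_window)
    summary: dict = {"seed": config.seed}
    try:
        peaks = dynamics.detect_peaks(
            smoothed, config.min_prominence_frac, config.min_separation_s
        )
        stages = dynamics.define_stages(
            smoothed, peaks, config.stability_tol, config.stability_span_s
        )
        recirc = dynamics.recirculation_time(peaks)
        summary["recirculation_time_s"] = recirc
        summary["recirculation_zscore"] = dynamics.zscore(recirc)
        summary["recirculation_delay_true_s"] = config.recirc_delay
        summary["stage1_s"] = list(stages.stage1)
        summary["stage1_rising_s"] = list(stages.stage1_rising)
        summary["stage3_s"] = list(stages.stage3) if stages.stage3 else None
    except dynamics.NotMeasurableError as exc:
        summary["recirculation_time_s"] = None
        summary["not_measurable_reason"] = str(exc)
        peaks = stages = None

    # -- choriocapillaris image --------------------------------------------
    cc_result = None
    if stages is not None and stages.stage3_found:
        auto = normalization.autonormalize(icg, config.dark_fraction)
        img1 = ccimage.stage_mean_image(auto.stack, stages.stage1_rising)
        img3 = ccimage.stage_mean_image(auto.stack, stages.stage3)
        cc_result = ccimage.subtract_stages(
            img1, img3, pixel_scale=config.pixel_scale, provenance=stages
        )

    # -- morphometry --------------------------------------------------------
    if cc_result is not None:
        ves = morphometry.frangi_enhance(
            cc_result.pixels, config.frangi_scales, config.pixel_scale
        )
        voids = morphometry.segment_flow_voids(
            cc_result.pixels,
            ves,
            pixel_scale=config.pixel_scale,
            threshold=config.void_threshold,
            min_area=config.min_void_area_um2,
        )
        if len(voids):
            fv = morphometry.flow_void_summary(voids)
            summary["flow_voids"] = {
                "n": int(fv.loc["count", "area_um2"]),
                "mean_area_um2": float(fv.loc["mean", "area_um2"]),
                "mean_perimeter_um": float(fv.loc["mean", "perimeter_um"]),
                "mean_effective_diameter_um": float(
                    fv.loc["mean", "effective_diameter_um"]
                ),
            }
        crop = config.spectrum_crop or min(500, *cc_result.pixels.shape)
        spec = morphometry.radial_power_spectrum(
            cc_result.pixels, config.pixel_scale, crop=min(crop, *cc_result.pixels.shape)
        )
        summary["cc_row_spacing_um"] = spec.row_spacing
        summary["cc_spacing_reliable"] = bool(spec.reliable)

    rpe_sp = morphometry.drp_spacing(scene.rpe_centroids, config.drp_bin_width)
    cone_sp = morphometry.drp_spacing(scene.cone_centroids, config.drp_bin_width / 2)
    summary["rpe_spacing_um"] = rpe_sp.spacing
    summary["cone_spacing_um"] = cone_sp.spacing
    if cc_result is not None and summary.get("flow_voids"):
        # the CC size scale is the flow-void size (effective diameter), the
        # feature a reader compares against cell spacings across layers
        cc_sp = morphometry.SpacingResult(
            spacing=summary["flow_voids"]["mean_effective_diameter_um"],
            method="spectrum",
        )
        r_rpe, r_cc = morphometry.size_scale_ratios(cone_sp, rpe_sp, cc_sp)
        summary["size_ratio_rpe_over_cone"] = r_rpe
        summary["size_ratio_cc_over_cone"] = r_cc

    # -- cross-modality validation -----------------------------------------
    rng = np.random.default_rng(config.seed + 7)
    ref = scene.rpe_centroids
    keep = rng.random(len(ref)) >= config.rpe_dropout
    test = ref[keep] + rng.normal(0, config.centroid_jitter_um, (keep.sum(), 2))
    thr = half_spacing_threshold(rpe_sp)
    match = match_centroids(test, ref, thr)
    summary["rpe_match"] = {
        "tp": match.tp,
        "fp": match.fp,
        "fn": match.fn,
        "recall": match.recall,
        "precision": match.precision,
        "threshold_um": thr,
    }

    # -- artifacts ----------------------------------------------------------
    if out is not None:
        io.save_registered(out / "icg_registered", icg)
        io.write_trace(
            out / "trace.csv", trace.times, trace.values, trace.valid, chan.factors
        )
        io.write_centroids(out / "rpe_centroids.csv", scene.rpe_centroids, "truth")
        if cc_result is not None:
            import tifffile

            tifffile.imwrite(
                out / "choriocapillaris.tif", cc_result.pixels.astype(np.float32)
            )
        if peaks is not None:
            _plot_dynamics(out / "dynamics.png", smoothed, peaks, stages)
        io.write_json(out / "summary.json", summary)
    return summary


def _plot_dynamics(path, smoothed, peaks, stages) -> None:
    """Annotated fluorescence-intensity time plot (trace + peaks + stages)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    t, v = smoothed.times[smoothed.valid], smoothed.values[smoothed.valid]
    ax.plot(t, v, lw=1, color="k", label="normalized AO-ICG signal")
    ax.plot(peaks.peak_times, peaks.peak_values, "rv", label="bolus peaks")
    if stages is not None:
        ax.axvspan(*stages.stage1_rising, color="tab:orange", alpha=0.3, label="stage 1 rise")
        if stages.stage3:
            ax.axvspan(*stages.stage3, color="tab:blue", alpha=0.2, label="stage 3")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (norm.)")
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
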