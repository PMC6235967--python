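# Methods

## Signal model

The fluorescence intensity of an AO-ICG video frame at time *t* is modelled
as

    I(x, t) = g(t) · [ a_rpe(t) · RPE(x) + a_cc(t) · CC(x) + b ] + noise

where `RPE(x)` is the epithelial mosaic pattern, `CC(x)` the binary
perfused-vessel mask (1 = vessel, 0 = flow void), `b` the constant
near-infrared autofluorescence baseline, and `g(t)` a per-frame illumination
gain. The vascular amplitude is a sum of two Gaussian bolus passages

    a_cc(t) = A · [ exp(−(t−t₁)²/2σ₁²) + ρ · exp(−(t−t₁−Δ)²/2σ₂²) ],

with recirculation delay Δ, amplitude ratio ρ < 1 and σ₂ > σ₁ (the
secondary passage is broadened and weakened by mixing with the bloodstream).
The epithelial amplitude is a saturating uptake

    a_rpe(t) = P · (1 − exp(−k · max(0, t − t₀))).

Defaults: t₀ = 8 s, t₁ = 13 s, σ₁ = 2 s, Δ = 18.3 s (the normative mean
transit), ρ = 0.35, σ₂ = 5 s, P = 1, A = 1.5, b = 0.12, k = 1.2 s⁻¹. The
uptake rate is deliberately fast — uptake is essentially complete within
~2–3 s of dye arrival — reflecting the observation that RPE cells are
already uniformly fluorescent in the earliest-phase images and that the
stage-subtraction strategy works at all: it requires the RPE contribution to
be comparable in stage 1 and stage 3, and it makes the composite trace's
peak spacing an unbiased readout of Δ (a slower uptake superimposes a slope
on the primary peak and drags its apex late).

## Synthetic scenes

Cell mosaics are jittered triangular lattices (uniform per-coordinate
displacement, as a fraction of the pitch). Defaults: RPE 14 µm and cones
4 µm at jitter 0.05 (foveal mosaics are highly ordered), choriocapillaris
flow voids on a 31 µm lattice at jitter 0.08 with ~15 µm elliptical voids
(equal-area ellipse axes, 12% diameter CV). The RPE pattern is the Voronoi
partition of its centroids — bright interiors with mild per-cell brightness
variation, dark boundaries; cones are Gaussian spots; the nonfluorescent
multiply-scattered channel is a static smooth texture that tracks only
`g(t)`. A note on geometry: the first spectral ring of a hexagonal lattice
with nearest-neighbour pitch *s* sits at the row frequency 1/(√3/2·s), so
the power-spectrum "row-to-row spacing" of the default pattern reads
≈ 0.87 × 31 ≈ 27 µm; the field's convention of quoting that number as the
void spacing absorbs this ~13% geometric factor.

Acquisition artifacts: per-frame rigid translation from an integer-clipped
Gaussian random walk (default amplitude ±5 px, step SD 1.2 px) realised by
translating a viewing window across a padded canvas, so content genuinely
enters and leaves the field; blinks as scheduled frame intervals rendered at
1% intensity; Poisson-like noise (Gaussian with variance ∝ mean, scale knob,
clipped at zero). Not modelled: optical PSF and wavefront residuals,
intra-frame (line-wise) distortion, torsion, photon-accurate radiometry, and
late-phase heterogeneous RPE fluorescence. Passing tests therefore
demonstrate algorithmic correctness under rigid motion and shot noise, not
robustness to intra-frame warp — the known fidelity gap versus strip-based
registration of real AOSLO video.

## Pipeline choices

* **Blinks** — a frame is rejected when its spatial mean falls below 0.5 ×
  the median frame mean (and any non-positive frame); detection runs on the
  nonfluorescent channel, whose brightness is static apart from gain.
* **Registration** — whole-frame integer-pixel translation maximizing the
  cross-correlation with a reference frame (default: the brightest valid
  frame), computed on the nonfluorescent channel and re-used for the
  simultaneously acquired ones. Integer shifts avoid resampling blur in the
  later subtraction. The common ROI is the maximal rectangle observed
  in-bounds by every valid shifted frame; all downstream statistics are
  restricted to it.
* **Autonormalization** — the darkest 2% of pixels of the smoothed
  temporal-mean image (a fixed set across frames) proxy the background; each
  frame is divided by its mean over that set. The fraction is a free
  parameter (`dark_fraction`), capped at 10%.
* **Channel normalization** — each fluorescence frame is divided by the
  frame's nonfluorescent spatial mean normalized around one; the resulting
  trace is affinely rescaled to [0, 1] over valid frames (disable the
  rescale when absolute differences matter).
* **Peak timing** — the trace is smoothed by a validity-aware Gaussian
  kernel of 15-sample support (σ = window/6, the ±3σ convention); local
  maxima need prominence ≥ 5% of the trace range and ≥ 5 s separation; each
  peak time is then refined to the vertex of a least-squares parabola fitted
  within ±1 s of the maximum (≈ σ/2 of the narrowest bolus peak — inside
  that neighbourhood the quadratic model is accurate, and the fit averages
  away sample noise that an argmax cannot).
* **Stages** — the pre-arrival baseline is the median of samples before the
  trace first reaches 20% of the peak-1 rise; the rising phase starts where
  the trace exceeds baseline + 10% of the rise. Stage 1 is symmetric about
  peak 1, bounded by the inter-peak minimum. Stage 3 is the earliest
  post-last-peak window of ≥ 10 s in which |d/dt| ≤ 0.005 × (peak-1 rise)
  per second, extended to the end; if none exists the acquisition is flagged
  and no choriocapillaris image is produced. Under the default kinetics the
  stage-3 onset lands ~30 s after peak 1, inside the empirically observed
  16–102 s band.
* **Subtraction** — stage-1-rising mean minus stage-3 mean on
  auto-normalized frames, signed values retained; display enhancement
  (high-pass at the measured cell size, 1st–99th percentile stretch) is a
  separate, presentation-only step.
* **Flow voids** — Frangi vesselness (bright-tubular, scales 5–20 µm mapped
  to σ = scale/2) is binarized (Otsu by default, or a fixed value); voids
  are 8-connected components of the sub-threshold set, minus components
  below 20 µm² or touching the border (truncated shapes bias metrics).
  Scripted add/remove edits substitute for the interactive corrections an
  expert grader would make; without them the automatic threshold
  overestimates void size by roughly 10–15% on the default scenes, which
  propagates into the pipeline's CC/cone size ratio.
* **Power spectrum** — centre crop (500 px native sampling when available),
  mean subtraction, Hann window, |FFT|², radial average in integer-radius
  annuli; the three lowest annuli are excluded from peak picking (residual
  DC/shading) and the peak is refined by a parabola through the peak annulus
  and its neighbours. A peak at the exclusion boundary or the Nyquist edge
  is flagged unreliable.
* **DRP spacing** — annular neighbour densities normalized by annulus area
  and overall density (bounding-box estimate); points within the profile
  radius of the border serve only as neighbours. The spacing is the Rodieck
  effective radius √(V/πD̄) of the summed density deficit up to the first
  recovered annulus. The estimator reads the *dead-space* radius: on
  jittered lattices it sits ~10% below the nominal pitch (the bias is shared
  across layers, so size-scale ratios are nearly unbiased), and it collapses
  toward zero for complete spatial randomness — patterns whose dead space is
  under half the mean inter-point distance are flagged non-mosaic.
* **Matching** — one-to-one assignment maximizing within-threshold pairs and
  then minimizing total distance (linear assignment with over-threshold
  pairs priced prohibitively); deterministic and order-independent, verified
  against an exhaustive dynamic program in the tests. Convention: AO-ICG
  detections are "test" (false positives), darkfield "reference" (false
  negatives), threshold = half the measured cell spacing.

## Problem sizes

Tests and the acceptance script run on 64–200 px fields, 500–1250 frames at
16.7 Hz, 20 videos for the delay-recovery experiment, and 500–540 px static
patterns for spectral checks — small enough to iterate quickly, large
enough that every estimator operates in its intended regime (≥ ~50 cells
per mosaic, ≥ ~20 voids, ≥ 2 full recirculation periods per trace).

## Known limitations

Rigid-translation registration cannot represent intra-frame distortion of
real AOSLO scans. The matching experiment models dropout (cells that take up
no dye) but no spurious detections, so its precision is exactly 1 rather
than the ~0.95 seen with human graders. Automatic void segmentation without
manual edits inflates void sizes versus expert-corrected masks. The DRP
estimator's one-bin-level underestimate on perfect lattices is inherent to
its stop-at-recovery rule.
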