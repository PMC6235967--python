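# aoicg

Analysis of adaptive-optics indocyanine-green angiography (AO-ICG) video of
the human outer retina: the photoreceptor–RPE–choriocapillaris complex at
cellular resolution.

## The problem

An AOSLO equipped for ICG fluorescence records a video of a small retinal
patch while an injected dye bolus transits the eye. Three things are buried
in that video:

1. **The choriocapillaris.** ICG dye is taken up by RPE cells almost
   immediately, so early ("stage 1", around the primary bolus peak) and late
   ("stage 3", the post-recirculation plateau) frames both mix RPE and
   vascular signal. Averaging the frames of the *rising phase* of stage 1
   and subtracting the stage-3 average cancels the RPE mosaic and reveals
   the capillary meshwork with its dark flow voids.
2. **Recirculation time.** The mean-fluorescence trace shows a sharp primary
   peak and a broadened, weaker secondary peak ~18 s later as the bolus
   recirculates. The peak-to-peak time is a candidate biomarker of systemic
   vascular perfusion; a patient's value is scored against the normative
   18.31 ± 2.98 s as *z* = (x − 18.31)/2.98.
3. **Morphometry.** Flow voids (Frangi vesselness → threshold → region
   metrics: area, perimeter, effective diameter 2√(A/π)), the flow-void
   row-to-row spacing (peak of the radially averaged 2-D power spectrum of a
   500×500 px crop), cell-to-cell spacing of cone/RPE mosaics (density
   recovery profile, Rodieck effective radius of the dead space), and
   cross-modality validation of detected mosaics (optimal centroid matching
   at half the measured cell spacing, reported as precision/recall).

Because raw patient video is not redistributable, the package ships a
ground-truthed synthetic generator (`aoicg.synthetic`) that renders
multi-channel acquisitions — RPE/cone/choriocapillaris patterns, two-peak
dye kinetics with fast RPE uptake, eye motion, blinks, illumination gain,
shot noise — so every stage of the pipeline is testable end to end.

## Worked example

```sh
aoicg run demo --seed 1
```

renders a 200 µm × 200 µm healthy-eye acquisition (1250 frames at 16.7 Hz,
1 µm/px, recirculation delay 18.3 s built in) and runs the whole chain. The
summary it printed:

```
recirculation time: 18.30 s
```

and from `demo/summary.json` (abridged):

| quantity | value | meaning |
|---|---|---|
| `recirculation_time_s` | 18.30 | peak-to-peak bolus transit (truth: 18.3 s) |
| `recirculation_zscore` | −0.002 | within the normative 18.31 ± 2.98 s range |
| `stage1_rising_s` | [8.2, 13.0] | rising phase of the primary peak |
| `stage3_s` | [43.7, 74.8] | stable plateau used for subtraction |
| `cc_row_spacing_um` | 27.1 | flow-void row spacing from the power spectrum |
| `rpe_spacing_um` | 12.6 | RPE cell spacing by density recovery profile |
| `size_ratio_rpe_over_cone` | 3.6 | RPE/cone size-scale ratio |
| `rpe_match` recall/precision | 0.92 / 1.00 | AO-ICG vs darkfield centroid agreement |

`demo/` also holds the registered stack, the annotated intensity-time plot
(`dynamics.png`), the choriocapillaris image (`choriocapillaris.tif`) and
every table as CSV. The stages are also available piecewise
(`aoicg simulate / preprocess / normalize / dynamics / ccimage / quantify /
validate`), exchanging TIFF + CSV/YAML artifacts.

As a library:

```python
from aoicg.pipeline import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(seed=1))
```

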