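# camdart

Ca²⁺ microdomain analysis for ratiometric live-cell fluorescence imaging.

Immune-cell activation (T cells, NK cells) begins with brief, spatially
confined elevations of free cytosolic Ca²⁺ — *microdomains* — that appear
within seconds of stimulation, e.g. when an antibody-coated bead touches
the cell membrane and mimics an immune synapse. Quantifying where and
when these events occur, across populations of cells that differ in
shape and deform over time, requires a consistent spatial reference
frame. `camdart` provides a batch pipeline for exactly this analysis:

1. **Postprocessing** — affine registration of the two indicator
   channels, background subtraction, optional Lucy–Richardson
   deconvolution, additive/multiplicative/biexponential bleaching
   correction, and per-pixel ratio computation with clipping.
2. **Cell detection and tracking** — per-frame instance segmentation
   (classical backend built in, pluggable for learned models),
   Hungarian frame-to-frame linking with gap bridging, and extraction of
   a fixed-size ROI per cell with the cell kept centered by integer
   shifts (intensities preserved exactly).
3. **Shape normalization** — each cell outline, expressed in polar
   coordinates (r_o, θ) about the cell centroid, is mapped onto a circle
   of radius c·r_av where r_av = Σᵢ r_o,i / N is the mean outline radius;
   image values follow via the inverse radial map with nearest-neighbor
   interpolation. Angles are preserved, so positions relative to the
   membrane and the stimulation site remain comparable across cells.
4. **Microdomain detection** — connected sets of cell pixels whose
   intensity exceeds a threshold *relative to the frame's mean cell
   intensity* (default 2.0, 8-connectivity, 4–200 px), making detection
   invariant to global intensity scale.
5. **Dartboard projection** — every cell's events are rotated so the
   bead-contact direction (user-supplied on a 1–12 clock scale) is
   aligned, time-shifted so contact is t = 0, and accumulated on an
   equal-area ring×segment polar grid. Ring radii follow
   r_k = R·√(b² + k(1−b²)/n) so each annulus has the same area, and
   densities are normalized per area unit, per second, per cell.

A fully deterministic synthetic-video generator (deforming star-convex
cells, two complementary channels, biexponential bleaching, scripted or
Poisson-placed events, shot/read noise) provides ground truth so every
stage is testable without any microscopy data.

## Worked example

Simulate a 4-cell recording (170 frames at 10 frames/s, bead contact at
t = 1 s) and run the complete pipeline on it:

```python
from camdart.config import PipelineConfig
from camdart.pipeline import run_pipeline
from camdart.synthetic import SyntheticSpec
import pandas as pd

cfg = PipelineConfig(output_dir="demo_out", seed=42)
spec = SyntheticSpec(n_cells=4, n_frames=170, seed=42)
run_pipeline(cfg, simulate=True, spec=spec)

print(pd.read_csv("demo_out/domains/group_per_cell.csv").to_string(index=False))
```

```
 cell_id  activated  mean_domains_per_frame
       0       True                0.483444
       1       True                0.258278
       2       True                0.397351
       3       True                0.317881
```

All four cells are *activated* (≥ 1 microdomain from bead contact
onward) and show 0.26–0.48 detected domains per frame over the 15 s
analysis window. The dartboard table for the first time bin (0–5 s
after contact) shows where those events sit after alignment:

```python
board = pd.read_csv("demo_out/dartboard/dartboard.csv")
print(board[(board.bin_start_s == 0.0) & (board["count"] > 0)]
      [["ring", "segment", "count", "density"]].to_string(index=False))
```

```
 ring  segment  count   density
    2        0      9  8.952466
    2        1      6  5.968310
    3        0     15 14.920776
    3        1      3  2.984155
    3       11      1  0.994718
    4        0     12 11.936621
    4        9      3  2.984155
```

Segment 0 is centered on the aligned bead-contact direction; rings count
outward from the central bullseye. The generator places events at a
10:1 rate contrast near vs. far from the contact site, and the
projection recovers exactly that signature: the contact-facing wedge
(segment 0, outer rings) dominates, with densities in events per area
unit per second per cell. `demo_out/dartboard/dartboard_bin*.png`
contain the corresponding polar heatmaps.

The same run is available from the shell:

```bash
camdart run --out demo_out --seed 42 --simulate
```

Real recordings are analysed the same way: point `input_ch1`/`input_ch2`
(or a combined dual-view TIFF plus `dual_view_layout`) and the
`bead_contacts` sidecar CSV (`cell_id, contact_frame, clock_position`)
to your data in a YAML config and run `camdart run --config pipeline.yaml`.

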