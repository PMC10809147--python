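# Methods

This note documents the models and numerical choices behind `camdart`,
the defaults and why they were chosen, and what the synthetic-data tests
do and do not demonstrate about real microscopy data.

## Coordinate and angle conventions

Pixel indices are 0-based `(row, col) = (y, x)` with pixel centers at
integer coordinates. Polar angles are measured counterclockwise from
the +x (column) axis *as displayed*, i.e. image "up" (−y) is π/2. Bead
contacts are specified on a clock face overlaid on the image (12 = up,
3 = right, clockwise), mapped to radians by θ = π/2 − clock·π/6. After
alignment, the common reference contact direction is θ = 0 (clock 3);
this is arbitrary and configurable. All conversions go through
`camdart._geometry` so the convention cannot drift between modules.

## Postprocessing

**Registration.** The two indicator channels are aligned by maximizing
normalized cross-correlation (NCC). Phase correlation (without spectral
whitening, which is unreliable for smooth low-frequency images)
initialises a subpixel translation; Powell refinement then optimises a
euclidean (rotation + translation) model and, for `register_model:
affine`, polishes the full 6-parameter affine. The affine polish is kept
only when it both improves the NCC and stays within a small
neighbourhood of the euclidean solution — an unconstrained affine search
can trade geometric plausibility for marginal NCC gains. NCC is
evaluated only over pixels where the resampled moving image is defined
(NaN fill outside the domain), because zero-filled borders otherwise
bias the optimum toward smaller shifts. By default only the first frame
is registered and the transform applied to all frames; per-frame
registration is available. Interpolation for resampling is bilinear
(nearest is exposed); deformable registration is out of scope.

**Ratio.** ch1/ch2 per pixel; denominators ≤ 1e−9 give 0 rather than
NaN/Inf. Zero is safe downstream because microdomain thresholds are
strictly above 1× the cell mean. Optional clipping to a ratio range of
interest saturates at the bounds without resurrecting masked pixels.

**Background.** Scalar or per-frame subtraction with clipping at zero;
the level comes from a user ROI, a dark-percentile estimate (default
1st percentile), or a constant.

**Bleaching.** Three corrections:

* *additive*: per frame, add `target − mean(frame over cell mask)` to
  all pixels; the masked mean becomes exactly the target.
* *multiplicative*: per frame, scale by `target / mean`.
* *biexponential*: fit f(t) = a + b₁e^(−t/τ₁) + b₂e^(−t/τ₂) to the
  masked mean trace (least squares, τ > 0 enforced, several τ
  initialisations spanning the observation window, exchange degeneracy
  resolved by sorting τ₁ ≤ τ₂) and subtract f(t) − f(0) from each frame.

`target` defaults to the first frame's masked mean. The frame-wise
variants clamp at zero, which is exact as long as offsets are
non-negative (the bleaching direction); stacks brightening over time
could clip dark pixels.

## Lucy–Richardson deconvolution

Per-frame 2-D Richardson–Lucy with the observed frame as initial
estimate: u_{k+1} = u_k · [psf* ⊛ (d / (psf ⊛ u_k))]. Convolutions use
FFTs over reflectively padded frames; reflective boundaries conserve
total intensity for compactly supported objects (verified to < 1% over
15 iterations, and to machine precision for interior objects). A guard
ε = 1e−12 sets the ratio to 1 (no update) where the re-blurred estimate
underflows. The update is multiplicative, so nonnegativity is preserved
at every iteration; a delta PSF and a flat image are exact fixed points.
The default iteration count is 10 — a conventional choice; the method is
otherwise parameter-free given the PSF (Gaussian by σ, or a single-page
TIFF). Temporally coupled restoration is not implemented; a `backend`
hook accepts external restoration callables.

## Segmentation, tracking, ROI extraction

The default segmentation backend is classical: Gaussian smoothing
(σ = 1.5), Otsu threshold, hole filling, watershed on the distance
transform to split touching cells, and a minimum-area filter
(default 150 px ≈ a 7 px-radius cell at 0.368 µm/px). Any callable
mapping a frame to a label image can replace it — this is the adapter
point for learned instance-segmentation models, which are deliberately
not bundled. A constant frame yields an empty result, not an error.

Linking solves the per-frame-pair assignment problem exactly (Hungarian
algorithm on Euclidean centroid distance) with a gate of `max_disp_px`
per elapsed frame; tracks missing for up to `max_gap = 2` consecutive
frames are bridged; tracks with fewer detections than `min_frames` are
dropped. `min_frames` defaults to the frame count of the analysis
window (1 s before to 15 s after contact), so only cells observable for
the whole analysis survive.

ROIs are fixed-size (track-maximal bounding box + padding) and re-center
the cell with *integer* shifts only, so pixel values — and therefore
relative-intensity detections — are unchanged by extraction. Rotational
motion is not compensated.

## Shape normalization

For each frame, boundary vertices are converted to polar samples
(r_o, θ) about the mask centroid, resampled to `n_boundary_samples`
(default 360) uniform angular bins. Outlines must be star-convex about
the centroid; when a bin contains multiple boundary crossings the
outermost one is used and a warning is emitted. The radial map
T: (r, θ) → (r · c·r_av / r_o(θ), θ) sends the outline to a circle of
radius c·r_av (scale factor c = 1 by default). Output pixels are filled
through the inverse map — each template pixel at (r′, θ) samples the
source at radius r′·r_o(θ)/(c·r_av) along the same angle — with
nearest-neighbor lookup both for r_o(θ) and for the image value, so a
circular cell is reproduced identically up to discretization (≥ 99% of
pixels). The normalized mask is exactly the template disk.

Within a trace the template radius is fixed to c · median(r_av over
frames) rather than per-frame r_av, so a cell whose outline breathes
over time maps to one constant circle and temporal statistics remain
comparable. Pixels inside the template disk whose source location falls
outside the cell mask (possible for concave outlines) take the source
value regardless of mask membership. The mapping is angle-preserving
but not area-preserving; the radial area distortion is absorbed by the
dartboard's per-area normalization.

## Microdomain detection and statistics

Relative intensity rel(p) = I(p) / mean over the cell mask of the frame;
candidates are mask pixels with rel > threshold; connected components
(8-connectivity default) within [min_size, max_size] = [4, 200] px
become detections. The defaults (threshold 2.0) are deliberate,
conservative starting points — the appropriate values depend on the
imaging setup and noise level and are expected to be tuned per
experiment, ideally from a noise analysis. The mask mean includes the
candidate pixels themselves. Detection runs on shape-normalized frames
by default (`shape_norm: on`), where the cell mask is the template disk.

A cell is *activated* if at least `min_active_frames = 1` frames from
contact onward contain a domain. Group statistics (activated fraction,
per-timepoint mean ± SEM of domain counts) are computed over the
analysis window, default 1 s before to 15 s after contact; SEM for a
single cell is reported as 0 and flagged.

## Dartboard projection

Geometry: a central bullseye of radius fraction b = 0.2 plus
n_rings = 5 annuli of exactly equal area (r_k = R√(b² + k(1−b²)/n)),
each split into n_segments = 12 equal wedges; segment 0 is *centered*
on the aligned contact direction so "near contact" is one wedge.
Events enter by domain centroid (one domain = one count); radii are
normalized by the template radius and clipped to [0, 1]. Counts per
(time bin × ring × segment) divide by segment area × bin duration ×
number of cells — pooled counts across cells, not per-cell averages.
Default time bins are 0–5, 5–10 and 10–15 s after contact; a moving
average over uniform fine bins (shrinking window at the edges) serves
refined time courses. Rendering uses a polar mesh whose per-wedge values
round-trip exactly to the densities.

## Synthetic data generator

The generator emulates the structure of a bead-stimulation experiment at
desk scale. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| frame interval | 0.1 s, 170 frames | ~17 s recording covering 1 s pre- to 15 s post-contact; a scaled-down rendition of high-speed ratiometric imaging |
| pixel size | 0.368 µm | EMCCD with 2× binning at 100× magnification |
| cell radius | 18 ± 2 px | ≈ 6.6 µm, lymphocyte scale |
| shape | circle + Fourier harmonics (3, 0.06), (5, 0.03), slow temporal modulation | star-convex by construction — inside the shape normalizer's validity domain |
| contact | frame 10 (t = 1 s), clock position random or fixed | |
| event rates | 1.0 /s near contact vs 0.1 /s elsewhere, from contact onward | the 10:1 spatial contrast that the dartboard is designed to resolve |
| "near contact" | within ±1 clock hour and r_frac ≥ 0.6 | subplasmalemmal events at the contact site |
| events | Gaussian spots, σ 1.5 px, amplitude 3× cell mean on ch1, proportional dip on ch2, 3 frames | |
| intensities | ch1 100, ch2 150, background 10 | arbitrary camera units |
| bleaching | ch2 × f(t)/f(0), f biexponential (a, b₁, τ₁, b₂, τ₂) = (0.3, 0.4, 2 s, 0.3, 10 s) | the rising indicator bleaches negligibly; both decay constants lie inside the observation window so they are identifiable |
| noise | Gaussian σ = 5 (5% of cell mean), optional Poisson | detection threshold sits far above the background relative-intensity noise |

All randomness comes from one seed (bit-reproducible TIFFs). The ground
truth records masks, boundaries, event positions/times and pre-noise
channel means.

What the generator does **not** emulate: indicator photophysics (Kd,
Hill kinetics), PSF-accurate optics (events are ideal Gaussians), cell
crowding and contact, focus drift, and non-star-convex morphologies
(available only behind an explicit flag for negative testing). Passing
the synthetic tests therefore demonstrates correctness of the
*computational contracts* — geometry, alignment, detection logic,
parameter recovery under the stated noise — not performance on any
particular microscope's data, where thresholds and segmentation
parameters must be tuned.

## Evaluation protocol

`camdart.evaluation` runs the pipeline on a 20-cell study (170 frames,
inter-channel misalignment (1.4, −2.6) px applied to ch2) and scores:

* *detection precision/recall*: ground-truth events are predicted in
  normalized coordinates from their scripted polar position (angles are
  preserved by normalization and the radius fraction maps to
  r_frac × template radius); a detection within 5 px during the event's
  lifetime (± 1 frame) is a match. Precision is per detected domain,
  recall per true event.
* *spatial contrast*: counts in the contact-facing segment vs. the
  opposite segment (summed over annuli, first time bin); when the
  opposite segment is empty the raw near count is reported as the ratio.
* *registration error*: max |recovered − applied| channel shift.
* *bleaching recovery*: relative τ errors of the biexponential fit on a
  noiseless ch2 mean trace, per the generator's bleach parameters.

Problem sizes (20 cells, 170 frames, 10⁵ Monte-Carlo points, 200 oracle
masks, 100 scripted alignment events) were chosen so the whole
evaluation completes in a few minutes on a single CPU.

## Known limitations

* Shape normalization requires star-convex outlines; strongly concave
  or partially-out-of-field cells fail (with a logged warning and
  exclusion from group statistics rather than an abort).
* The additive bleaching correction applies one offset to *all* pixels
  of a frame, including background.
* Bead contacts must be supplied by the user (sidecar CSV); automatic
  contact detection is not implemented.
* Track linking handles translation only; division/merging and rotation
  are out of scope.
* Only multi-page TIFF I/O is supported natively; other formats must be
  converted beforehand.
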