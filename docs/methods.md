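# Methods

This note documents the models, estimators and numerical choices behind
`fibroswarm`, in the spirit of a methods supplement: what each procedure
assumes, which parameters matter, and what the synthetic data do and do
not emulate.

## Agent-based migration model

Cells are point agents with unit headings in a circular (2D) or
spherical (3D) arena.  At each frame the heading of cell *i* is updated
to the normalised sum

```
h_i <- normalize( a * u_centre(i) + m * mean_neighbour_heading(i) + n * eta_i )
```

with `a = attraction_weight` (centripetal pull towards the arena
centre), `m = alignment_weight` (Vicsek-type alignment with the mean
heading of neighbours within `neighbor_radius`), `n = noise_weight`
(isotropic unit noise `eta`), after which the position advances by
exactly `speed` pixels along the new heading.  Cells reflect elastically
off the arena boundary.  This is the smallest model that reproduces the
qualitative dichotomy the analysis pipeline is built to detect: with
`a, m > 0` the population migrates as an aligned, centre-directed swarm;
with `a = m = 0` (`mode="random"`) each trajectory is an isotropic
fixed-step random walk, so mean squared displacement is exactly
`speed² × lag` and the movement-similarity score is 90° in expectation.
`mode="chimera"` seeds a second lineage in the inner half-radius disc,
mirroring explant-chimera geometries in which labelled outer-ring cells
invade an inner core.

Defaults (200 cells, arena radius 200 px, speed 2 px/frame, dt 15 min,
neighbour radius 30 px, weights 1/1/0.3) were chosen once to give a
clear statistical contrast between modes at desk scale — cell speeds
and densities are not calibrated to any measured tissue, and no
proliferation, death or mechanics is modelled.  Step length is fixed
rather than drawn from a speed distribution; real cells also pause and
reorient with temporal persistence that this model does not attempt.

## Rendering and the PIV oracle

The renderer draws each cell as an isotropic Gaussian spot (sd
`spot_sigma`, default 2 px) in the channel of its lineage, then applies
`Poisson(signal × photon_scale)/photon_scale` shot noise and additive
Gaussian read noise — the standard fluorescence detection model.  It
emulates nuclear-reporter movies well enough to exercise PIV, linking
and front extraction; it does not emulate membrane labels, z-blur,
photobleaching or motion blur.

`advected_pair` builds PIV validation data with *exact* ground truth:
a speckle texture (Gaussian-filtered uniform noise, correlation length
~1.5 px) is synthesised on a canvas padded by the maximum displacement
and warped by a known flow (translation, rigid rotation, or radial
expansion) with cubic-spline interpolation, then both frames are
cropped to the interior.  The padding matters: without it the warp
would have to invent content at the image border, and windows there
would no longer see a pure displacement.

## Iterative PIV

`run_piv` is a multi-pass window-offsetting scheme over strictly
decreasing window sizes (default 64/32/16 px, 50% overlap).  Each
window of frame A is located inside a search region of frame B (the
window offset by the rounded predictor from the previous pass, padded
by half a window) using fast normalized cross-correlation with local
mean/variance normalization — the Lewis NCC used by template matching.
Full NCC rather than plain zero-mean FFT correlation is deliberate:
with partial pattern overlap (clipped search regions at frame edges)
raw correlation carries an overlap envelope that biases peaks towards
zero shift, while NCC is unbiased position by position.  The integer
peak is refined per axis with a 3-point Gaussian fit (parabolic
fallback when a lobe is non-positive; skipped entirely when the peak is
a perfect match, so identical frames give exactly zero).  A window
whose predicted displacement cannot fit inside the frame — the pattern
has been advected out of view — is unmeasurable; it keeps the predictor
value but is flagged invalid rather than reported as a measurement.

After every pass the field passes the normalized median test: per
component, with `m` the median of the 8 neighbours and `r_m` the median
absolute deviation of the neighbours from `m`, the residual is
`|v − m| / (r_m + noise)`; vectors whose larger component residual
exceeds `threshold` are flagged and replaced by the neighbourhood
median (defaults noise 0.2, threshold 5).  The first-to-second peak
ratio is retained as a diagnostic only and never used for rejection.
Pass count, overlap and the replacement policy are not constrained by
the upstream plugin conventions this mirrors; they are exposed in
`PIVConfig` and documented as assumptions.

## Movement-similarity score

For each frame interval `t → t+1`, cells present at both ends are
triangulated (scipy Delaunay) at their *start* positions; neighbours
are cells sharing a triangulation edge.  Each cell's score is the mean
angle between its displacement vector and each neighbour's, computed as
`atan2(|v₁ × v₂|, v₁·v₂)` (numerically exact at 0° and 180°, unlike
arccos); zero-length vectors are excluded pairwise, and a cell with no
usable pair contributes no score that frame.  The global score is the
unweighted mean over all (cell, frame) scores — the simplest reading of
"average all angles"; pooling all angles instead of averaging per cell
first changes the value by < 0.1° in all regimes tested here.  Angles
are kept on [0, 180]; display colour maps conventionally clamp at 90
(an isotropic *mean* of 90° requires the unfolded range).  Coplanar or
Qhull-degenerate 3D point sets fall back to a 2D triangulation on the
two highest-variance axes, with a logged notice.  The triangulation is
recomputed every frame since positions move; neighbours are not
additionally gated by distance (an option the data could motivate but
the definition does not require).

## Kinematics, landmarks, overlays

Step displacement is the Euclidean 3D distance between consecutive
positions of the same cell; velocity divides by the frame interval
(default 15 min).  The population velocity curve is the per-time-point
mean smoothed by a centred moving average (window 5 time points).
Landmark displacement follows exactly five landmark tracks sampled
every second frame (stride 2): per sample the five displacements are
averaged and the running sum is reported versus time.  Time-coded
overlays draw the trailing 12 segments of each track coloured along a
purple-to-red ramp; they are visual artefacts and feed no statistics.

## Enrichment index

`MFI_G / (MFI_G + MFI_R)` over an ROI, where MFI is the mean pixel
intensity of a channel.  The index assumes co-registered channels on a
common intensity calibration: it is invariant to a shared gain but not
to per-channel gain, which is the main practical caveat when comparing
across acquisitions.

## Fractal dimension and lacunarity

Analysis is restricted to the bounding box of the foreground (making
the estimate translation invariant).  Grey-scale input is binarised at
40% of its maximum — a bit-depth-independent reading of a 0.40 pixel
threshold.  Box grids at scales of powers of two from 2 px to a quarter
of the longer bbox side (≥ 4 scales required) are evaluated at 4 grid
origins (the origin plus 3 random offsets).  The box count per scale is
the **minimum cover** over origins: an offset grid can only cover the
same set with at least as many boxes, and averaging over origins
systematically inflates counts at coarse scales, dragging the fitted
dimension low (on reference sets by ~0.1).  With minimum cover the
estimator lands within 0.03 of the truth for the filled square (2.0),
the 1-px line (1.0) and the depth-5 Sierpinski carpet
(log 8/log 3 ≈ 1.8928).  `fd` is minus the least-squares slope of
log N versus log ε; the fit R² is reported.

Lacunarity at each scale and origin is `(σ/μ)²` of per-box foreground
mass over the boxes lying **fully inside** the bounding box — including
empty interior boxes (pores), but excluding partial border boxes, so a
solid all-ones image scores exactly 0 at every scale.  The scalar
lacunarity is the mean over scales and origins; it is undefined (NaN)
for patterns thinner than the smallest box.  Dense, space-filling
textures score high fd / low lacunarity and porous sparse textures the
reverse — the direction used to contrast scar with healthy matrix.

## Trichrome quantification

Images are decomposed with the naive CMYK transform
(`K = 1 − max(R,G,B)`, `C = (1−R−K)/(1−K)`, …): iron-haematoxylin
nuclei are darkest and dominate K; aniline-blue collagen dominates C.
Nuclei counting applies, in order: background subtraction by greyscale
opening with a radius-50 px disk (the morphological formulation of the
rolling-ball algorithm, using a decomposed footprint for speed),
contrast stretch saturating 0.1% of pixels, unsharp mask
`(in − 0.6·G(in, 2))/0.4`, a radius-1 median filter, and the "Minimum"
auto-threshold (iterative histogram smoothing to bimodality; Otsu
fallback with a logged notice when bimodality is unreachable, e.g. on
near-constant channels, which short-circuit to zero counts).  Touching
objects are split by watershed on the Euclidean distance transform and
particles of 30–200 px² are counted.  Scar area thresholds the cyan
channel with the same auto-threshold family and reports foreground
pixels in the ROI (µm² when a pixel size is supplied).  No colour
deconvolution is attempted beyond CMYK; heavily counterstained slides
would need proper stain unmixing.

## Orientation fields

The structure tensor (Gaussian-derivative gradients, tensor smoothing
sigma 4 px, reflective boundaries) is averaged within grid cells of
pitch `grid_size` (default 150 px).  The orientation of image
structures is the gradient orientation rotated by 90°, mapped to
[0, 180) and measured from +x towards +y (image rows); coherence is the
normalised eigenvalue anisotropy `(λ₁−λ₂)/(λ₁+λ₂)`, exactly 0 on flat
cells, which are flagged unreliable (floor 0.1).  Vector overlays use
unit ("100%") length scaling relative to the grid pitch.

## Leading-front trajectories

Each selected frame (max-projected over z if present) is smoothed with
a Gaussian (default sigma 8 px; the smoothing scale of the upstream
contour plugin has no documented pixel meaning, so it is exposed as a
parameter calibrated on the planar-front fixture) and the front is the
iso-contour at half the global maximum.  The time-indexed fronts define
an arrival-order surface (per pixel, the number of frames before the
swarm covers it); predicted trajectories are integral curves of its
gradient seeded evenly along the earliest front, which makes them
locally perpendicular to every contour by construction.  Integration
(step 0.5 px, bilinear gradient interpolation) stops at the region the
swarm never reached, at the image border, or when the gradient
vanishes; identical frames (a static front) yield zero-length
trajectories.  The construction assumes a monotonically advancing
front; oscillating fronts would fold the arrival surface.

## IO, pipeline, determinism

Tracks travel as CSV with the fixed header
`track_id,frame,t_min,x,y,z[,lineage]`; floats are written at 6
significant digits, and read paths enforce the table invariants
(unique (track, frame) pairs, finite coordinates).  Movies are
multi-page TIFF with a JSON description carrying axes, shape and
timing, so write-then-read round trips are bit exact.  Pipeline runs
execute stages in dependency order, stamp every artefact with a
provenance record (tool version, config hash stable under key
reordering, input hashes, seed, timestamp), and are byte-identical on
CSV artefacts for identical config and seed.  All stochastic components
take a single integer seed through `numpy.random.default_rng`.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale: 512² PIV frames
(~3.5 s for the full cascade), simulations of 200–1500 cells over
10–60 frames, 729² fractal fixtures, 512² histology fixtures.  Passing
them shows the estimators are correct on data matching their
assumptions (exact ground truth, clean separation, no optics); it does
not validate performance on real microscopy, where segmentation error,
uneven illumination, stain variability and 3D effects dominate and
would surface first in the linking and thresholding stages.
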