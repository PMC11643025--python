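# Methods

This note describes the models behind each metric, the parameters that
matter, the synthetic-data generators used for validation, and the numerical
choices made where the procedure was genuinely open.

## Coordinate and geometry conventions

Pixel indices are 0-based with pixel centers at integer coordinates; `x` is
the column, `y` the row, and `y` increases downward. After band
straightening, "basal" is the direction of increasing row index, so the most
basal membrane coordinate in a column is the maximum skeleton row. The
default in-plane pixel size is 0.065 µm (100x spinning-disk acquisition; a
120-pixel band corresponds to 7.8 µm).

Band straightening resamples an open polyline at unit arc-length steps and
samples the image along the local normal (tangents by central differences of
the resampled path, which realizes the mean of adjacent segment normals at
vertices). Interpolation is bilinear by default with a nearest-neighbor
option; the original protocol does not state its scheme, and the two agree
exactly on axis-aligned lines. Even band widths are coerced up to the next
odd value (with a warning) so a unique center row exists — the protocol's
120-px width has none. Samples falling outside the image are zero-filled and
flagged; columns with more than 50% out-of-bounds samples are excluded
downstream.

Polygon ROIs are rasterized by point-in-polygon containment of pixel
centers, with centers exactly on an edge included. Area-fraction subregions
rank mask pixels by the Euclidean distance transform (distance to the
nearest background pixel) with ties broken by raster order in a single
ascending sort; the peripheral region takes the head, the central region the
tail. Output sizes are exactly `round(fraction x area)`; the two regions are
disjoint whenever those rounded sizes fit in the mask (at exactly
complementary fractions rounding can force a one-pixel overlap — irrelevant
at the 0.15/0.65 fractions used).

## Basal mRNA fraction

The segmented layer is divided per column into `n_bins = 10` equal-length
intervals from the basal to the apical edge; each pixel's unit row interval
contributes to bins in proportion to overlap, so fractional thicknesses bin
without bias and a uniform layer yields exactly 1/n per bin. Binning follows
the local extent per column, which handles curved layers and reduces to
global equal bins on rectangular fixtures. Intensities are summed (not
averaged) per bin; for equal-area bins the resulting fractions are
identical, and summation is the natural choice when columns are excluded.
The basal fraction sums the basal-most bins covering `basal_extent = 0.30`
of the layer — the extent must cover an integer number of bins; partial bins
are not interpolated. A uniform background level is subtracted (clipped at
zero) before binning; if no level is given, the median intensity outside the
layer mask is a reasonable default estimate. Tubular epithelia are
straightened along the basement-membrane polyline first and binned
identically; a maximum-intensity projection over a few optical sections
(~1 µm) is available as a pre-step.

## DEJ topographical variation

DEJ_var is an image-analysis analogue of the arithmetic mean roughness of a
machined surface profile. Stages, on the straightened 121-px band:

1. **Automatic threshold** — Otsu's criterion on a 256-bin histogram
   (between-class variance maximization); the protocol names no method and
   Otsu is the canonical automatic global threshold. Constant bands are
   rejected rather than thresholded arbitrarily.
2. **Skeletonization** — standard 2D thinning to a 1-px-wide, 8-connected
   skeleton.
3. **Pruning of incomplete segments** — two rules with
   `min_span_fraction = 0.25` (configurable): spur branches (endpoint-to-
   junction paths) spanning fewer columns than that fraction of the band
   length are removed, with the junction pixel also removed when its local
   neighborhood stays connected without it (no stubs left at thick
   attachments); then whole components spanning fewer columns are removed.
   The protocol gives no explicit rule; this one removes fragments while
   provably never touching a full-width membrane line.
4. **Basal trace** — the maximum skeleton row per column; columns with no
   skeleton pixel are dropped, not interpolated, consistent with
   normalization "to the number of x-positions measured".
5. **Noise-gated mean** — displacement `d(x) = |basal_y(x) − center_row|`
   measured to the band's center row (the segmentation line); values
   strictly below `noise_threshold_px = 3` (~0.2 µm) are set to 0 (a
   displacement of exactly 3 px is retained); DEJ_var is the mean gated
   displacement over measured columns, reported in px and µm.

Multi-ROI pooling is weighted by the number of measured columns by default
(so the pooled value is the gated mean over all columns of all ROIs); an
unweighted flag is provided since the original pooling rule is unstated.

Properties verified by tests: DEJ_var ≥ 0 with equality iff all gated
displacements vanish; raising the gate never increases it; scaling image
intensities leaves it unchanged; scaling the true displacement field never
decreases the end-to-end value.

## PDI and cortical ratio

A first-moment reading of the peripheral index (distance between cell
centroid and intensity-weighted centroid, normalized to a uniform
hypothetical) degenerates to 0/0 for uniform signal; the second-moment form

    PDI = (Σ I_i r_i² / Σ I_i) / (Σ r_i² / N)

is the only reading consistent with the calibration that homogeneous signal
scores exactly 1, and is the form implemented. Distances are in pixels from
the mask's geometric centroid by default, with a nucleus-center override;
PDI is dimensionless and invariant to intensity scaling and rigid
translation. The cortical ratio is the mean intensity over the peripheral
15% area band divided by the mean over the most central 65% region; a zero
central mean is reported as an undefined-ratio error, never as infinity.

## Fiber morphometry

3D stacks are thresholded at a user-set intensity (the batch runner enforces
one threshold per condition group, so comparisons are made at equal
settings), labeled with 26-connectivity by default, and filtered: a
component is removed iff it is both small (`volume < 0.5 µm³`) and round
(`sphericity > 0.8`), so large objects of any shape and small elongated
segments always survive. Both cutoffs are configurable; the original
protocol specifies only that "morphological filters" remove "small spherical
volumes".

Sphericity is `ψ = π^⅓ (6V)^⅔ / A` with `V` from the voxel count and the
physical voxel size (anisotropic voxels supported via `z_step_um`). The
surface area `A` is by default a marching-cubes mesh estimate, which tracks
the true area of voxelized solids closely (digital balls of radius 3–10
voxels score ψ ≈ 0.90–0.97; a 3×3×60 rod scores ≈ 0.49). Voxel-face counting
is available as an alternative but overestimates a sphere's area by ~1.5x
and correspondingly deflates ψ to ~0.67 — with it, the default 0.8 cutoff
would not classify balls as spherical. For few-voxel components the mesh
under-estimates the solid's surface, so `A` is clamped from below by the
isoperimetric bound (the sphere area at volume `V`), keeping ψ ≤ 1.

## Synthetic data generators

All generators are pure functions of `(seed, params)` — identical calls are
bit-identical — and record a ground-truth object from which each metric's
true value is computable without running the analysis pipelines. The noise
model is Poisson shot noise (off by default) plus optional Gaussian read
noise (σ default 0); the PSF is an isotropic Gaussian, σ = 1.2 px, roughly
the diffraction limit at 0.065 µm pixels. Defaults were chosen once as
typical desk-scale study conditions: layers of 100 px thickness × 300 px
width with 2000 spots; membranes of 500 columns in a 121-px band; disk cells
of radius 40 px with 10⁵ photons; fiber scenes of 5 cylinders (r = 3,
ℓ = 70 voxels) and 10 spherical blobs (r = 4 voxels) in a 64×128×128 stack.

- **Layer**: spot depth from the basal edge follows a truncated exponential
  with scale λ (λ → ∞ uniform); a target basal fraction is converted to λ by
  root-finding. The recorded `true_basal_fraction` is the *expected
  measurable* fraction: the depth density propagated through the same
  sub-pixel splat and Gaussian blur the renderer applies, integrated over
  the basal extent by dense quadrature on the pixel grid. This is computed
  from the generative model alone and differs from the pre-blur target by
  the deterministic PSF/edge effect (≈0.2–0.6% at defaults), which would
  otherwise appear as estimator bias; the pre-blur target is recorded
  alongside.
- **Membrane**: a bright connected curve of given thickness at
  `center + displacement(x)` for flat, sine, square or smoothed-random-walk
  displacement fields, with the straight reference polyline returned; the
  true mean |displacement| is closed-form (0, 2A/π, A) or recorded.
- **Cell**: fraction `w` of total expected intensity uniform over the
  peripheral 15% band, `1 − w` over the interior; the expected cortical
  ratio `(w/A_peripheral)/((1 − w)/A_interior)` follows from the recorded
  areas (the central 65% is a subset of the interior, where density is
  uniform). `w = 1` produces, by design, a downstream undefined-ratio error.
- **Fibers**: randomly oriented solid cylinders plus spherical blobs with
  voxel-accurate labels; isotropic voxels by default (axial step equal to
  the in-plane pixel size, matching fine serial sectioning) so blobs are
  spheres in physical space. Objects are rejection-sampled to not touch
  (default), keeping labels unambiguous for recovery scoring; with
  `avoid_overlap=False` later objects overwrite earlier ones and overlaps
  are logged.

What the generators deliberately do not model: staining chemistry,
bleaching, depth-dependent aberrations, structured background, or realistic
tissue texture. Passing recovery tests therefore demonstrates correctness of
the measurement pipelines under the stated generative assumptions, not
robustness to every property of real tissue images.

## Problem sizes and tolerances

Recovery tests use 50 seeded replicates per condition for the basal-fraction
estimator (tolerance: mean within 2 standard errors of the generative
truth), single images for DEJ membranes (10% for the square wave, whose
skeleton rounds corners at transitions; 5% for the sine), 5% for the
cortical-ratio closed form at 10⁵ photons, and recall ≥ 0.95 / leakage
≤ 0.05 for fiber-vs-blob classification at default filter settings. Oracle
tests compare against exhaustive brute-force implementations (point-in-
polygon, between-class-variance search, distance ranking) on randomized
small fixtures.

## Known limitations

- The basal trace takes the most basal skeleton pixel per column; deep
  undercuts (multi-valued membrane profiles) are collapsed to their deepest
  point, as in any per-column profile metric.
- Otsu thresholding assumes a roughly bimodal band histogram; extremely
  sparse membranes in a wide band can shift the threshold.
- Per-column binning assumes the layer mask is vertically contiguous per
  column after straightening; holes inside the mask are treated as in-layer
  gaps with zero intensity contribution.
- Sphericity of components a few voxels in size is dominated by
  discretization; the isoperimetric clamp makes such components read as
  spherical, which is the desired behaviour for the small-object filter but
  makes ψ uninformative below ~10 voxels.
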