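# epiquant

Quantitative fluorescence-microscopy metrics for stratified and tubular
epithelia, built for studies of subcellular mRNA localization and
epithelial–matrix organization. The package turns manually segmented ROIs
plus intensity images into five scalar readouts:

- **Basal mRNA fraction** — the share of a segmented epithelial layer's FISH
  signal in the basal-most 30% of its apico-basal thickness, from 10 equal
  bins per layer (`epiquant.basal`).
- **DEJ topographical variation (DEJ_var)** — a roughness metric for the
  dermal–epidermal junction: straighten a 121-px band around a segmentation
  line drawn on the basal membrane stain, Otsu-threshold, skeletonize, prune
  incomplete segments, take the most basal skeleton coordinate per
  x-position, and average the noise-gated absolute displacement from the
  line (displacements < 3 px are set to 0) (`epiquant.dej`).
- **Peripheral distribution index (PDI)** — intensity-weighted second-moment
  dispersion of RNA signal in a cell, normalized to a hypothetical uniform
  distribution: `PDI = (Σ I_i r_i² / Σ I_i) / (Σ r_i² / N)`; > 1 peripheral,
  = 1 homogeneous, < 1 perinuclear (`epiquant.cells`).
- **Cortical ratio** — mean protein intensity in the peripheral 15% area
  band of a segmented cell over the mean in its most central 65%
  (`epiquant.cells`).
- **Fiber volume** — cumulative volume of fibrillar structures in a 3D
  stack after intensity thresholding (equal across samples of one
  comparison), connected-component labeling, and removal of small spherical
  objects (sphericity `ψ = π^⅓(6V)^⅔/A`) inconsistent with fiber segments
  (`epiquant.fibers`).

A seeded synthetic-image generator (`epiquant.synthetic`) emulates each
input class — basally enriched punctate layers, displaced membrane contours,
cortically partitioned cells, fiber/blob stacks — with closed-form ground
truth, enabling end-to-end parameter-recovery tests.

## Worked example

```python
import numpy as np
from epiquant import (make_membrane_image, dej_variation_pipeline,
                      make_layer_image, bin_layer, basal_fraction)

# a membrane whose basal contour is a sine of amplitude 20 px
img, line, truth = make_membrane_image(seed=3, amplitude_px=20, waveform="sine")
res = dej_variation_pipeline(img, line, noise_threshold_px=0)
print(f"DEJ_var = {res.dej_var_px:.2f} px (truth 2A/pi = {2*20/np.pi:.2f})")

# an epithelial layer with 50% of spot signal in the basal 30%
img, truth = make_layer_image(seed=7, target_basal_fraction=0.5)
frac = basal_fraction(bin_layer(img))
print(f"basal fraction = {frac:.3f} (truth {truth.true_basal_fraction:.3f})")
```

prints

```
DEJ_var = 12.66 px (truth 2A/pi = 12.73)
basal fraction = 0.503 (truth 0.495)
```

The recovered DEJ_var matches the analytic mean |A sin| = 2A/π of the sine
membrane to within the voxelization error of the rendered curve. The layer
estimate scatters around the generative model's expected measurable fraction
(0.495, slightly below the nominal 0.5 because the PSF blurs a little signal
across the 30% boundary and the layer edges); over seeded replicates its
mean recovers that truth within sampling error.

There is also a CLI (`epiquant simulate|basal-fraction|dej-var|pdi|cortical|fibers|run`);
`epiquant run --config run.yaml --out results.csv` executes a whole manifest
of (image, ROI, metric) entries and writes one tidy row per measurement,
enforcing equal fiber thresholds within each condition group.

## Documentation

`docs/methods.md` describes the model behind each metric, its parameters and
defaults, the synthetic-data generators and their limits, and the numerical
choices made.
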