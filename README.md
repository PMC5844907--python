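# intensify3d

Intensity normalization for large fluorescence-microscopy image stacks
(2-photon and light-sheet), with a synthetic sphere phantom and a
detection-based evaluation harness for controlled validation.

## The problem

Depth- and position-dependent signal loss is endemic to 3D fluorescence
imaging: excitation and emission decay with tissue depth, the light sheet
attenuates across the field, clearing and antibody penetration vary through
the sample. The resulting brightness gradients — within each plane and
across the stack — break every downstream step that assumes comparable
intensities: threshold-based detection, co-localization, 3D rendering,
stitching.

This package corrects a stack using only its own background, guided by two
user parameters:

- **MBI** (maximum background intensity): the highest pixel value still
  attributable to background, chosen on one reference plane;
- **SFS** (spatial filter size): the smoothing window, at least twice the
  size of the largest signal structure.

Per plane (XY normalization): the MBI is propagated to every plane by
quantile rank, pixels above it are deleted and in-filled from the plane's
own sub-MBI background, the result is smoothed into a background mask *M*
by a separable Savitzky–Golay filter of window SFS, and the plane is
corrected by division,

```
N(x) = I(x) / M(x) · s,      s = median of M over tissue,
```

so that pure background returns to its typical level instead of saturating.
Across planes (Z normalization), each plane's intensity histogram —
summarized by 10,000 recorded quantiles of its tissue pixels — is
harmonized by one of three modes: an upper-quantile shift, a contrast
stretch between the 10th percentile and the upper quantile, or
semi-quantile normalization (full quantile matching below the upper
quantile, contrast stretch above it). For light-sheet data where the
specimen does not fill the frame, a per-plane tissue detector (PCA over
local intensity/texture features, then 2-cluster GMM-EM or K-means) keeps
the imaging medium out of the correction.

## Worked example

Generate a distorted synthetic stack, normalize it, and score the result:

```bash
intensify3d phantom generate --preset desk --distortion none     --seed 1 --out ref
intensify3d phantom generate --preset desk --distortion combined --seed 1 --out dist
# MBI 155 = the upper edge of the background on the middle (reference) plane
intensify3d normalize --input dist --output corr \
    --mbi 155 --sfs 41 --reference-plane 32 --z-mode semiq --seed 1
intensify3d evaluate --truth ref/ground_truth.tsv --stack corr/normalized \
    --reference ref --threshold otsu
```

The evaluate step prints a flat table; the run above ends with:

```
threshold	542
n_true	50
n_detected	50
tp	50
fp	0
fn	0
tpr	1.0000
false_discovery_fraction	0.0000
reference_tpr	1.0000
histogram_emd	0.053009
mae_voxel_count	0.129295
mae_mean_intensity	0.038910
mae_integrated_intensity	0.166287
mae_centroid_distance	0.172017
mae_n_common_tp	50.000000
```

Reading it: after correction all 50 spheres are recovered with no false
detections, the corrected histogram sits close to the undistorted one
(EMD 0.053 on the unit intensity scale), and per-sphere measurements of
the true positives deviate from the undistorted reference by ~4% in mean
intensity. Evaluating the distorted stack instead gives tpr 0.96 with a
14% false-discovery fraction, EMD 0.095, and a 5.8% mean-intensity error.
The same pipeline is available from Python via
`intensify3d.normalize_stack` / `intensify3d.run_normalize`.

## Layout

| Module | Role |
| --- | --- |
| `intensify3d.stack_io` | TIFF series I/O, support-mask and quantile-log output |
| `intensify3d.tissue_detector` | tissue vs. imaging-medium segmentation |
| `intensify3d.xy_normalizer` | MBI propagation, signal removal, background mask, division |
| `intensify3d.z_normalizer` | quantile profiles and the three Z modes |
| `intensify3d.phantom` | Gaussian-sphere phantom and distortion fields |
| `intensify3d.evaluator` | 3D object counting, truth matching, MAE, histogram EMD |
| `intensify3d.validation` | the end-to-end phantom validation protocol |
| `intensify3d.pipeline` / `intensify3d.cli` | run orchestration, manifest, CLI |

See `docs/methods.md` for the model, parameter guidance, and limitations.
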