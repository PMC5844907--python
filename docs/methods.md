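# Methods

## Model and assumptions

The correction rests on two assumptions about fluorescence stacks:

1. In an ideal acquisition, the intensity distribution of the *background*
   would be the same everywhere in the imaged region. Observed differences
   in the background distribution — within a plane or across depth — are
   therefore acquisition artifacts to be removed.
2. Signal-carrying pixels are sparse and spatially scattered, while
   background pixels are numerous with a continuous histogram, so
   background quantiles can be estimated accurately even after the signal
   is excised.

Under a multiplicative shading model `I(x) = g(x)·I₀(x) + ε`, a smooth
estimate *M* of the background equals `g · B` (B the true background
level), so dividing by *M* removes *g* from signal and background alike and
preserves signal-to-noise ratios: for a two-level image with flat *M*, the
ratio `N(s)/N(b) = s/b` exactly. What division cannot do is *undo* noise:
in a region attenuated by `g`, corrected noise is amplified by `1/g`.
Attenuation beyond roughly the background-to-noise ratio is unrecoverable
by any rescaling method; this bounds the distortion strengths the phantom
experiments use (see below).

## Pipeline

1. **Tissue detection** (optional, per plane). Three per-pixel features —
   local mean, local standard deviation (window `feature_window`, default
   9 px), raw intensity — are standardized, reduced to two principal
   components, and split into two clusters by GMM-EM (full covariances,
   tol 1e-4, ≤200 iterations, k-means++ init) or K-means (10 restarts).
   The brighter cluster is tissue (autofluorescent tissue outshines
   mounting medium in both target modalities), which also makes the result
   seed-invariant. Clustering runs on a strided subsample
   (`downsample_factor`, default 8) and the label map is upsampled
   nearest-neighbor, then cleaned: fill holes, drop components below
   `min_component_area` (default 0.1% of the plane), dilate by
   `dilation_radius` (default SFS/4) to keep the media/tissue border out
   of the correction. Detection is per-plane with no 3D coupling — tissue
   extent can change arbitrarily between planes.

2. **MBI propagation.** The user picks the MBI on one reference plane.
   Its *quantile rank* q\* among that plane's tissue pixels — not its raw
   value — is transferred: plane *i* gets `mbi_i = Q_i(q*)`. Rank is
   invariant to per-plane brightness changes, which is exactly the
   variation being corrected. Two practical rules follow:

   - the reference plane must contain signal (pick one mid-stack); on a
     signal-free plane every pixel is background and q\* degenerates to 1;
   - choose the MBI slightly *conservatively* (our validation harness uses
     the 95th percentile of the reference plane). The rank must stay below
     the signal — including the dim halos around bright objects — on
     *every* plane, and with the level-preserving in-fill (below), cutting
     a sliver off the top of the background costs nothing, while signal
     leaking into the background estimate biases it.

3. **Signal removal and in-fill.** Tissue pixels above `mbi_i` are
   replaced by draws (i.i.d., with replacement) from the plane's own
   sub-MBI tissue pixels. Each draw is re-centred on the local background
   level: the sampled donor contributes its residual against the
   donor-masked moving average (window = SFS) at its own location, added
   to the same average at the filled location, clipped to `[0, mbi_i]`.
   On a gradient-free plane this is exactly plain resampling from the
   empirical background law; on a shaded plane it keeps the in-fill on the
   local gradient instead of pulling it toward the plane-wide mean (which
   would flatten, under every removed region, the very gradient the mask
   must estimate).

4. **Background mask.** The signal-free plane (medium filled with the
   tissue median) is smoothed by a separable 2D Savitzky–Golay filter:
   window = SFS coerced up to odd, polynomial order `sg_order` (default 3),
   rows then columns. Edges use least-squares polynomial fits over the
   terminal window, so linear (and cubic) trends are reproduced exactly to
   the boundary — with mirror padding the mask would flatten at plane
   edges, exactly where attenuation is worst. The mask is floored at
   `mask_floor` (default 1 ADU) so division is always defined. SFS should
   be at least twice the largest signal structure; gradients below that
   scale are treated as background structure and removed.

5. **Division and standardization.** `N = I/M · s` on tissue pixels, with
   `s` = median of *M* over tissue — a robust per-plane scale that returns
   pure background to its typical ADU level, preventing integer
   "overexposure" on write. Non-tissue pixels pass through untouched.
   Results stay floating-point until file output (round-half-up, clip to
   the input bit depth), so Z normalization never double-quantizes.

6. **Z normalization.** Per plane, 10,000 quantiles of the corrected
   tissue pixels are recorded at ranks k/(Q+1), k = 1..Q (avoiding the 0/1
   ranks), by linear interpolation of order statistics — a compact
   sufficient statistic that also serves the tool's memory model (planes
   are processed one at a time; only profiles are kept). One shared target
   is the *mean* over planes of each profile component. Modes:

   - **upper_quantile**: multiply tissue by `target_uq / uq_i` — a pure
     histogram shift;
   - **contrast_stretch**: affine map sending (10th percentile, upper
     quantile) to the targets, extrapolated outside the anchors, floored
     at 0;
   - **semi_quantile**: below the upper quantile, monotone piecewise-linear
     matching of the recorded quantiles to the target vector; above it,
     the contrast-stretch law anchored at the upper quantile so the two
     branches meet continuously. Pixels below the first recorded quantile
     (a handful per plane) extrapolate with the contrast-stretch slope.

   All three maps are monotone nondecreasing — ranks within a plane are
   never inverted. The boundary rank between the two semi-quantile regimes
   is q\* capped at `min_i(1 − signal_fraction_i)` (signal fractions are
   known from the removal step): planes richer in signal than the
   reference would otherwise have their "upper quantile" land inside the
   signal range, making the stretch content-dependent. The supra-quantile
   slope is the background-spread ratio `(target_uq − target_lq)/(uq_i −
   lq_i)` rather than an anchor at the plane maximum — the maximum is a
   single noisy voxel and varies with plane content.

   Planes with no tissue are skipped: passed through unchanged and
   excluded from the target.

7. **Reproducibility.** Every stochastic step draws from a substream keyed
   `(seed, plane_index)`, so results are bit-identical across reruns,
   plane orderings, and process-pool worker counts; the worker setting is
   purely a speed knob. Each run writes a JSON manifest (config, seed,
   version, warnings) sufficient to reproduce it.

## The sphere phantom

Validation data is synthesized, with full ground truth: `n_spheres`
Gaussian spheres `A·exp(−‖r−c‖²/2σ²)` rendered on a zero volume, blurred
by a Gaussian PSF, plus a flat background and i.i.d. Gaussian sensor
noise, quantized to the stack's bit depth. Desk-scale defaults:
128×128×64 voxels, 50 spheres, σ ∈ [1, 2] voxels, amplitude ∈
[1500, 3000] ADU, background 300 ADU, noise σ 8 ADU, PSF σ (1, 1, 2)
voxels, margin 8, 16-bit. Centers are rejection-sampled with a 14-voxel
minimum separation so every sphere is a distinct 26-connected object at
detection thresholds. A full-scale preset (600×600×500, 500 spheres) is
available behind `--preset fig5`.

Why these values: a detectable sphere occupies roughly `87·σ_eff³` voxels
above background, so sphere size controls the signal-pixel fraction — with
σ ≤ 2 the phantom keeps signal at a few percent of the volume, honouring
the sparsity assumption the method relies on. Background noise is set to
~2.7% of the background level (a well-exposed sCMOS regime): the phantom
is meant to probe *shading* correction, and the residual background CV
after correction is bounded below by noise × the mean inverse attenuation,
so a noise-dominated phantom would measure the camera, not the correction.

Distortions multiply the *noise-free* volume (illumination and detection
losses act before the sensor); fresh noise is added afterwards. The four
families — linear in X, separable linear in X and Y, logarithmic in Z
(`g = (1−c) + c(1 − ln(1+z)/ln Z)`), and combined — use per-kind default
strengths chosen so the worst-case attenuation is ~3–5×: a = 0.7 (X),
a = 0.55 (XY), c = 0.8 (Z), and a = 0.35 with c = 0.53 combined. Strengths
compound across axes, and past ~5× the darkest corner falls below the
noise floor where no correction is defined (corrected noise there is
amplified `1/g`-fold). All field values lie in (0, 1]; ground truth is
independent of distortion.

What the phantom does *not* emulate: anisotropic scattering, aberration,
autofluorescence texture, Poisson (signal-dependent) noise, tissue/medium
boundaries (the phantom fills the frame, so the validation pipeline runs
with tissue detection off — the detector is validated separately on
two-region planes). Passing these tests shows the pipeline recovers smooth
multiplicative fields under sparse Gaussian objects; it does not certify
behaviour on structured backgrounds (e.g. white vs. grey matter), which the
method's own assumptions exclude.

## Evaluation protocol

Detection mimics threshold-based 3D object counting: binarize at a shared
threshold, label 26-connected components, drop those below `min_size`
(default 5 voxels), and measure voxel count, intensity-weighted centroid,
mean/integrated/max intensity. The shared operating point is an Otsu
threshold computed once on the undistorted stack; every other stack is
first brightness-matched to the reference by an affine map anchored on its
median (the background level — signal is sparse) and its 99.99th
percentile (robust maximum). Literal min/max anchors would let a single
amplified-noise voxel set the scale of the whole stack relative to the
threshold. Detections match ground-truth centers greedily by ascending
distance (one-to-one, gate = 2× mean sphere σ): matched = TP, unmatched
detections = FP, unmatched truths = FN. Because object detection has no
defined negative count, the false-positive axis is reported as the
false-discovery fraction fp/detections. Per-sphere statistics are compared
as relative MAE against the *reference detections* (same counter on the
undistorted stack), over spheres that are true positives in every arm
being compared — restricting to a common sphere set prevents the distorted
arm from being scored only on the easy spheres it managed to detect.
Histogram restoration is scored by a 1D earth-mover distance between
histograms rescaled to [0, 1] by their own robust (0.01/99.99 percentile)
ranges, on 256 shared bins.

The validation harness (`intensify3d.validation`) fixes the pipeline
settings an informed user would choose on a phantom: reference plane =
mid-stack, MBI = its 95th percentile, SFS 41 (≈2× the largest sphere's
above-background footprint), semi-quantile Z mode.

## Numerical choices and degenerate inputs

- Quantile computation: one sort per plane, linear interpolation between
  order statistics (matching numpy's default convention) — both in the
  profiles and in MBI propagation.
- Semi-quantile exactness: with Q = 10,000 recorded quantiles the map is a
  compression; recomputed sub-UQ profiles match the target to ~1e-4
  relative on generic noisy planes, and exactly (machine precision) when
  the plane's pixel count aligns with the rank grid (n = Q + 2, where the
  recorded quantiles are the order statistics themselves). The
  upper-quantile mode matches its target to 1e-9 relative on any input.
- Constant plane: tissue detection returns all-true with a warning;
  SG filter reproduces the constant; all Z modes reduce to the identity.
- A plane with no tissue after cleanup passes through unchanged, is
  excluded from Z targets, and is flagged in the manifest.
- MBI below every tissue pixel raises immediately (the user must raise it).
- SFS ≥ the smaller plane dimension raises; even SFS is coerced up to odd
  with a note.
- Seeds: all randomness flows from `numpy.random.default_rng([seed, key])`
  substreams; keys are plane indices (XY in-fill) and fixed offsets
  (phantom placement 1, base noise 2, distortion noise 1000+kind).

## Known limitations

- A single intensity threshold (the MBI) cannot separate signal from
  background when a plane's *background* spans a wider range than its
  dimmest signal — strong in-plane gradients on the raw data put dim
  signal below bright-corner background. The rank-based propagation
  mitigates but cannot eliminate this; it is intrinsic to the parameter.
- Division amplifies noise by the inverse attenuation; regions attenuated
  below the noise floor are unrecoverable and will surface as
  false-positive speckle if thresholded.
- The semi-quantile mode assumes background *distributions* should agree
  across planes; if backgrounds differ intrinsically (different tissue
  types at different depths), it will "correct" genuine biology.
- The tissue detector separates two classes only (tissue vs. medium) and
  assumes tissue is the brighter one.
- The object counter is plain connected-components labelling; it has no
  watershed step, so touching objects merge (the phantom enforces a
  minimum sphere separation for exactly this reason).
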