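"""Per-plane tissue vs. imaging-medium segmentation.

Light-sheet acquisitions of cleared organs usually image the specimen inside
a bath of mounting medium; correcting "background" gradients in the medium
would only amplify noise there, so normalization should act on tissue pixels
alone.  Each plane is classified independently: simple per-pixel features
(local mean, local standard deviation, raw intensity) are standardized,
projected on two principal components, and split into two clusters with
either a Gaussian-mixture EM fit or K-means.  The cluster with the higher
mean raw intensity is called tissue — autofluorescent tissue is brighter
than medium in both acquisition regimes this tool targets.  The raw cluster
map is then cleaned morphologically to avoid normalization artifacts at the
media/tissue border.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import binary_dilation, disk, remove_small_objects
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

logger = logging.getLogger("intensify3d")


@dataclass
class TissueDetectorConfig:
    """Settings for tissue/medium classification.

    method: "gmm_em", "kmeans", or "none" (mask everything as tissue).
    downsample_factor: stride used when sampling pixels for clustering.
    feature_window: odd window (full-resolution pixels) for local mean/std.
    min_component_area: connected components smaller than this are dropped;
        None means 0.1% of the plane area.
    dilation_radius: final binary dilation of the mask; None lets the caller
        derive it from the spatial filter size.
    """

    method: str = "none"
    downsample_factor: int = 8
    feature_window: int = 9
    min_component_area: int | None = None
    dilation_radius: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("gmm_em", "kmeans", "none"):
            raise ValueError(f"unknown tissue detection method {self.method!r}")
        if self.feature_window < 3 or self.feature_window % 2 == 0:
            raise ValueError("feature_window must be odd and >= 3")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")


@dataclass
class TissueMask:
    grid: np.ndarray  # 2D bool, True = tissue

    @property
    def tissue_fraction(self) -> float:
        return float(self.grid.mean())


def extract_pixel_features(plane: np.ndarray, cfg: TissueDetectorConfig) -> np.ndarray:
    """Per-pixel feature table on the downsampled grid.

    Columns: local mean, local std (over ``feature_window``), raw intensity —
    each standardized to zero mean / unit variance; constant columns map to
    all-zero so they carry no weight in the PCA.
    """
    plane = np.asarray(plane, dtype=np.float64)
    w = cfg.feature_window
    local_mean = ndimage.uniform_filter(plane, size=w, mode="reflect")
    local_sq = ndimage.uniform_filter(plane * plane, size=w, mode="reflect")
    local_var = np.maximum(local_sq - local_mean * local_mean, 0.0)
    local_std = np.sqrt(local_var)
    f = cfg.downsample_factor
    cols = [a[::f, ::f].ravel() for a in (local_mean, local_std, plane)]
    feats = np.column_stack(cols)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    out = np.zeros_like(feats)
    nz = sd > 0
    out[:, nz] = (feats[:, nz] - mu[nz]) / sd[nz]
    return out


def postprocess_mask(raw: np.ndarray, cfg: TissueDetectorConfig) -> TissueMask:
    """Clean a raw cluster map: fill holes, drop specks, dilate the border."""
    grid = np.asarray(raw, bool)
    grid = ndimage.binary_fill_holes(grid)
    min_area = cfg.min_component_area
    if min_area is None:
        min_area = max(1, int(round(0.001 * grid.size)))
    if min_area > 1:
        # drop components strictly smaller than min_area
        grid = remove_small_objects(grid, max_size=min_area - 1, connectivity=2)
    radius = cfg.dilation_radius if cfg.dilation_radius is not None else 0
    if radius > 0:
        grid = binary_dilation(grid, footprint=disk(radius))
    if not grid.any():
        logger.warning("tissue mask empty after cleanup; plane treated as containing no tissue")
    return TissueMask(grid=grid)


def detect_tissue(plane: np.ndarray, cfg: TissueDetectorConfig) -> TissueMask:
    """Classify a plane into tissue vs. medium.

    Deterministic for a fixed seed; because the tissue label is assigned to
    the brighter cluster, the result is in practice also seed-invariant.
    A constant plane admits no meaningful clustering and returns all-true.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if cfg.method == "none":
        return TissueMask(grid=np.ones(plane.shape, bool))
    if plane.max() == plane.min():
        logger.warning("degenerate plane (constant); returning all-true tissue mask")
        return TissueMask(grid=np.ones(plane.shape, bool))

    feats = extract_pixel_features(plane, cfg)
    n_comp = min(2, feats.shape[1])
    scores = PCA(n_components=n_comp, random_state=cfg.seed).fit_transform(feats)

    if cfg.method == "kmeans":
        model = KMeans(n_clusters=2, n_init=10, random_state=cfg.seed)
        labels = model.fit_predict(scores)
    else:
        model = GaussianMixture(
            n_components=2,
            covariance_type="full",
            tol=1e-4,
            max_iter=200,
            init_params="k-means++",
            random_state=cfg.seed,
        )
        labels = model.fit_predict(scores)

    f = cfg.downsample_factor
    raw_ds = plane[::f, ::f].ravel()
    mean0 = raw_ds[labels == 0].mean() if (labels == 0).any() else -np.inf
    mean1 = raw_ds[labels == 1].mean() if (labels == 1).any() else -np.inf
    tissue_label = 0 if mean0 >= mean1 else 1
    ds_shape = plane[::f, ::f].shape
    small = (labels == tissue_label).reshape(ds_shape)
    # nearest-neighbor upsample back to full resolution
    full = np.repeat(np.repeat(small, f, axis=0), f, axis=1)[: plane.shape[0], : plane.shape[1]]
    return postprocess_mask(full, cfg)
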