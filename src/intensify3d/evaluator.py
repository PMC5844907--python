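"""Detection-based scoring of normalization quality.

Normalization is judged the way a microscopist would use the data: fixed-
threshold 3D object counting.  Objects are 26-connected components above a
threshold (with a minimum size), measured for centroid, voxel count, mean /
integrated / max intensity.  Detections are matched one-to-one to the known
sphere centers; the true-positive rate and the false-discovery fraction
(fp / detections — object detection has no defined negative count, so a
classical FPR is not available) summarize detection quality, and the
per-sphere statistics of common true positives are compared between a test
stack and the reference detections on the undistorted stack as relative mean
absolute errors.  A min-max-matched histogram earth-mover distance measures
how well a correction restores the original intensity histogram.

One common operating point is used for a whole experiment: an Otsu threshold
computed once on the undistorted stack and applied to every other stack
after matching its min/max range to the undistorted one — the single manual
threshold a human would pick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .stack_io import ImageStack

logger = logging.getLogger("intensify3d")


@dataclass
class DetectedObject:
    id: int
    centroid: tuple[float, float, float]  # (x, y, z), intensity-weighted
    voxel_count: int
    mean_intensity: float
    integrated_intensity: float
    max_intensity: float


@dataclass
class DetectionComparison:
    n_true: int
    n_detected: int
    tp: int
    fp: int
    fn: int
    matches: dict[int, DetectedObject] = field(default_factory=dict)  # truth idx -> detection

    @property
    def tpr(self) -> float:
        return self.tp / self.n_true if self.n_true else 0.0

    @property
    def fpr_proxy(self) -> float:
        """False-discovery fraction fp / n_detected (0 when nothing detected)."""
        return self.fp / self.n_detected if self.n_detected else 0.0


def count_objects_3d(
    stack: ImageStack | np.ndarray, threshold: float, min_size: int = 5
) -> list[DetectedObject]:
    """Threshold, label 26-connected 3D components, and measure them."""
    vol = stack.as_array().astype(np.float64) if isinstance(stack, ImageStack) else np.asarray(stack, dtype=np.float64)
    binary = vol > threshold
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    counts = ndimage.sum_labels(binary, labels, idx)
    keep = counts >= min_size
    objects: list[DetectedObject] = []
    if not keep.any():
        return objects
    kept_idx = idx[keep]
    sums = ndimage.sum_labels(vol, labels, kept_idx)
    maxima = ndimage.maximum(vol, labels, kept_idx)
    coms = ndimage.center_of_mass(vol, labels, kept_idx)  # (z, y, x), weighted
    for oid, (lab, cnt, tot, mx, com) in enumerate(
        zip(kept_idx, counts[keep], sums, maxima, coms)
    ):
        objects.append(
            DetectedObject(
                id=oid,
                centroid=(float(com[2]), float(com[1]), float(com[0])),
                voxel_count=int(cnt),
                mean_intensity=float(tot / cnt),
                integrated_intensity=float(tot),
                max_intensity=float(mx),
            )
        )
    return objects


def match_to_truth(detected, truth, max_dist: float) -> DetectionComparison:
    """Greedy one-to-one matching by ascending centroid-to-center distance."""
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    centers = truth.centers
    n_true = len(truth)
    n_det = len(detected)
    if n_det and n_true:
        cents = np.array([d.centroid for d in detected])
        dists = np.linalg.norm(cents[:, None, :] - centers[None, :, :], axis=2)
        pairs = [
            (dists[i, j], i, j)
            for i in range(n_det)
            for j in range(n_true)
            if dists[i, j] <= max_dist
        ]
        pairs.sort()
    else:
        pairs = []
    used_det: set[int] = set()
    matches: dict[int, DetectedObject] = {}
    for _, i, j in pairs:
        if i in used_det or j in matches:
            continue
        used_det.add(i)
        matches[j] = detected[i]
    tp = len(matches)
    return DetectionComparison(
        n_true=n_true,
        n_detected=n_det,
        tp=tp,
        fp=n_det - tp,
        fn=n_true - tp,
        matches=matches,
    )


_MAE_STATS = ("voxel_count", "mean_intensity", "integrated_intensity")


def mae_vs_reference(
    test: DetectionComparison,
    reference: DetectionComparison,
    restrict: set[int] | None = None,
) -> dict[str, float] | None:
    """Relative MAE of per-sphere statistics vs. the undistorted reference.

    Over spheres that are true positives in both comparisons (optionally
    further restricted to a shared sphere set, so that several test stacks
    can be compared over identical spheres), the mean absolute difference
    of each statistic, divided by the reference mean of that statistic;
    centroid error is reported as the mean Euclidean distance in voxels
    (key ``centroid_distance``).  Returns None when no true positives are
    shared.
    """
    common = sorted(set(test.matches) & set(reference.matches))
    if restrict is not None:
        common = sorted(set(common) & restrict)
    if not common:
        return None
    out: dict[str, float] = {}
    for stat in _MAE_STATS:
        t = np.array([getattr(test.matches[j], stat) for j in common], dtype=np.float64)
        r = np.array([getattr(reference.matches[j], stat) for j in common], dtype=np.float64)
        out[stat] = float(np.mean(np.abs(t - r)) / np.mean(r))
    tc = np.array([test.matches[j].centroid for j in common])
    rc = np.array([reference.matches[j].centroid for j in common])
    out["centroid_distance"] = float(np.mean(np.linalg.norm(tc - rc, axis=1)))
    out["n_common_tp"] = float(len(common))
    return out


def histogram_distance(stack_a, stack_b, bins: int = 256, percentile: float = 0.01) -> float:
    """Earth-mover distance between range-matched intensity histograms.

    Each stack is rescaled to [0, 1] by its own brightness range (removing
    global brightness/scale), binned on a shared grid, and compared by 1D
    EMD (integral of |CDF difference|).  The range endpoints are robust
    extremes (``percentile`` / ``100 - percentile``) rather than literal
    single-voxel min/max, which would let one noise outlier set the scale
    of the whole histogram; values beyond the anchors land in the end
    bins.  A constant stack puts all mass in one bin.
    """
    vols = []
    for s in (stack_a, stack_b):
        v = s.as_array().astype(np.float64) if isinstance(s, ImageStack) else np.asarray(s, dtype=np.float64)
        lo, hi = np.percentile(v, [percentile, 100.0 - percentile])
        vols.append(np.zeros_like(v) if hi == lo else np.clip((v - lo) / (hi - lo), 0.0, 1.0))
    edges = np.linspace(0.0, 1.0, bins + 1)
    cdfs = []
    for v in vols:
        h, _ = np.histogram(v.ravel(), bins=edges)
        p = h / h.sum()
        cdfs.append(np.cumsum(p))
    width = 1.0 / bins
    return float(np.sum(np.abs(cdfs[0] - cdfs[1])) * width)


def minmax_match(stack, reference, high_percentile: float = 99.99) -> np.ndarray:
    """Linearly rescale a stack onto the reference's brightness levels.

    The rescale anchors the background level (stack median — signal is
    sparse, so the median sits in the background) and a robust maximum
    (``high_percentile``) onto the reference's.  Anchoring on literal
    single-voxel extremes would let lone noise outliers — which corrections
    of deeply attenuated regions inevitably amplify — randomly shift the
    whole stack relative to the shared detection threshold; background and
    signal-top anchors keep one threshold meaningful across all stacks.
    """
    v = stack.as_array().astype(np.float64) if isinstance(stack, ImageStack) else np.asarray(stack, dtype=np.float64)
    r = reference.as_array().astype(np.float64) if isinstance(reference, ImageStack) else np.asarray(reference, dtype=np.float64)
    lo, hi = np.percentile(v, [50.0, high_percentile])
    rlo, rhi = np.percentile(r, [50.0, high_percentile])
    if hi == lo:
        return np.full_like(v, rlo)
    return (v - lo) / (hi - lo) * (rhi - rlo) + rlo


def reference_threshold(reference: ImageStack) -> float:
    """Otsu threshold on the undistorted stack — the shared operating point."""
    return float(threshold_otsu(reference.as_array()))


def score_stack(
    stack,
    reference: ImageStack,
    truth,
    threshold: float | None = None,
    min_size: int = 5,
    max_dist: float | None = None,
) -> tuple[DetectionComparison, DetectionComparison, dict[str, float] | None, float]:
    """Full scoring of one test stack against the undistorted reference.

    Returns (test comparison, reference comparison, relative MAEs, EMD).
    The test stack is min-max matched to the reference before applying the
    shared threshold.
    """
    if threshold is None:
        threshold = reference_threshold(reference)
    if max_dist is None:
        sigmas = [s.sigma for s in truth.spheres]
        max_dist = 2.0 * float(np.mean(sigmas)) if sigmas else 5.0
    ref_det = count_objects_3d(reference, threshold, min_size)
    ref_cmp = match_to_truth(ref_det, truth, max_dist)
    matched = minmax_match(stack, reference)
    det = count_objects_3d(matched, threshold, min_size)
    cmp_ = match_to_truth(det, truth, max_dist)
    maes = mae_vs_reference(cmp_, ref_cmp)
    emd = histogram_distance(stack, reference)
    return cmp_, ref_cmp, maes, emd
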