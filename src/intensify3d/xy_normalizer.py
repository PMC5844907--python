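"""Per-plane (XY) intensity normalization.

The correction model assumes that in a perfect acquisition the background
intensity distribution would be the same everywhere, and that signal pixels
are sparse.  Each plane is therefore corrected against its own background:

1. the user picks, on one reference plane, the Maximum Background Intensity
   (MBI) — the highest pixel value still attributable to background — and a
   Spatial Filter Size (SFS) of at least twice the largest signal structure;
2. the MBI is propagated to every other plane by quantile-rank matching on
   tissue pixels (rank is invariant to the per-plane brightness changes that
   are being corrected, so it travels across planes where a raw threshold
   would not);
3. signal pixels (above the plane's MBI) are deleted and in-filled with
   draws from the plane's own sub-MBI background distribution;
4. the signal-free plane is smoothed into a background mask M by a separable
   2D Savitzky-Golay filter of window SFS, keeping only gradients at scales
   larger than the signal;
5. the plane is corrected by division, N(x) = I(x) / M(x), and rescaled by
   the median of M over tissue so that pure background stays at its typical
   ADU level instead of saturating ("overexposure") after integer conversion.

Planes are independent given their MBI values; processing order does not
matter and per-plane RNG substreams keyed by (seed, plane index) make serial
and parallel execution bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import savgol_filter

from .stack_io import ImageStack
from .tissue_detector import TissueDetectorConfig, TissueMask, detect_tissue

logger = logging.getLogger("intensify3d")


@dataclass
class NormalizationConfig:
    """The full user contract for one normalization run.

    mbi is in ADU on the reference plane; sfs in pixels (coerced up to odd);
    z_mode one of {"upper_quantile", "contrast_stretch", "semi_quantile",
    "none"}.  quantile_count quantiles at ranks k/(Q+1) are recorded per
    plane for Z normalization.
    """

    mbi: float
    sfs: int
    reference_plane_index: int = 0
    sg_order: int = 3
    z_mode: str = "semi_quantile"
    lower_quantile_rank: float = 0.10
    quantile_count: int = 10000
    tissue: TissueDetectorConfig = field(default_factory=TissueDetectorConfig)
    seed: int = 0
    mask_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.mbi <= 0:
            raise ValueError("mbi must be positive")
        if self.sg_order < 1:
            raise ValueError("sg_order must be >= 1")
        if self.sfs < self.sg_order + 2:
            raise ValueError("sfs must be >= sg_order + 2")
        if not 0 < self.lower_quantile_rank < 1:
            raise ValueError("lower_quantile_rank must be in (0, 1)")
        if self.z_mode not in ("upper_quantile", "contrast_stretch", "semi_quantile", "none"):
            raise ValueError(f"unknown z_mode {self.z_mode!r}")
        if self.mask_floor <= 0:
            raise ValueError("mask_floor must be positive")

    @property
    def odd_sfs(self) -> int:
        if self.sfs % 2 == 0:
            logger.info("SFS %d is even; coerced to %d", self.sfs, self.sfs + 1)
            return self.sfs + 1
        return self.sfs


@dataclass
class BackgroundMask:
    """Smooth, strictly positive background estimate — the divisor M."""

    grid: np.ndarray
    floor_applied: bool


@dataclass
class PlaneNormalizationRecord:
    plane_index: int
    mbi_i: float
    mbi_quantile_rank: float
    n_signal_pixels_replaced: int
    standardization_scale: float
    skipped: bool = False


def propagate_mbi(
    stack: ImageStack, masks: Sequence[TissueMask], cfg: NormalizationConfig
) -> tuple[np.ndarray, float]:
    """Assign an MBI to every plane by quantile-rank matching.

    Returns (per-plane MBI values, shared quantile rank q*).  q* is the
    fraction of reference-plane tissue pixels at or below cfg.mbi; each
    plane's MBI is the q*-quantile of its own tissue pixels (the reference
    plane keeps cfg.mbi exactly).  Planes without tissue get NaN and are
    skipped downstream.
    """
    ref = cfg.reference_plane_index
    if not 0 <= ref < stack.z_count:
        raise ValueError(f"reference_plane_index {ref} out of range")
    ref_vals = np.asarray(stack.planes[ref], dtype=np.float64)[masks[ref].grid]
    if ref_vals.size == 0:
        raise ValueError("reference plane has no tissue pixels")
    q_star = float(np.mean(ref_vals <= cfg.mbi))
    if q_star == 0.0:
        raise ValueError("MBI below all tissue pixels on the reference plane")
    mbi = np.empty(stack.z_count)
    for i, (plane, mask) in enumerate(zip(stack.planes, masks)):
        if i == ref:
            mbi[i] = cfg.mbi
            continue
        vals = np.asarray(plane, dtype=np.float64)[mask.grid]
        if vals.size == 0:
            logger.warning("plane %d has no tissue pixels; flagged skip", i)
            mbi[i] = np.nan
            continue
        mbi[i] = float(np.quantile(vals, q_star))
    return mbi, q_star


def remove_signal(
    plane: np.ndarray,
    mbi_i: float,
    mask: TissueMask,
    rng: np.random.Generator,
    local_window: int | None = None,
) -> tuple[np.ndarray, int]:
    """Delete supra-MBI tissue pixels and in-fill from the background law.

    Replacement values are drawn i.i.d. with replacement from the empirical
    set of sub-MBI tissue pixels of the same plane, so the in-fill follows
    the observed background distribution without parametric assumptions.

    With ``local_window`` set, each draw is re-centred on the local
    background level: the sampled donor contributes its residual against
    the donor-pool mean around its own location, added to the mean around
    the in-filled location (masked moving averages over ``local_window``).
    On a plane with a strong shading gradient the sub-MBI pool spans the
    whole gradient, and raw global draws would flatten under removed
    regions the very gradient the background mask must estimate; local
    re-centring preserves it.  On a gradient-free plane both schemes
    coincide.
    """
    plane = np.asarray(plane, dtype=np.float64)
    out = plane.copy()
    tissue = mask.grid
    signal = tissue & (plane > mbi_i)
    n = int(signal.sum())
    if n == 0:
        return out, 0
    donor_mask = tissue & (plane <= mbi_i)
    donors_flat = np.flatnonzero(donor_mask.ravel())
    if donors_flat.size == 0:
        raise ValueError("MBI below all tissue pixels")
    picks = rng.choice(donors_flat, size=n, replace=True)
    values = plane.ravel()[picks]
    if local_window is not None and local_window >= 3:
        local = _masked_local_mean(plane, donor_mask, local_window)
        residuals = values - local.ravel()[picks]
        filled = local[signal] + residuals
        values = np.clip(filled, 0.0, mbi_i)
    out[signal] = values
    return out, n


def _masked_local_mean(plane: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Moving average of ``plane`` over ``valid`` pixels (window x window)."""
    from scipy import ndimage

    v = valid.astype(np.float64)
    num = ndimage.uniform_filter(plane * v, size=window, mode="reflect")
    den = ndimage.uniform_filter(v, size=window, mode="reflect")
    global_mean = plane[valid].mean() if valid.any() else plane.mean()
    with np.errstate(invalid="ignore"):
        local = np.where(den > 1e-12, num / np.maximum(den, 1e-12), global_mean)
    return local


def compute_background_mask(
    signal_free: np.ndarray, mask: TissueMask, cfg: NormalizationConfig
) -> BackgroundMask:
    """Smooth the signal-free plane into the background mask M.

    Non-tissue pixels are filled with the median of tissue pixels so the
    filter sees no media/tissue step; the filter is a separable 2D
    Savitzky-Golay (window = SFS, order = sg_order, rows then columns, with
    least-squares polynomial fits over the terminal windows at the edges so
    ramps are preserved to the boundary).  The result is floored at
    mask_floor to keep the divisor strictly positive.
    """
    plane = np.asarray(signal_free, dtype=np.float64)
    window = cfg.odd_sfs
    if window >= min(plane.shape):
        raise ValueError(
            f"SFS too large for plane: window {window} vs shape {plane.shape}"
        )
    filled = plane.copy()
    tissue = mask.grid
    if tissue.any() and not tissue.all():
        filled[~tissue] = np.median(plane[tissue])
    smoothed = savgol_filter(filled, window, cfg.sg_order, axis=0, mode="interp")
    smoothed = savgol_filter(smoothed, window, cfg.sg_order, axis=1, mode="interp")
    floored = smoothed < cfg.mask_floor
    if floored.any():
        smoothed = np.maximum(smoothed, cfg.mask_floor)
    return BackgroundMask(grid=smoothed, floor_applied=bool(floored.any()))


def normalize_plane(
    plane: np.ndarray, mask_img: BackgroundMask, tissue: TissueMask
) -> tuple[np.ndarray, float]:
    """Correct a plane by division and restore its ADU scale.

    Tissue pixels become I(x)/M(x) * s with s = median of M over tissue, so
    pure background maps back to about its typical level; non-tissue pixels
    pass through untouched.  The result stays real-valued — integer clipping
    happens only at write time, after Z normalization.
    """
    plane = np.asarray(plane, dtype=np.float64)
    m = mask_img.grid
    if np.any(m <= 0):
        raise AssertionError("background mask contains non-positive values")
    if plane.shape != m.shape:
        raise ValueError("plane/mask shape mismatch")
    t = tissue.grid
    if not t.any():
        return plane.copy(), 1.0
    scale = float(np.median(m[t]))
    out = plane.copy()
    out[t] = plane[t] / m[t] * scale
    return out, scale


def _plane_rng(seed: int, plane_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, plane_index])


def effective_uq_rank(q_star: float, records, masks) -> float:
    """Shared upper-quantile rank for Z normalization.

    The MBI rank q* carries the reference plane's signal fraction; on a
    plane richer in signal that rank would land inside the signal range,
    making the background/signal boundary of the quantile profiles a
    content-dependent quantity and destabilizing the supra-quantile
    stretch.  Signal removal has already measured each plane's signal
    fraction, so the shared rank is capped at the smallest per-plane
    background fraction — guaranteed to be background on every plane.
    """
    rank = q_star
    for rec, mask in zip(records, masks):
        if rec.skipped:
            continue
        n_tissue = int(mask.grid.sum())
        if n_tissue == 0:
            continue
        rank = min(rank, 1.0 - rec.n_signal_pixels_replaced / n_tissue)
    return rank


def normalize_plane_xy(
    plane: np.ndarray,
    plane_index: int,
    mbi_i: float,
    tissue_mask: TissueMask,
    cfg: NormalizationConfig,
) -> tuple[np.ndarray, PlaneNormalizationRecord]:
    """XY-normalize one plane (signal removal -> mask -> division)."""
    if not np.isfinite(mbi_i):
        rec = PlaneNormalizationRecord(plane_index, np.nan, np.nan, 0, 1.0, skipped=True)
        return np.asarray(plane, dtype=np.float64).copy(), rec
    rng = _plane_rng(cfg.seed, plane_index)
    signal_free, n_replaced = remove_signal(
        plane, mbi_i, tissue_mask, rng, local_window=cfg.odd_sfs
    )
    bg = compute_background_mask(signal_free, tissue_mask, cfg)
    corrected, scale = normalize_plane(plane, bg, tissue_mask)
    rank = float(np.mean(np.asarray(plane, dtype=np.float64)[tissue_mask.grid] <= mbi_i)) if tissue_mask.grid.any() else np.nan
    rec = PlaneNormalizationRecord(plane_index, float(mbi_i), rank, n_replaced, scale)
    return corrected, rec


def normalize_stack_xy(
    stack: ImageStack,
    cfg: NormalizationConfig,
    masks: Sequence[TissueMask] | None = None,
    plane_order: Sequence[int] | None = None,
):
    """XY-normalize every plane of a stack.

    Returns (corrected real-valued planes, per-plane records, quantile
    profiles, tissue masks).  Planes are processed independently with RNG
    substreams keyed by (seed, plane index), so any ``plane_order`` — and any
    parallel schedule — yields bit-identical results.
    """
    from . import z_normalizer  # profiles are defined with the Z machinery

    if masks is None:
        if cfg.tissue.method == "none":
            masks = [TissueMask(np.ones(p.shape, bool)) for p in stack.planes]
        else:
            tcfg = cfg.tissue
            if tcfg.dilation_radius is None:
                tcfg = replace(tcfg, dilation_radius=max(1, cfg.odd_sfs // 4))
            masks = [detect_tissue(p, tcfg) for p in stack.planes]

    mbi, q_star = propagate_mbi(stack, masks, cfg)

    corrected: list[np.ndarray | None] = [None] * stack.z_count
    records: list[PlaneNormalizationRecord | None] = [None] * stack.z_count
    order = list(plane_order) if plane_order is not None else list(range(stack.z_count))
    for i in order:
        corrected[i], records[i] = normalize_plane_xy(
            stack.planes[i], i, mbi[i], masks[i], cfg
        )
    uq_rank = effective_uq_rank(q_star, records, masks)
    profiles = z_normalizer.build_profiles(
        corrected, masks, cfg, uq_rank, skip=[r.skipped for r in records]
    )
    return corrected, records, profiles, masks
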