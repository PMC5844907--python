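"""Cross-plane (Z) harmonization of corrected stacks.

After XY normalization each plane is internally uniform but plane-to-plane
brightness still varies (depth-dependent excitation/detection loss, light
sheet attenuation).  Because axial resolution and Z step are arbitrary, each
plane is treated as an independent sample and harmonized through its
intensity quantiles.  Per plane, 10,000 quantiles of the tissue pixels are
recorded (at ranks k/(Q+1)) — a compact sufficient statistic that avoids
holding the stack in memory — and one shared target is built by averaging
profiles across planes.  Three modes:

- upper_quantile: multiply each plane so its MBI-rank quantile matches the
  stack target (pure histogram shift; spread untouched);
- contrast_stretch: affine map sending the 10th-percentile and upper
  quantile to the stack targets (corrects spread as well);
- semi_quantile: full quantile matching below the upper quantile — the
  background — with the supra-quantile (signal) range following the
  contrast-stretch affine law anchored at the upper quantile; the two
  pieces meet continuously there.

All maps are monotone nondecreasing, so within-plane pixel ranks are never
inverted.  Non-tissue pixels are untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("intensify3d")


@dataclass
class QuantileProfile:
    """Per-plane quantile summary of the corrected tissue pixels."""

    plane_index: int
    quantiles: np.ndarray  # values at ranks k/(Q+1), k = 1..Q
    uq_rank: float  # shared MBI quantile rank q*
    uq_value: float
    lq_value: float
    max_value: float


@dataclass
class ZTarget:
    mode: str
    target_uq: float
    target_lq: float
    target_max: float
    target_quantiles: np.ndarray | None = None


def quantile_ranks(quantile_count: int) -> np.ndarray:
    """Rank grid k/(Q+1), k = 1..Q — avoids the 0/1 ranks hitting extremes."""
    q = quantile_count
    return np.arange(1, q + 1, dtype=np.float64) / (q + 1)


def build_profiles(
    corrected_planes: Sequence[np.ndarray],
    masks,
    cfg,
    uq_rank: float,
    skip: Sequence[bool] | None = None,
) -> list[QuantileProfile | None]:
    """Record quantile profiles of corrected planes (tissue pixels only).

    Skipped planes (no tissue) get ``None`` and are excluded from targets.
    """
    ranks = quantile_ranks(cfg.quantile_count)
    profiles: list[QuantileProfile | None] = []
    for i, plane in enumerate(corrected_planes):
        if skip is not None and skip[i]:
            profiles.append(None)
            continue
        vals = np.asarray(plane, dtype=np.float64)[masks[i].grid]
        if vals.size == 0:
            profiles.append(None)
            continue
        # one sort per plane; interpolated order statistics at all ranks
        svals = np.sort(vals)
        positions = np.arange(svals.size, dtype=np.float64)
        qs = np.interp(ranks * (svals.size - 1), positions, svals)
        uq, lq = np.interp(
            np.array([uq_rank, cfg.lower_quantile_rank]) * (svals.size - 1),
            positions,
            svals,
        )
        profiles.append(
            QuantileProfile(
                plane_index=i,
                quantiles=qs,
                uq_rank=uq_rank,
                uq_value=float(uq),
                lq_value=float(lq),
                max_value=float(svals[-1]),
            )
        )
    return profiles


def build_target(profiles: Sequence[QuantileProfile | None], mode: str) -> ZTarget:
    """Average the per-plane profiles into one cross-stack target."""
    live = [p for p in profiles if p is not None]
    if not live:
        raise ValueError("no usable quantile profiles")
    target = ZTarget(
        mode=mode,
        target_uq=float(np.mean([p.uq_value for p in live])),
        target_lq=float(np.mean([p.lq_value for p in live])),
        target_max=float(np.mean([p.max_value for p in live])),
    )
    if mode == "semi_quantile":
        target.target_quantiles = np.mean([p.quantiles for p in live], axis=0)
    return target


def apply_upper_quantile(
    plane: np.ndarray, profile: QuantileProfile, target: ZTarget, tissue: np.ndarray
) -> np.ndarray:
    """Multiply tissue pixels so the plane's upper quantile hits the target."""
    out = np.asarray(plane, dtype=np.float64).copy()
    if profile.uq_value == 0:
        logger.warning("plane %d: upper quantile is 0; skipped", profile.plane_index)
        return out
    out[tissue] = out[tissue] * (target.target_uq / profile.uq_value)
    return out


def apply_contrast_stretch(
    plane: np.ndarray, profile: QuantileProfile, target: ZTarget, tissue: np.ndarray
) -> np.ndarray:
    """Affine map sending (lq, uq) -> (target_lq, target_uq); floor at 0.

    Applied to all tissue pixels, extrapolating outside the anchor interval.
    Degenerate spread (uq == lq) falls back to the upper-quantile shift.
    """
    if profile.uq_value == profile.lq_value:
        logger.warning(
            "plane %d: zero quantile spread; falling back to upper-quantile mode",
            profile.plane_index,
        )
        return apply_upper_quantile(plane, profile, target, tissue)
    out = np.asarray(plane, dtype=np.float64).copy()
    slope = (target.target_uq - target.target_lq) / (profile.uq_value - profile.lq_value)
    out[tissue] = target.target_lq + (out[tissue] - profile.lq_value) * slope
    np.maximum(out, 0.0, where=tissue, out=out)
    return out


def apply_semi_quantile(
    plane: np.ndarray, profile: QuantileProfile, target: ZTarget, tissue: np.ndarray
) -> np.ndarray:
    """Quantile-match the background; contrast-stretch the signal range.

    Tissue pixels at or below the plane's upper quantile follow the monotone
    piecewise-linear map from the plane's sub-UQ quantiles to the target's;
    pixels above follow the contrast-stretch law, the affine map with slope
    (target_uq - target_lq) / (uq - lq), anchored at the upper quantile.
    Both branches send uq_value to target_uq, so the full map is continuous.
    (Anchoring the upper branch at the plane maximum instead would tie the
    signal range to a single extreme voxel and blow the supra-UQ background
    tail of signal-poor planes out to the stack-wide maximum; the
    background-spread slope is stable and preserves restored signal levels.)
    """
    if target.target_quantiles is None:
        raise ValueError("target lacks quantile vector for semi-quantile mode")
    out = np.asarray(plane, dtype=np.float64).copy()
    ranks = quantile_ranks(len(profile.quantiles))
    sub = ranks <= profile.uq_rank
    xp = np.append(profile.quantiles[sub], profile.uq_value)
    fp = np.append(target.target_quantiles[sub], target.target_uq)
    # enforce nondecreasing knots (fp is a mean of nondecreasing vectors; the
    # appended junction can only tie, never invert)
    low = tissue & (out <= profile.uq_value)
    high = tissue & (out > profile.uq_value)
    if low.any():
        mapped = np.interp(out[low], xp, fp)
        # below the first knot, extrapolate with the contrast-stretch slope
        # (clamping would pile the deep tail onto one value, and the first
        # segment's own slope is an extreme-tail spacing ratio — noise)
        below = out[low] < xp[0]
        if below.any():
            if profile.uq_value > profile.lq_value:
                slope0 = (target.target_uq - target.target_lq) / (
                    profile.uq_value - profile.lq_value
                )
            else:
                slope0 = 1.0
            mapped[below] = np.maximum(fp[0] + (out[low][below] - xp[0]) * slope0, 0.0)
        out[low] = mapped
    if high.any():
        if profile.uq_value > profile.lq_value:
            slope = (target.target_uq - target.target_lq) / (
                profile.uq_value - profile.lq_value
            )
        else:
            slope = 1.0  # degenerate spread: pure shift above the junction
        out[high] = target.target_uq + (out[high] - profile.uq_value) * slope
    return out


_MODE_FUNCS = {
    "upper_quantile": apply_upper_quantile,
    "contrast_stretch": apply_contrast_stretch,
    "semi_quantile": apply_semi_quantile,
}


def normalize_stack_z(
    corrected_planes: Sequence[np.ndarray],
    profiles: Sequence[QuantileProfile | None],
    cfg,
    masks,
) -> tuple[list[np.ndarray], ZTarget | None]:
    """Apply the configured Z mode plane-by-plane against one shared target."""
    if cfg.z_mode == "none":
        return [np.asarray(p, dtype=np.float64).copy() for p in corrected_planes], None
    func = _MODE_FUNCS[cfg.z_mode]
    target = build_target(profiles, cfg.z_mode)
    out = []
    for plane, profile, mask in zip(corrected_planes, profiles, masks):
        if profile is None:
            out.append(np.asarray(plane, dtype=np.float64).copy())
            continue
        out.append(func(plane, profile, target, mask.grid))
    return out, target
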