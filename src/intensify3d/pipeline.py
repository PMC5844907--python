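"""End-to-end normalization runs: read, correct, write, and log.

Ties the modules together behind one call: tissue detection (optional),
MBI propagation, per-plane XY normalization, Z harmonization, and output of
the corrected series plus support images, the per-plane quantile log, the
per-plane record table, and a JSON run manifest sufficient to re-run the
correction bit-identically.  Plane-level work can run on a process pool;
per-plane RNG substreams keyed by (seed, plane index) make the result
independent of scheduling, so the worker count is purely a speed knob.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import __version__
from .stack_io import ImageStack, write_quantile_log, write_stack, write_support_masks
from .tissue_detector import TissueMask, detect_tissue
from .xy_normalizer import (
    NormalizationConfig,
    effective_uq_rank,
    normalize_plane_xy,
    propagate_mbi,
)
from . import z_normalizer

logger = logging.getLogger("intensify3d")


def _xy_worker(args):
    plane, index, mbi_i, mask, cfg = args
    corrected, record = normalize_plane_xy(plane, index, mbi_i, mask, cfg)
    return index, corrected, record


def normalize_stack(stack: ImageStack, cfg: NormalizationConfig, workers: int = 1):
    """Full in-memory normalization (XY then Z) of a stack.

    Returns (final real-valued planes, records, profiles, masks, z-target).
    """
    if cfg.tissue.method == "none":
        masks = [TissueMask(np.ones(p.shape, bool)) for p in stack.planes]
    else:
        tcfg = cfg.tissue
        if tcfg.dilation_radius is None:
            tcfg = replace(tcfg, dilation_radius=max(1, cfg.odd_sfs // 4))
        masks = [detect_tissue(p, tcfg) for p in stack.planes]

    mbi, q_star = propagate_mbi(stack, masks, cfg)

    jobs = [(stack.planes[i], i, mbi[i], masks[i], cfg) for i in range(stack.z_count)]
    corrected: list[np.ndarray | None] = [None] * stack.z_count
    records = [None] * stack.z_count
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            for index, plane, record in pool.map(_xy_worker, jobs):
                corrected[index] = plane
                records[index] = record
    else:
        for job in jobs:
            index, plane, record = _xy_worker(job)
            corrected[index] = plane
            records[index] = record

    skip = [r.skipped for r in records]
    uq_rank = effective_uq_rank(q_star, records, masks)
    profiles = z_normalizer.build_profiles(corrected, masks, cfg, uq_rank, skip=skip)
    final, target = z_normalizer.normalize_stack_z(corrected, profiles, cfg, masks)
    return final, records, profiles, masks, target


def run_normalize(
    input_dir: str | Path,
    output_dir: str | Path,
    cfg: NormalizationConfig,
    workers: int = 1,
    pattern: str = "*.tif*",
    stack: ImageStack | None = None,
) -> dict:
    """Normalize a TIFF series folder and write all outputs + manifest."""
    from .stack_io import read_stack

    t0 = time.perf_counter()
    output_dir = Path(output_dir)
    if stack is None:
        stack = read_stack(input_dir, pattern)
    final, records, profiles, masks, _target = normalize_stack(stack, cfg, workers)

    out_stack = ImageStack(
        planes=final, bit_depth=stack.bit_depth, source_names=list(stack.source_names)
    )
    written = write_stack(out_stack, output_dir / "normalized", suffix="_norm")
    write_support_masks(
        [m.grid for m in masks], output_dir / "support", names=stack.source_names
    )
    log_rows = [
        (stack.source_names[p.plane_index], records[p.plane_index].mbi_i, p.uq_rank, p.quantiles)
        for p in profiles
        if p is not None
    ]
    write_quantile_log(log_rows, output_dir)

    rec_path = output_dir / "plane_records.tsv"
    with open(rec_path, "w") as fh:
        fh.write("plane\tmbi\tmbi_quantile_rank\tn_signal_pixels_replaced\tstandardization_scale\tskipped\n")
        for name, r in zip(stack.source_names, records):
            fh.write(
                f"{name}\t{r.mbi_i:.6g}\t{r.mbi_quantile_rank:.8g}\t"
                f"{r.n_signal_pixels_replaced}\t{r.standardization_scale:.8g}\t{int(r.skipped)}\n"
            )

    warnings = [
        f"plane {r.plane_index} skipped (no tissue)" for r in records if r.skipped
    ]
    if cfg.sfs % 2 == 0:
        warnings.append(f"SFS {cfg.sfs} coerced to {cfg.sfs + 1}")
    manifest = {
        "tool": "intensify3d",
        "version": __version__,
        "input_dir": str(input_dir),
        "output_dir": str(output_dir),
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "workers": workers,
        "n_planes": stack.z_count,
        "n_written": len(written),
        "warnings": warnings,
        "timings": {"total_s": round(time.perf_counter() - t0, 3)},
    }
    with open(output_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _config_dict(cfg: NormalizationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
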