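"""Per-B-scan fluid segmentation pipeline and 3D aggregation.

One B-scan is processed as: proposed NS transform -> ILM / flattened-RPE
segmentation on the membership plane -> automated seed initialization
(conventional NS transform + k-means) -> kernel graph-cut minimization ->
post-filtering (discard fluid outside the ILM..flattened-RPE band and
components smaller than ``min_region_px``).  Fluid-free scans come out empty:
their fluid seeds land in the dark background, which the band clip removes.

Volumes are ordered stacks of B-scans; the fluid volume is the voxel count
times the voxel size, and the largest 26-connected 3D component is reported
separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from ._exceptions import InvalidInputError
from .config import PipelineConfig
from .graphcut import build_and_cut
from .io import validate_gray
from .layers import BoundaryCurve, segment_layers
from .ns import FilterBank, NSImage, build_filter_bank, to_ns_proposed
from .seeds import SeedSet, init_seeds

__all__ = ["BScanResult", "VolumeResult", "segment_bscan", "postprocess",
           "segment_volume"]


@dataclass
class BScanResult:
    """Mask plus the intermediates of one B-scan segmentation."""

    mask: np.ndarray
    ilm: BoundaryCurve
    rpe_flat: BoundaryCurve
    seeds: SeedSet
    ns: NSImage = None
    raw_mask: np.ndarray = None

    @property
    def fluid_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class VolumeResult:
    masks: list = field(default_factory=list)
    results: list = field(default_factory=list)
    fluid_voxels: int = 0
    fluid_volume_mm3: float = 0.0
    largest_component_voxels: int = 0
    per_slice_stats: list = field(default_factory=list)


def postprocess(mask: np.ndarray, ilm: BoundaryCurve, rpe_flat: BoundaryCurve,
                min_region_px: int) -> np.ndarray:
    """Clip fluid to the ILM..flattened-RPE band and drop small components.

    Pixels above the ILM or below the flattened RPE are zeroed; 8-connected
    components with area strictly below ``min_region_px`` are removed.
    """
    mask = np.asarray(mask).astype(bool)
    n_rows, n_cols = mask.shape
    if ilm.n_cols != n_cols or rpe_flat.n_cols != n_cols:
        raise InvalidInputError("layer curves must cover the mask width")
    rows = np.arange(n_rows)[:, None]
    band = (rows >= ilm.rows[None, :]) & (rows <= rpe_flat.rows[None, :])
    clipped = mask & band
    if min_region_px > 0 and clipped.any():
        labels, n_comp = ndimage.label(clipped, structure=np.ones((3, 3), dtype=int))
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_region_px)
        clipped[np.isin(labels, small[small > 0])] = False
    return clipped.astype(np.uint8)


def segment_bscan(g: np.ndarray, cfg: PipelineConfig | None = None,
                  rng_seed: int | None = None,
                  bank: FilterBank | None = None,
                  keep_intermediates: bool = True) -> BScanResult:
    """Run the full fluid segmentation on one B-scan."""
    cfg = cfg or PipelineConfig()
    g = validate_gray(g)
    seed_params = cfg.seeds if rng_seed is None else replace(cfg.seeds, rng_seed=rng_seed)

    ns = to_ns_proposed(g, bank or build_filter_bank(), cfg.ns)
    ilm, rpe_flat = segment_layers(ns, cfg.layers)
    seeds = init_seeds(g, ilm, rpe_flat, seed_params, cfg.ns)
    raw = build_and_cut(ns.T, ns.I, seeds, cfg.energy)
    mask = postprocess(raw, ilm, rpe_flat, cfg.min_region_px)
    return BScanResult(mask=mask, ilm=ilm, rpe_flat=rpe_flat, seeds=seeds,
                       ns=ns if keep_intermediates else None,
                       raw_mask=raw if keep_intermediates else None)


def segment_volume(slices, cfg: PipelineConfig | None = None,
                   rng_seed: int | None = None,
                   truths=None) -> VolumeResult:
    """Segment an ordered stack of B-scans and report the fluid volume."""
    cfg = cfg or PipelineConfig()
    slices = list(slices)
    if not slices:
        raise InvalidInputError("a volume needs at least one slice")
    shapes = {np.asarray(s).shape for s in slices}
    if len(shapes) != 1:
        raise InvalidInputError(f"inconsistent slice shapes: {sorted(shapes)}")
    if truths is not None and len(truths) != len(slices):
        raise InvalidInputError("one truth mask per slice required")

    bank = build_filter_bank()
    vol = VolumeResult()
    for i, s in enumerate(slices):
        res = segment_bscan(s, cfg, rng_seed=rng_seed, bank=bank,
                            keep_intermediates=False)
        vol.masks.append(res.mask)
        vol.results.append(res)
        stats = {"slice": i, "fluid_px": res.fluid_px}
        if truths is not None:
            from .metrics import evaluate_mask
            stats["dice"] = evaluate_mask(res.mask, truths[i]).dice
        vol.per_slice_stats.append(stats)

    stack = np.stack([m.astype(bool) for m in vol.masks])
    vol.fluid_voxels = int(stack.sum())
    voxel_mm3 = cfg.px_height_mm * cfg.px_width_mm * cfg.slice_spacing_mm
    vol.fluid_volume_mm3 = vol.fluid_voxels * voxel_mm3
    if vol.fluid_voxels:
        labels, _ = ndimage.label(stack, structure=np.ones((3, 3, 3), dtype=int))
        areas = np.bincount(labels.ravel())
        vol.largest_component_voxels = int(areas[1:].max())
    return vol
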