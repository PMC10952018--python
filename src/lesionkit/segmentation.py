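"""Hypermetabolic lesion segmentation from SUV volumes.

The standard FDG-PET delineation recipe: threshold the volume at a fixed
fraction of SUVmax (41% by default), split the foreground into connected
components (flood fill), drop sub-voxel specks, and fill interior cavities so
every lesion is a closed solid ready for meshing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, LabeledMask, SUVVolume

__all__ = [
    "SegmentationConfig",
    "threshold_segment",
    "label_components",
    "fill_holes",
    "segment_lesions",
]

log = logging.getLogger(__name__)

#: scipy binary structures for the three standard 3D adjacencies
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class SegmentationConfig:
    """Parameters of the segmentation chain.

    fraction: threshold as a fraction of SUVmax (default 0.41).
    reference: 'global' thresholds at fraction * volume-wide SUVmax;
        'per_lesion' re-grows each component at fraction * its own SUVmax.
    connectivity: foreground adjacency (6, 18 or 26). Cavity detection always
        uses the dual background connectivity 6.
    min_voxels: components smaller than this are discarded as noise specks.
    """

    fraction: float = 0.41
    reference: str = "global"
    connectivity: int = 26
    min_voxels: int = 2

    def __post_init__(self):
        if not 0 < self.fraction < 1:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction}")
        if self.reference not in ("global", "per_lesion"):
            raise ValueError(f"reference must be 'global' or 'per_lesion', got {self.reference!r}")
        if self.connectivity not in _STRUCTS:
            raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")


def _relabel_by_first_voxel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K in order of first appearance in a C-order scan."""
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    if nz.size == 0:
        return labels
    order = flat[nz]
    # first occurrence index of each label value, then rank those positions
    uniq, first = np.unique(order, return_index=True)
    rank = np.empty(uniq.max() + 1, dtype=labels.dtype)
    rank[uniq[np.argsort(first)]] = np.arange(1, uniq.size + 1)
    out = labels.copy()
    out[labels > 0] = rank[labels[labels > 0]]
    return out


def threshold_segment(
    volume: SUVVolume, fraction: float = 0.41, reference: str = "global", connectivity: int = 26
) -> BinaryMask:
    """Binarize an SUV volume at ``fraction`` of SUVmax (strict ``>``).

    In 'global' mode the threshold is fraction * volume-wide SUVmax. In
    'per_lesion' mode a global pass finds candidate components first; each is
    then re-grown as the connected region of ``SUV > fraction * component
    SUVmax`` containing it, so lesions fainter than the hottest one are
    delineated against their own peak.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    suvmax = volume.suvmax
    if suvmax <= 0:
        raise ValueError("cannot threshold an all-zero volume: SUVmax = 0 makes the threshold degenerate")
    global_mask = volume.values > fraction * suvmax
    if reference == "global":
        return BinaryMask(values=global_mask, spacing=volume.spacing, origin=volume.origin)
    if reference != "per_lesion":
        raise ValueError(f"unknown reference {reference!r}")

    struct = _STRUCTS[connectivity]
    seeds, n = ndimage.label(global_mask, structure=struct)
    out = np.zeros_like(global_mask)
    for k in range(1, n + 1):
        comp = seeds == k
        comp_max = float(volume.values[comp].max())
        regrown = volume.values > fraction * comp_max
        grown_labels, _ = ndimage.label(regrown, structure=struct)
        hit = np.unique(grown_labels[comp])
        out |= np.isin(grown_labels, hit[hit > 0])
    return BinaryMask(values=out, spacing=volume.spacing, origin=volume.origin)


def label_components(mask: BinaryMask, connectivity: int = 26) -> LabeledMask:
    """Flood-fill connected-component labeling of the foreground.

    Labels are assigned 1..K in ascending order of each component's first
    voxel in a lexicographic (C-order) scan, so the output is deterministic.
    """
    struct = _STRUCTS[connectivity]
    labels, _ = ndimage.label(mask.values, structure=struct)
    labels = _relabel_by_first_voxel(labels.astype(np.int32))
    return LabeledMask(values=labels, spacing=mask.spacing, origin=mask.origin)


def fill_holes(mask: LabeledMask, background_connectivity: int = 6) -> LabeledMask:
    """Fill interior cavities of each labeled component.

    A cavity is a background region not reachable from the grid boundary
    through background under the (dual) background connectivity. Each cavity
    is assigned the label owning the majority of its adjacent foreground
    voxels; ties go to the lower label, with a warning when a cavity touches
    several labels.
    """
    labels = mask.values
    bg = labels == 0
    struct = _STRUCTS[background_connectivity]
    bg_labels, n_bg = ndimage.label(bg, structure=struct)
    if n_bg == 0:
        return LabeledMask(values=labels.copy(), spacing=mask.spacing, origin=mask.origin)

    # background components touching any face of the array are exterior
    border = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, -1):
            sl[ax] = idx
            border[tuple(sl)] = True
    exterior = np.unique(bg_labels[border & bg])
    exterior = set(int(e) for e in exterior if e > 0)

    out = labels.copy()
    for k in range(1, n_bg + 1):
        if k in exterior:
            continue
        cavity = bg_labels == k
        # foreground voxels adjacent to the cavity decide ownership
        halo = ndimage.binary_dilation(cavity, structure=struct) & (labels > 0)
        owners, counts = np.unique(out[halo], return_counts=True)
        if owners.size == 0:  # isolated background pocket inside another cavity
            continue
        if owners.size > 1:
            warnings.warn(
                f"cavity of {int(cavity.sum())} voxels touches labels {owners.tolist()}; "
                "assigned by majority vote",
                stacklevel=2,
            )
        winner = owners[counts == counts.max()].min()  # tie -> lower label
        out[cavity] = winner
    return LabeledMask(values=out, spacing=mask.spacing, origin=mask.origin)


def _filter_small(labels: np.ndarray, min_voxels: int) -> np.ndarray:
    if min_voxels <= 1:
        return labels
    keep = labels.copy()
    counts = np.bincount(labels.ravel())
    for k in np.nonzero(counts[1:] < min_voxels)[0] + 1:
        keep[labels == k] = 0
    return _relabel_by_first_voxel(keep)


def segment_lesions(volume: SUVVolume, config: SegmentationConfig | None = None) -> LabeledMask:
    """Full chain: threshold -> label -> minimum-size filter -> fill holes."""
    cfg = config or SegmentationConfig()
    mask = threshold_segment(volume, cfg.fraction, cfg.reference, cfg.connectivity)
    labeled = label_components(mask, cfg.connectivity)
    filtered = _filter_small(labeled.values, cfg.min_voxels)
    labeled = replace(labeled, values=filtered)
    filled = fill_holes(labeled)
    if filled.n_labels == 0:
        warnings.warn("no lesion components survive thresholding and size filtering", stacklevel=2)
    for k in filled.labels:
        comp = filled.values == k
        log.info(
            "lesion %d: %d voxels, SUVmax %.3f",
            k,
            int(comp.sum()),
            float(volume.values[comp].max()),
        )
    return filled
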