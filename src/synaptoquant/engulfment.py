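"""Microglial reconstruction and engulfed-synapse counting.

A microglial volume is reconstructed from its marker channel (Iba1-like) by
intensity thresholding, with fully enclosed cavities filled by default so
that phagocytosed material inside unevenly stained cytoplasm still counts as
"inside".  Engulfment is then read as centroid-in-mask: among the synapse
(Syp) centroids that carry a C1q tag, how many sit inside the microglia, and
what fraction of those also carry NP signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import INTENSITY_MAX, BinaryMask, SpotSet, VoxelGrid

__all__ = ["EngulfmentResult", "segment_mask", "count_engulfed", "threshold_sweep"]


@dataclass
class EngulfmentResult:
    """Counts of C1q-tagged synaptic centroids inside the microglial mask."""

    n_tagged_inside: int
    n_tagged_inside_with_NP: int

    @property
    def fraction_NP_positive(self) -> float:
        if self.n_tagged_inside == 0:
            return float("nan")
        return self.n_tagged_inside_with_NP / self.n_tagged_inside


def segment_mask(
    grid: VoxelGrid,
    threshold: float,
    fill_cavities: bool = True,
    largest_component_only: bool = False,
) -> BinaryMask:
    """Threshold the marker channel into a binary microglial volume.

    Voxels with intensity >= threshold are inside; fully enclosed cavities
    are filled by default; optionally only the largest connected component
    is kept.
    """
    if not 0 <= threshold <= INTENSITY_MAX:
        raise ValueError("threshold must lie within [0, 65535]")
    mask = grid.data >= threshold
    if fill_cavities and mask.any():
        mask = ndimage.binary_fill_holes(mask)
    if largest_component_only and mask.any():
        lab, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return BinaryMask(
        data=mask, voxel_size_nm=grid.voxel_size_nm, source_threshold=threshold
    )


def count_engulfed(
    syp_tagged: SpotSet,
    np_positive: np.ndarray,
    mask: BinaryMask,
) -> EngulfmentResult:
    """Count tagged centroids inside the mask, split by NP positivity.

    ``syp_tagged`` holds the C1q-colocalized Syp centroids (flags computed
    upstream by the colocalization module); ``np_positive`` is the per-spot
    boolean NP-colocalization flag.  A centroid is inside iff the voxel
    containing it is mask-true.
    """
    np_positive = np.asarray(np_positive, dtype=bool).reshape(len(syp_tagged))
    inside = mask.contains(syp_tagged.coords_nm)
    return EngulfmentResult(
        n_tagged_inside=int(inside.sum()),
        n_tagged_inside_with_NP=int((inside & np_positive).sum()),
    )


def threshold_sweep(
    grid: VoxelGrid,
    syp_tagged: SpotSet,
    np_positive: np.ndarray,
    thresholds: np.ndarray,
    fill_cavities: bool = True,
) -> list[tuple[float, EngulfmentResult]]:
    """Sensitivity of the engulfment readout to the mask threshold.

    The marker-channel segmentation threshold is a required analysis choice;
    this sweep reports the NP-positive fraction at each candidate threshold
    so its influence can be audited.
    """
    out = []
    for t in np.asarray(thresholds, dtype=float):
        m = segment_mask(grid, float(t), fill_cavities=fill_cavities)
        out.append((float(t), count_engulfed(syp_tagged, np_positive, m)))
    return out
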