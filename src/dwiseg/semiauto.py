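"""Semi-automatic baseline: gray-level threshold + largest connected region.

The baseline mimics how a reader would segment a hyperintense tumor on a
high-b-value DWI volume in three steps: (1) manually pick a lower gray-level
bound known to lie inside the tumor, (2) keep every voxel at or above that
bound, (3) keep only the largest 3D connected region of the result.  It
rests on the assumption that the tumor is the largest bright connected
structure in the volume; when an adjacent bright structure is larger, the
method latches onto it and fails — a failure mode the phantom module can
reproduce on demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .volume_io import ImageVolume, LabelVolume

__all__ = [
    "EmptyMaskError",
    "ThresholdSpec",
    "threshold_mask",
    "largest_component",
    "semiauto_segment",
]

#: skimage `connectivity` (orthogonal steps allowed) per 3D neighborhood.
_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


class EmptyMaskError(ValueError):
    """An operation that needs foreground received an empty mask."""


@dataclass(frozen=True)
class ThresholdSpec:
    """Manually chosen lower gray-level bound plus neighborhood system."""

    t_min: float
    connectivity: int = 26

    def __post_init__(self):
        if self.connectivity not in _CONNECTIVITY:
            raise ValueError(
                f"connectivity must be one of {sorted(_CONNECTIVITY)}, "
                f"got {self.connectivity}"
            )


def threshold_mask(vol: ImageVolume, t_min: float) -> LabelVolume:
    """Voxels with gray value >= t_min (inclusive lower bound)."""
    fg = (vol.voxels >= t_min).astype(np.uint8)
    return LabelVolume(fg, spacing=vol.spacing, origin=vol.origin)


def largest_component(mask: LabelVolume, connectivity: int = 26) -> LabelVolume:
    """Largest connected region of a binary mask under 6/18/26-connectivity.

    Ties in component size are broken deterministically in favor of the
    component containing the smallest linearized (C-order) voxel index.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(
            f"connectivity must be one of {sorted(_CONNECTIVITY)}, "
            f"got {connectivity}"
        )
    grid = mask.voxels.astype(bool)
    if not grid.any():
        raise EmptyMaskError("largest_component needs >= 1 foreground voxel")
    labels = measure.label(grid, connectivity=_CONNECTIVITY[connectivity])
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0  # background
    best = sizes.max()
    tied = np.flatnonzero(sizes == best)
    if len(tied) == 1:
        winner = tied[0]
    else:
        flat = labels.ravel()
        winner = flat[np.flatnonzero(np.isin(flat, tied))[0]]
    out = (labels == winner).astype(np.uint8)
    return LabelVolume(out, spacing=mask.spacing, origin=mask.origin)


def semiauto_segment(vol: ImageVolume, spec: ThresholdSpec) -> LabelVolume:
    """Threshold at spec.t_min, then keep the largest connected region."""
    mask = threshold_mask(vol, spec.t_min)
    if mask.foreground_count == 0:
        raise EmptyMaskError(
            f"threshold {spec.t_min} leaves no foreground voxel"
        )
    return largest_component(mask, spec.connectivity)
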