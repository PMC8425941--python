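"""Volume containers, NIfTI I/O, and spatial/intensity preprocessing.

The package works on 3D scalar grids. Three thin containers distinguish the
roles a grid can play:

``ImageVolume``
    gray values (diffusion-weighted signal; scanner-arbitrary units),
``LabelVolume``
    a binary tumor mask on the same lattice,
``ProbabilityVolume``
    a per-voxel probability map in [0, 1], the network output.

All grids carry voxel spacing in mm and the physical origin of voxel
(0, 0, 0).  Voxel indices are 0-based throughout; physical (mm) coordinates
are only used where a metric explicitly asks for them.  Volumes are kept in
the stored voxel lattice — no reorientation to a canonical anatomical frame
is applied unless explicitly requested at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "FormatError",
    "ShapeError",
    "ImageVolume",
    "LabelVolume",
    "ProbabilityVolume",
    "read_volume",
    "write_volume",
    "crop_or_pad",
    "normalize",
]


class FormatError(ValueError):
    """A file or array violates the expected volume format."""


class ShapeError(ValueError):
    """Two grids that must share a lattice do not, or a shape is invalid."""


def _check_lattice(shape, spacing):
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ShapeError(f"shape must be three positive integers, got {shape}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ShapeError(f"spacing must be three positive reals, got {spacing}")
    return shape, spacing


@dataclass
class ImageVolume:
    """3D scalar grid of gray values with voxel spacing (mm) and origin."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ShapeError(
                f"expected a 3D grid, got {self.voxels.ndim} dimensions"
            )
        _, self.spacing = _check_lattice(self.voxels.shape, self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_lattice(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing
        )


@dataclass
class LabelVolume(ImageVolume):
    """Binary mask on an image lattice; values strictly in {0, 1}."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))]
            raise FormatError(
                f"label volume contains non-binary values {bad[:5].tolist()}"
            )
        self.voxels = self.voxels.astype(np.uint8)

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class ProbabilityVolume(ImageVolume):
    """Per-voxel probabilities in [0, 1] (network output)."""

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(np.float32)
        lo, hi = float(self.voxels.min()), float(self.voxels.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise FormatError(
                f"probability volume has values outside [0,1]: [{lo}, {hi}]"
            )
        np.clip(self.voxels, 0.0, 1.0, out=self.voxels)


def _affine_from(spacing, origin):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(
    path, kind: str = "image", canonical: bool = False
) -> ImageVolume | LabelVolume | ProbabilityVolume:
    """Read a 3D NIfTI file into the container named by *kind*.

    Parameters
    ----------
    path : str or Path
        A readable ``.nii`` / ``.nii.gz`` file.
    kind : {"image", "label", "probability"}
        Which container to build.  ``"label"`` additionally validates that
        the stored values are strictly binary.
    canonical : bool
        If True, reorient to RAS (closest canonical) axes before wrapping.
        Off by default: processing happens on the acquisition lattice.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if canonical:
        img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(
            f"{path.name}: expected a 3D image, got {data.ndim} dimensions"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    cls = {"image": ImageVolume, "label": LabelVolume,
           "probability": ProbabilityVolume}
    if kind not in cls:
        raise ValueError(f"kind must be one of {sorted(cls)}, got {kind!r}")
    return cls[kind](data, spacing=spacing, origin=origin)


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1, encoding spacing/origin in the affine."""
    path = Path(path)
    data = vol.voxels
    if isinstance(vol, LabelVolume):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _crop_pad_slices(n_in: int, n_out: int) -> tuple[slice, slice]:
    """Per-axis source/destination slices for a centered crop or pad.

    When the margin is odd the extra voxel is taken from / added to the
    high-index side, so the low-side margin is floor(margin / 2).
    """
    if n_out <= n_in:  # crop
        lo = (n_in - n_out) // 2
        return slice(lo, lo + n_out), slice(0, n_out)
    lo = (n_out - n_in) // 2  # pad
    return slice(0, n_in), slice(lo, lo + n_in)


def crop_or_pad(vol, target_shape, fill: float = 0.0):
    """Center-crop and/or zero-pad a volume to ``target_shape``.

    Each axis is handled independently; content is centered and, for odd
    margins, the extra voxel is removed from (or added to) the high-index
    side.  Padding voxels take the value ``fill``.  The container type is
    preserved (a mask stays a mask).
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t <= 0 for t in target_shape):
        raise ShapeError(f"target_shape must be 3 positive ints: {target_shape}")
    src = vol.voxels
    pairs = [_crop_pad_slices(s, t) for s, t in zip(src.shape, target_shape)]
    out = np.full(target_shape, fill, dtype=src.dtype)
    out[tuple(d for _, d in pairs)] = src[tuple(s for s, _ in pairs)]
    return replace(vol, voxels=out)


def normalize(vol: ImageVolume, method: str = "zscore") -> ImageVolume:
    """Intensity-normalize an image volume.

    ``zscore`` maps to zero mean / unit standard deviation (a constant
    volume maps to all zeros); ``minmax`` maps the value range to [0, 1]
    (constant input again maps to zeros); ``none`` is the identity.  DWI
    gray values are scanner-arbitrary, so per-volume z-scoring is the
    default network input convention.
    """
    v = vol.voxels.astype(np.float64)
    if method == "none":
        return replace(vol, voxels=vol.voxels.copy())
    if method == "zscore":
        sd = v.std()
        out = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    elif method == "minmax":
        lo, hi = v.min(), v.max()
        out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
    else:
        raise ValueError(
            f"method must be 'zscore', 'minmax' or 'none', got {method!r}"
        )
    return replace(vol, voxels=out.astype(np.float32))
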