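"""Synthetic DWI phantom generation.

Rectal tumors are hyperintense on high-b-value diffusion-weighted images,
so a minimal but useful phantom is a bright ellipsoid (the tumor) on a
darker anatomical background, optionally accompanied by

* a *confounder*: a second bright structure (emulating adjacent tissue
  whose gray level approaches the tumor's — the documented failure mode of
  threshold-based segmentation), and
* small bright *specks* (point-like false-positive candidates such as
  residual luminal fluid or noise spikes).

The image is corrupted by Rician noise — the magnitude of a complex
Gaussian — which is the physically appropriate noise model for magnitude
MR images.  The paired ground-truth mask is the exact voxelized tumor
ellipsoid, untouched by noise.

Grid conventions follow the acquisition protocol this emulates: a 256x256
in-plane matrix with a 340 mm field of view (1.328 mm pixels) and 4 mm
slices with a 1 mm gap (5 mm slice spacing).  The default working grid for
experiments is 64x64x16, a 4x in-plane / 2x through-plane downscaling of
the native 256x256x32 grid, keeping a full train-evaluate cycle cheap;
native-resolution phantoms are generated by passing the native shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .volume_io import ImageVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "CohortRanges",
    "generate_phantom",
    "generate_cohort",
    "make_confounder_phantom",
    "DEFAULT_SHAPE",
    "NATIVE_SHAPE",
    "DEFAULT_SPACING",
]

NATIVE_SHAPE = (256, 256, 32)
DEFAULT_SHAPE = (64, 64, 16)
#: mm per voxel: 340 mm FOV / 256 matrix in-plane, 4 mm slices + 1 mm gap.
DEFAULT_SPACING = (340.0 / 256.0, 340.0 / 256.0, 5.0)


@dataclass(frozen=True)
class ConfounderSpec:
    """A second bright ellipsoid that is not tumor."""

    center: tuple[int, int, int]
    semiaxes: tuple[float, float, float]
    intensity: float


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one phantom volume.

    Intensities are unitless (DWI gray values are scanner-arbitrary); the
    only hard constraint is tumor hyperintensity relative to background.
    """

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    tumor_center: tuple[int, int, int] | None = None  # None -> grid center
    tumor_semiaxes: tuple[float, float, float] = (10.0, 10.0, 4.0)
    tumor_intensity: float = 500.0
    background_intensity: float = 100.0
    confounder: ConfounderSpec | None = None
    n_specks: int = 0
    speck_size: int = 1
    speck_intensity: float | None = None  # None -> tumor_intensity
    noise_sigma: float = 25.0
    seed: int = 0

    def resolved_center(self) -> tuple[int, int, int]:
        if self.tumor_center is not None:
            return self.tumor_center
        return tuple(s // 2 for s in self.shape)

    def validate(self) -> None:
        if self.tumor_intensity <= self.background_intensity:
            raise ValueError(
                "tumor must be hyperintense: tumor_intensity "
                f"{self.tumor_intensity} <= background "
                f"{self.background_intensity}"
            )
        if any(a <= 0 for a in self.tumor_semiaxes):
            raise ValueError(f"semiaxes must be positive: {self.tumor_semiaxes}")
        c = self.resolved_center()
        for ci, ai, ni in zip(c, self.tumor_semiaxes, self.shape):
            if ci - ai < 0 or ci + ai > ni - 1:
                raise ValueError(
                    f"tumor ellipsoid (center {c}, semiaxes "
                    f"{self.tumor_semiaxes}) exceeds grid bounds {self.shape}"
                )


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator):
    """Magnitude of (signal + n1) + i*n2 with n1, n2 ~ N(0, sigma)."""
    if sigma == 0:
        return signal.astype(np.float32)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Generate one (image, mask) pair from a fully resolved spec.

    The mask is exactly the voxelized tumor ellipsoid
    {x : sum_i ((x_i - c_i)/a_i)^2 <= 1}.  The noiseless image assigns
    ``background_intensity`` everywhere, then paints the confounder, the
    specks, and finally the tumor (so overlaps never dim the tumor), and
    Rician noise is applied last.  Identical specs (same seed) produce
    bitwise-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    center = spec.resolved_center()

    tumor = _ellipsoid_mask(shape, center, spec.tumor_semiaxes)
    signal = np.full(shape, spec.background_intensity, dtype=np.float64)

    if spec.confounder is not None:
        conf = _ellipsoid_mask(
            shape, spec.confounder.center, spec.confounder.semiaxes
        )
        signal[conf & ~tumor] = spec.confounder.intensity

    if spec.n_specks > 0:
        speck_val = (
            spec.tumor_intensity
            if spec.speck_intensity is None
            else spec.speck_intensity
        )
        r = max(int(spec.speck_size), 1)
        for _ in range(spec.n_specks):
            # rejection-sample a speck center off the tumor
            for _attempt in range(100):
                c = tuple(int(rng.integers(r, n - r)) for n in shape)
                if not tumor[c]:
                    break
            sl = tuple(slice(ci - r + 1, ci + r) for ci in c)
            region = signal[sl]
            region[~tumor[sl]] = speck_val

    signal[tumor] = spec.tumor_intensity
    image = _rician(signal, spec.noise_sigma, rng)

    img = ImageVolume(image, spacing=spec.spacing)
    msk = LabelVolume(tumor.astype(np.uint8), spacing=spec.spacing)
    return img, msk


@dataclass(frozen=True)
class CohortRanges:
    """Uniform sampling ranges for per-case phantom variation.

    Tumor size, position, and brightness vary independently across cases so
    that tumor volumes span a wide range (which is what makes a DSC-versus-
    volume correlation measurable on the cohort).
    """

    semiaxes_xy: tuple[float, float] = (5.0, 14.0)
    semiaxes_z: tuple[float, float] = (2.5, 6.0)
    center_jitter_xy: int = 8
    center_jitter_z: int = 2
    tumor_intensity: tuple[float, float] = (400.0, 600.0)
    background_intensity: tuple[float, float] = (90.0, 110.0)
    n_specks: tuple[int, int] = (0, 3)


def generate_cohort(
    n: int,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    noise_sigma: float = 25.0,
) -> list[tuple[ImageVolume, LabelVolume]]:
    """Draw *n* independent phantoms with per-case tumor variation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = ranges or CohortRanges()
    master = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        rng = np.random.default_rng(master.integers(2**31))
        ax = rng.uniform(*ranges.semiaxes_xy)
        ay = rng.uniform(*ranges.semiaxes_xy)
        az = rng.uniform(*ranges.semiaxes_z)
        # cap semiaxes so the ellipsoid fits the grid regardless of ranges
        ax, ay, az = (
            min(a, (n - 2) / 2.0) for a, n in zip((ax, ay, az), shape)
        )
        base = tuple(s // 2 for s in shape)
        jit = (ranges.center_jitter_xy, ranges.center_jitter_xy,
               ranges.center_jitter_z)
        center = []
        for c0, j, a, ni in zip(base, jit, (ax, ay, az), shape):
            lo = max(int(np.ceil(a)), c0 - j)
            hi = min(ni - 1 - int(np.ceil(a)), c0 + j)
            if hi < lo:  # tumor too large to jitter; pin to center
                lo = hi = c0
            center.append(int(rng.integers(lo, hi + 1)))
        spec = PhantomSpec(
            shape=shape,
            spacing=spacing,
            tumor_center=tuple(center),
            tumor_semiaxes=(ax, ay, az),
            tumor_intensity=float(rng.uniform(*ranges.tumor_intensity)),
            background_intensity=float(
                rng.uniform(*ranges.background_intensity)
            ),
            n_specks=int(rng.integers(ranges.n_specks[0],
                                      ranges.n_specks[1] + 1)),
            speck_size=1,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(2**31)),
        )
        cohort.append(generate_phantom(spec))
    return cohort


def make_confounder_phantom(
    spec: PhantomSpec,
) -> tuple[ImageVolume, LabelVolume]:
    """Generate a phantom whose largest bright region is NOT the tumor.

    Requires a confounder strictly larger in volume than the tumor and at
    least as intense, so that threshold-plus-largest-component segmentation
    provably latches onto the wrong structure.
    """
    if spec.confounder is None:
        raise ValueError("spec must include a confounder")
    tumor_vol = 4.0 / 3.0 * np.pi * float(np.prod(spec.tumor_semiaxes))
    conf_vol = 4.0 / 3.0 * np.pi * float(np.prod(spec.confounder.semiaxes))
    if conf_vol <= tumor_vol:
        raise ValueError(
            f"confounder volume ({conf_vol:.0f}) must exceed tumor volume "
            f"({tumor_vol:.0f})"
        )
    if spec.confounder.intensity < spec.tumor_intensity:
        raise ValueError(
            "confounder intensity must be >= tumor intensity "
            f"({spec.confounder.intensity} < {spec.tumor_intensity})"
        )
    return generate_phantom(spec)
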