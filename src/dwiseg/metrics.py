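"""Segmentation evaluation: Dice overlap, Hausdorff distance, cohort summaries.

The Dice similarity coefficient between a ground-truth voxel set A and a
segmentation B is

    DSC(A, B) = 2 |A ∩ B| / (|A| + |B|),

and the Hausdorff distance is the symmetrized maximum of directed
nearest-point distances,

    HD(A, B) = max( max_{a∈A} min_{b∈B} d(a, b),
                    max_{b∈B} min_{a∈A} d(b, a) ).

Conventions (documented choices where the metrics admit more than one):

* DSC of two empty masks is defined as 1 (perfect agreement of empties);
  empty-versus-nonempty is 0 by the formula.
* HD is exact (not a percentile variant), Euclidean, and computed on voxel
  indices by default; ``units="mm"`` scales indices by the header spacing.
* HD is undefined if either set is empty; evaluation records it as missing
  rather than inventing a sentinel.
* Group standard deviations are sample (n-1) standard deviations, the
  convention of cohort tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import directed_hausdorff

from .volume_io import ImageVolume, LabelVolume, ProbabilityVolume, ShapeError

__all__ = [
    "UndefinedDistanceError",
    "DegenerateInputError",
    "CaseEvaluation",
    "GroupSummary",
    "dice",
    "soft_dice_loss",
    "hausdorff",
    "evaluate_case",
    "summarize_group",
    "paired_t",
    "pearson",
    "cases_to_csv",
    "summary_to_json",
]


class UndefinedDistanceError(ValueError):
    """Hausdorff distance is undefined (an operand mask is empty)."""


class DegenerateInputError(ValueError):
    """A statistic's input is degenerate (zero variance / constant)."""


def _as_bool_grid(m) -> np.ndarray:
    if isinstance(m, LabelVolume):
        return m.voxels.astype(bool)
    return np.asarray(m).astype(bool)


def _require_same_lattice(a, b):
    ga, gb = _as_bool_grid(a), _as_bool_grid(b)
    if ga.shape != gb.shape:
        raise ShapeError(f"lattice mismatch: {ga.shape} vs {gb.shape}")
    return ga, gb


def dice(A, B) -> float:
    """Dice similarity coefficient of two binary masks on one lattice."""
    ga, gb = _require_same_lattice(A, B)
    va, vb = int(ga.sum()), int(gb.sum())
    if va + vb == 0:
        return 1.0
    return 2.0 * int((ga & gb).sum()) / (va + vb)


def soft_dice_loss(P, A, eps: float = 1e-6) -> float:
    """1 − soft Dice between a probability map P and a binary mask A.

    loss = 1 − (2 Σ P·A + eps) / (Σ P + Σ A + eps).  Differentiable in P;
    on binary P it equals 1 − DSC up to eps.
    """
    p = P.voxels if isinstance(P, ImageVolume) else np.asarray(P)
    a = _as_bool_grid(A)
    if p.shape != a.shape:
        raise ShapeError(f"lattice mismatch: {p.shape} vs {a.shape}")
    p = p.astype(np.float64)
    num = 2.0 * float((p * a).sum()) + eps
    den = float(p.sum()) + float(a.sum()) + eps
    return 1.0 - num / den


def _mask_points(mask: np.ndarray, spacing=None) -> np.ndarray:
    pts = np.argwhere(mask).astype(np.float64)
    if spacing is not None:
        pts *= np.asarray(spacing, dtype=np.float64)
    return pts


def hausdorff(A, B, units: str = "voxel") -> float:
    """Exact symmetric Hausdorff distance between two nonempty masks.

    ``units="voxel"`` measures Euclidean distance on 0-based voxel indices;
    ``units="mm"`` scales each index by the volume's spacing first (both
    masks must then carry identical spacing).
    """
    ga, gb = _require_same_lattice(A, B)
    if not ga.any() or not gb.any():
        raise UndefinedDistanceError(
            "Hausdorff distance is undefined for an empty mask"
        )
    if units == "voxel":
        spacing = None
    elif units == "mm":
        if not (isinstance(A, ImageVolume) and isinstance(B, ImageVolume)):
            raise ValueError("mm units require volumes with spacing metadata")
        if not np.allclose(A.spacing, B.spacing):
            raise ShapeError(f"spacing mismatch: {A.spacing} vs {B.spacing}")
        spacing = A.spacing
    else:
        raise ValueError(f"units must be 'voxel' or 'mm', got {units!r}")
    pa = _mask_points(ga, spacing)
    pb = _mask_points(gb, spacing)
    d_ab = directed_hausdorff(pa, pb)[0]
    d_ba = directed_hausdorff(pb, pa)[0]
    return max(d_ab, d_ba)


@dataclass
class CaseEvaluation:
    """Per-case segmentation scores: DSC, HD, and the two mask volumes."""

    case_id: str
    dsc: float
    hd: float | None  # None when undefined (empty prediction)
    truth_volume: int
    seg_volume: int


def evaluate_case(
    truth: LabelVolume, seg: LabelVolume, case_id: str = "",
    units: str = "voxel",
) -> CaseEvaluation:
    """Score one segmentation against its ground truth.

    An empty prediction (or truth) leaves HD undefined and recorded as
    ``None``; DSC is always defined.
    """
    d = dice(truth, seg)
    try:
        h = hausdorff(truth, seg, units=units)
    except UndefinedDistanceError:
        h = None
    ga, gb = _as_bool_grid(truth), _as_bool_grid(seg)
    return CaseEvaluation(
        case_id=str(case_id),
        dsc=float(d),
        hd=h,
        truth_volume=int(ga.sum()),
        seg_volume=int(gb.sum()),
    )


@dataclass
class GroupSummary:
    """Cohort-table style summary: DSC moments and extremes, HD moments."""

    dsc_mean: float
    dsc_std: float
    dsc_median: float
    dsc_max: float
    dsc_min: float
    hd_mean: float | None
    hd_std: float | None
    n_cases: int
    n_hd_undefined: int


def _sample_std(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize_group(cases: Sequence[CaseEvaluation]) -> GroupSummary:
    """Summarize per-case scores; HD stats skip undefined entries."""
    if not cases:
        raise ValueError("cannot summarize an empty case list")
    dsc = np.array([c.dsc for c in cases], dtype=np.float64)
    hd = np.array([c.hd for c in cases if c.hd is not None], dtype=np.float64)
    return GroupSummary(
        dsc_mean=float(dsc.mean()),
        dsc_std=_sample_std(dsc),
        dsc_median=float(np.median(dsc)),
        dsc_max=float(dsc.max()),
        dsc_min=float(dsc.min()),
        hd_mean=float(hd.mean()) if hd.size else None,
        hd_std=_sample_std(hd) if hd.size else None,
        n_cases=len(cases),
        n_hd_undefined=len(cases) - hd.size,
    )


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on the differences x − y (two-sided).

    Used to compare per-case DSC of two segmentation methods over the same
    cohort.  Raises for degenerate (zero-variance) differences.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length 1D samples, n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise DegenerateInputError("all paired differences are identical")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation R with two-sided p-value via the t transform.

    Used for the DSC-versus-tumor-volume association.  Raises for constant
    input.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("pearson needs two equal-length 1D samples, n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("pearson is undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def cases_to_csv(cases: Iterable[CaseEvaluation], path) -> None:
    """Write per-case evaluations as CSV (one row per case)."""
    pd.DataFrame([asdict(c) for c in cases]).to_csv(path, index=False)


def summary_to_json(summary: GroupSummary, path) -> None:
    """Write a group summary as JSON mirroring the cohort-table fields."""
    with open(path, "w") as fh:
        json.dump(asdict(summary), fh, indent=2)
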