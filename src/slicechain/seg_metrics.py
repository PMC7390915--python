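"""Overlap and surface-distance metrics for binary segmentations.

All four metrics operate on filled voxel masks:

* DSC(A, B) = 2|A∩B| / (|A| + |B|)          (Dice similarity coefficient)
* JI(A, B)  = |A∩B| / |A∪B|                 (Jaccard index)
* ASD       = (d_avg(A→B) + d_avg(B→A)) / 2 in mm, where d_avg(A→B) is the
  mean over surface points of A of the distance to the nearest surface
  point of B
* HD        = max(h(A→B), h(B→A)), the exact (not percentile) Hausdorff
  distance in mm

Surface points are the centres of boundary voxels: foreground voxels with
at least one face-adjacent (6-connectivity) background or out-of-volume
neighbour, scaled by the anisotropic voxel spacing.  Empty masks make the
metrics undefined and raise :class:`UndefinedMetricError`; callers decide
any 0/1 policy explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import t as t_dist

from .exceptions import DegenerateInputError, UndefinedMetricError, ValidationError
from .volume_io import BinaryMask

__all__ = [
    "MetricReport",
    "dsc",
    "jaccard",
    "surface_points",
    "asd",
    "hd",
    "evaluate_pair",
    "paired_t",
]


def _as_bool_array(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.voxels
    return np.asarray(mask).astype(bool)


def _check_pair(A, B) -> tuple[np.ndarray, np.ndarray]:
    a, b = _as_bool_array(A), _as_bool_array(B)
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


@dataclass
class MetricReport:
    """DSC, JI, ASD (mm) and HD (mm) for one (prediction, truth) pair."""

    dsc: float
    ji: float
    asd_mm: float
    hd_mm: float

    def as_dict(self) -> dict[str, float]:
        return {"dsc": self.dsc, "ji": self.ji, "asd_mm": self.asd_mm, "hd_mm": self.hd_mm}


def dsc(A, B) -> float:
    """Dice similarity coefficient, 2|A∩B| / (|A|+|B|)."""
    a, b = _check_pair(A, B)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise UndefinedMetricError("DSC is undefined for two empty masks")
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


def jaccard(A, B) -> float:
    """Jaccard index, |A∩B| / |A∪B|."""
    a, b = _check_pair(A, B)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise UndefinedMetricError("Jaccard index is undefined for two empty masks")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def surface_points(mask, spacing: tuple[float, float, float]) -> np.ndarray:
    """Surface point set of a mask, in mm.

    A boundary voxel is a foreground voxel with >= 1 face-adjacent
    (6-connectivity) background neighbour; the volume border counts as
    background.  Returns an (n, 3) array of voxel-centre coordinates
    ``index * spacing``.
    """
    m = _as_bool_array(mask)
    if not m.any():
        raise UndefinedMetricError("surface of an empty mask is undefined")
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    interior = ndimage.binary_erosion(m, structure=structure, border_value=0)
    boundary = m & ~interior
    idx = np.argwhere(boundary).astype(np.float64)
    return idx * np.asarray(spacing, dtype=np.float64)


def _directed_nearest(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    tree = cKDTree(points_b)
    d, _ = tree.query(points_a, k=1)
    return d


def asd(A, B, spacing: tuple[float, float, float]) -> float:
    """Average surface distance in mm (symmetric mean of directed means)."""
    pa = surface_points(A, spacing)
    pb = surface_points(B, spacing)
    dab = _directed_nearest(pa, pb).mean()
    dba = _directed_nearest(pb, pa).mean()
    return float((dab + dba) / 2.0)


def hd(A, B, spacing: tuple[float, float, float]) -> float:
    """Exact Hausdorff distance in mm, max of the two directed maxima."""
    pa = surface_points(A, spacing)
    pb = surface_points(B, spacing)
    hab = _directed_nearest(pa, pb).max()
    hba = _directed_nearest(pb, pa).max()
    return float(max(hab, hba))


def evaluate_pair(pred, truth, spacing: tuple[float, float, float]) -> MetricReport:
    """All four metrics for one (prediction, truth) pair."""
    return MetricReport(
        dsc=dsc(pred, truth),
        ji=jaccard(pred, truth),
        asd_mm=asd(pred, truth, spacing),
        hd_mm=hd(pred, truth, spacing),
    )


def paired_t(diffs) -> tuple[float, float]:
    """Paired t-test on per-case metric differences.

    Returns ``(t, p)`` with t = mean(d) / (sd(d)/sqrt(n)), sd using the
    n−1 denominator, and a two-sided p from the t distribution with n−1
    degrees of freedom.  Fewer than two differences or zero variance raise
    :class:`DegenerateInputError`.
    """
    d = np.asarray(diffs, dtype=np.float64).ravel()
    n = d.size
    if n < 2:
        raise DegenerateInputError(f"paired t-test needs >= 2 differences, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("paired t-test is undefined for zero-variance differences")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df=n - 1)
    return float(t), float(p)
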