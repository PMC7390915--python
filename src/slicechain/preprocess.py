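"""Body-mask construction, intensity normalization and augmentation.

CT scans carry external hardware — couch, immobilization plate,
thermoplastic mask — that a segmentation network should never see.  The
body mask is built per slice by Otsu thresholding, morphological closing
and 2D hole filling, then cleaned volumetrically by keeping the largest
26-connected component; multiplying it into the image removes everything
outside the patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateInputError, ValidationError
from .volume_io import BinaryMask, Case, CTVolume

__all__ = [
    "BodyMaskConfig",
    "NormalizationConfig",
    "otsu_threshold",
    "compute_body_mask",
    "apply_body_mask",
    "normalize",
    "augment_sample",
    "preprocess_case",
]

logger = logging.getLogger(__name__)

OTSU_BINS = 256


@dataclass
class BodyMaskConfig:
    """Parameters of body-mask construction.

    closing_radius_mm : disk radius of the per-slice morphological closing,
        in mm; converted to pixels with the in-plane spacing ``dx``.
    keep_largest_component : keep only the largest 3D 26-connected
        foreground component (drops the couch and other detached hardware).
    fill_holes_2d : fill enclosed background holes per slice after closing.
    """

    closing_radius_mm: float = 5.0
    keep_largest_component: bool = True
    fill_holes_2d: bool = True

    def __post_init__(self) -> None:
        if self.closing_radius_mm <= 0:
            raise ValidationError(f"closing_radius_mm must be > 0, got {self.closing_radius_mm}")


@dataclass
class NormalizationConfig:
    """Fixed intensity window mapped affinely onto [0, 1]."""

    window_low: float = -1000.0
    window_high: float = 1000.0

    def __post_init__(self) -> None:
        if not self.window_low < self.window_high:
            raise ValidationError(
                f"window_low must be < window_high, got [{self.window_low}, {self.window_high}]"
            )


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the input range.

    Returns the threshold maximizing the between-class variance; the
    foreground convention everywhere in this package is *strictly greater*
    than the threshold.  Constant input raises
    :class:`DegenerateInputError`.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateInputError("Otsu threshold is undefined for constant input")

    counts, edges = np.histogram(values, bins=OTSU_BINS, range=(lo, hi))
    counts = counts.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # candidate thresholds split the histogram after bin i (i = 0..bins-2)
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    s0 = np.cumsum(counts * centers)[:-1]
    s1 = (counts * centers).sum() - s0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateInputError("Otsu threshold is undefined: all mass in one bin")
    mu0 = np.where(valid, s0 / np.where(w0 > 0, w0, 1), 0.0)
    mu1 = np.where(valid, s1 / np.where(w1 > 0, w1, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    i = int(np.argmax(between))  # first maximum on ties
    return float(centers[i])


def _disk(radius_px: int) -> np.ndarray:
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def compute_body_mask(vol: CTVolume, cfg: BodyMaskConfig | None = None) -> BinaryMask:
    """Build the binary body mask of a volume.

    Per slice: Otsu threshold -> foreground, closing with a disk of radius
    ``round(closing_radius_mm / dx)`` pixels, 2D hole filling.  Then, if
    enabled, only the largest 3D 26-connected component is kept.  Constant
    slices yield an all-zero mask slice with a logged warning.
    """
    cfg = cfg or BodyMaskConfig()
    dx = vol.spacing[2]
    radius_px = max(1, int(round(cfg.closing_radius_mm / dx)))
    footprint = _disk(radius_px)

    out = np.zeros(vol.shape, dtype=bool)
    for k in range(vol.n_slices):
        sl = vol.voxels[k]
        try:
            t = otsu_threshold(sl)
        except DegenerateInputError:
            logger.warning("slice %d is constant; body mask left empty there", k)
            continue
        fg = sl > t
        fg = ndimage.binary_closing(fg, structure=footprint)
        if cfg.fill_holes_2d:
            fg = ndimage.binary_fill_holes(fg)
        out[k] = fg

    if cfg.keep_largest_component and out.any():
        labels, n = ndimage.label(out, structure=np.ones((3, 3, 3), dtype=bool))
        if n > 1:
            sizes = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
            out = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(voxels=out, spacing=vol.spacing)


def apply_body_mask(vol: CTVolume, body: BinaryMask) -> CTVolume:
    """Zero out everything outside the body.

    Voxels inside the mask are preserved bit-exactly; voxels outside are
    set to the volume minimum (the air/background level in raw HU).
    """
    if body.shape != vol.shape:
        raise ValidationError(
            f"body mask shape {body.shape} does not match volume shape {vol.shape}"
        )
    background = vol.voxels.min()
    voxels = np.where(body.voxels, vol.voxels, background)
    return CTVolume(voxels=voxels, spacing=vol.spacing)


def normalize(vol: CTVolume, cfg: NormalizationConfig | None = None) -> CTVolume:
    """Clip to the HU window and map affinely onto [0, 1]."""
    cfg = cfg or NormalizationConfig()
    clipped = np.clip(vol.voxels.astype(np.float32), cfg.window_low, cfg.window_high)
    scaled = (clipped - cfg.window_low) / (cfg.window_high - cfg.window_low)
    return CTVolume(voxels=scaled.astype(np.float32), spacing=vol.spacing)


def preprocess_case(
    case: Case,
    body_cfg: BodyMaskConfig | None = None,
    norm_cfg: NormalizationConfig | None = None,
) -> Case:
    """The full preprocessing chain applied to one case: body mask,
    multiplication into the image, window normalization to [0, 1]."""
    body = compute_body_mask(case.volume, body_cfg)
    masked = apply_body_mask(case.volume, body)
    normed = normalize(masked, norm_cfg)
    return Case(volume=normed, mask=case.mask, case_id=case.case_id)


def augment_sample(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    rng: np.random.Generator | int,
    *,
    flip: bool | None = None,
    angle_deg: float | None = None,
    max_angle_deg: float = 10.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Apply one shared random flip/rotation to all grids of a sample.

    One draw per call: a left-right flip with probability 0.5, then a
    rotation by an angle uniform in ``[-max_angle_deg, +max_angle_deg]``.
    The identical geometric transform is applied to every grid; images are
    interpolated bilinearly, masks nearest-neighbour and re-binarized.
    ``flip``/``angle_deg`` override the random draw (used for tests and
    reproducibility).
    """
    grids = list(images) + list(masks)
    if not grids:
        return [], []
    shape = grids[0].shape
    for g in grids:
        if g.shape != shape:
            raise ValidationError(f"all grids in a sample must share a shape, got {g.shape} vs {shape}")

    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    do_flip = bool(rng.random() < 0.5) if flip is None else bool(flip)
    angle = float(rng.uniform(-max_angle_deg, max_angle_deg)) if angle_deg is None else float(angle_deg)

    def transform(grid: np.ndarray, is_mask: bool) -> np.ndarray:
        g = grid.astype(np.float32)
        if do_flip:
            g = g[:, ::-1]
        if angle != 0.0:
            order = 0 if is_mask else 1
            g = ndimage.rotate(g, angle, reshape=False, order=order, mode="constant", cval=0.0)
        if is_mask:
            return (g > 0.5).astype(grid.dtype)
        return g.astype(grid.dtype, copy=False)

    out_images = [transform(g, is_mask=False) for g in images]
    out_masks = [transform(g, is_mask=True) for g in masks]
    return out_images, out_masks
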