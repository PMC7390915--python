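"""Sequential-iterative inference: propagate a seed contour slice by slice.

A manual (or ground-truth) contour on the beginning slice seeds the loop;
the model predicts the contour on the adjacent slice, the prediction is
binarized, cleaned, written into the output mask and fed back as the
current contour for the next step.  Propagation runs inferior→superior
("forward") or superior→inferior ("backward") and stops at the volume
end, after a configurable run of near-empty predictions (area-stop), or
at a step cap.

The input volume must already be preprocessed (body-masked, normalized to
[0, 1]) the same way the training data was.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError
from .sinet_model import SInetInput
from .volume_io import BinaryMask, Case, CTVolume

__all__ = [
    "PropagationConfig",
    "PropagationResult",
    "binarize",
    "propagate",
    "segment_case",
]


@dataclass
class PropagationConfig:
    """Inference-loop settings.

    binarize_threshold : probability cut; foreground is *strictly greater*.
    stop_min_voxels / stop_patience : the area-stop rule — halt after
        ``stop_patience`` consecutive predicted slices with fewer than
        ``stop_min_voxels`` foreground voxels (0 disables the rule).
    max_steps : cap on the number of predicted slices (None = to volume end).
    keep_largest_component : keep only the largest 2D 8-connected component
        of each binarized prediction, preventing speckle accumulation.
    """

    direction: str = "forward"
    binarize_threshold: float = 0.5
    stop_min_voxels: int = 10
    stop_patience: int = 2
    max_steps: Optional[int] = None
    keep_largest_component: bool = True

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValidationError(f"direction must be forward|backward, got {self.direction}")
        if not 0.0 < self.binarize_threshold < 1.0:
            raise ValidationError(
                f"binarize_threshold must be in (0, 1), got {self.binarize_threshold}"
            )


@dataclass
class PropagationResult:
    """Predicted mask volume plus per-slice provenance."""

    mask: BinaryMask
    seed_index: int
    visited: list[int] = field(default_factory=list)
    voxel_counts: dict[int, int] = field(default_factory=dict)
    stop_reason: str = "end-of-volume"


def binarize(p: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; 1 iff strictly greater than the cut."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    return np.asarray(p) > threshold


def _largest_component_2d(mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def propagate(
    model,
    vol: CTVolume,
    seed_mask: np.ndarray,
    seed_index: int,
    cfg: PropagationConfig,
) -> PropagationResult:
    """Run the sequential-iterative loop from a seed contour.

    The seed slice is copied into the output verbatim and never
    overwritten.  When the area-stop fires, the trailing below-floor
    slices are zeroed (they were the evidence of the target's end, not
    part of it).
    """
    seed_mask = np.asarray(seed_mask).astype(bool)
    if seed_mask.shape != vol.shape[1:]:
        raise ValidationError(
            f"seed mask shape {seed_mask.shape} != slice shape {vol.shape[1:]}"
        )
    if not 0 <= seed_index < vol.n_slices:
        raise ValidationError(f"seed_index {seed_index} out of range [0, {vol.n_slices})")
    if not seed_mask.any():
        raise ValidationError("seed mask is empty")

    step = 1 if cfg.direction == "forward" else -1
    out = np.zeros(vol.shape, dtype=bool)
    out[seed_index] = seed_mask

    visited: list[int] = []
    counts: dict[int, int] = {}
    low_run: list[int] = []
    stop_reason = "end-of-volume"
    current = seed_mask
    i = seed_index
    n_steps = 0

    while True:
        j = i + step
        if j < 0 or j >= vol.n_slices:
            stop_reason = "end-of-volume"
            break
        if cfg.max_steps is not None and n_steps >= cfg.max_steps:
            stop_reason = "max-steps"
            break
        inp = SInetInput(
            current_image=vol.voxels[i],
            current_mask=current.astype(vol.voxels.dtype),
            next_image=vol.voxels[j],
        )
        p = model.predict(inp)
        m = binarize(p, cfg.binarize_threshold)
        if cfg.keep_largest_component:
            m = _largest_component_2d(m)
        out[j] = m
        visited.append(j)
        counts[j] = int(m.sum())
        n_steps += 1

        if cfg.stop_min_voxels > 0 and counts[j] < cfg.stop_min_voxels:
            low_run.append(j)
            if len(low_run) >= cfg.stop_patience:
                stop_reason = "area-stop"
                break
        else:
            low_run = []
        current = m
        i = j

    if stop_reason == "area-stop":
        for j in low_run:
            out[j] = False

    return PropagationResult(
        mask=BinaryMask(voxels=out, spacing=vol.spacing),
        seed_index=seed_index,
        visited=visited,
        voxel_counts=counts,
        stop_reason=stop_reason,
    )


def segment_case(
    model_fwd,
    model_bwd,
    case: Case,
    cfg: PropagationConfig,
    mode: str = "extent",
    seed_mask: Optional[np.ndarray] = None,
    seed_index: Optional[int] = None,
) -> BinaryMask:
    """Segment one (preprocessed) case by propagation in one direction.

    Evaluation mode derives the seed from the ground truth: the most
    inferior nonzero slice for forward travel, the most superior for
    backward.  ``mode="extent"`` propagates exactly over the ground-truth
    extent with the area-stop disabled (the protocol used for metric
    comparisons); ``mode="free"`` lets the configured stop rule decide.
    Deployment callers pass ``seed_mask``/``seed_index`` explicitly.
    """
    if mode not in ("extent", "free"):
        raise ValidationError(f"mode must be extent|free, got {mode}")
    model = model_fwd if cfg.direction == "forward" else model_bwd
    if model is None:
        raise ValidationError(f"no model supplied for direction {cfg.direction}")

    if seed_mask is None or seed_index is None:
        if case.mask is None:
            raise ValidationError("evaluation-mode seeding needs a ground-truth mask")
        nz = np.flatnonzero(case.mask.voxels.reshape(case.mask.shape[0], -1).any(axis=1))
        if nz.size == 0:
            raise ValidationError("ground-truth mask is empty")
        a, b = int(nz[0]), int(nz[-1])
        seed_index = a if cfg.direction == "forward" else b
        seed_mask = case.mask.voxels[seed_index]
        if mode == "extent":
            cfg = PropagationConfig(
                direction=cfg.direction,
                binarize_threshold=cfg.binarize_threshold,
                stop_min_voxels=0,
                stop_patience=cfg.stop_patience,
                max_steps=b - a,
                keep_largest_component=cfg.keep_largest_component,
            )
    result = propagate(model, case.volume, seed_mask, seed_index, cfg)
    return result.mask
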