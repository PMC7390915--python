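"""Synthetic CT-like phantoms for end-to-end testing without patient data.

Each phantom emulates the geometry of a planning-CT head-and-neck scan:
an elliptical soft-tissue "body" (≈0 HU) on an air background (−1000 HU),
an external couch-like bar, and a target whose star-convex cross-section
drifts and tapers smoothly across slices with tunable target-to-surround
contrast.  The default desk-scale grid is 64×64×24 at (2.5, 0.98, 0.98) mm
spacing; the generator supports the full 512×512 in-plane size.

The target cross-section at slice ``s`` is the star-convex region

    rho <= r(theta; s) = R(s) * (1 + sum_k a_k cos(k theta + phi_k))

around a centre c(s), where c(s) and R(s) follow seeded Gaussian random
walks and R(s) tapers cosine-smoothly to a positive floor at both ends of
the target extent.  Lobed (rather than elliptical) cross-sections keep the
task from being solvable by a trivial intensity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import GenerationError, ValidationError
from .volume_io import BinaryMask, Case, CTVolume

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "generate_phantom",
    "generate_cohort",
    "low_contrast_variant",
    "DEFAULT_COHORT_RANGES",
]


@dataclass
class PhantomSpec:
    """Geometry, intensity and randomness parameters of one phantom."""

    shape: tuple[int, int, int] = (24, 64, 64)
    spacing: tuple[float, float, float] = (2.5, 0.98, 0.98)
    # body ellipse semi-axes as fractions of the in-plane size (row, col)
    body_semiaxes_frac: tuple[float, float] = (0.27, 0.38)
    couch: bool = True
    couch_rows: int = 2
    couch_intensity: float = 200.0
    # target extent and cross-section
    target_start: int = 5
    target_end: int = 18  # inclusive
    base_radius_frac: float = 0.16
    center_drift_sd: float = 0.5   # voxels per slice
    radius_drift_sd: float = 0.02  # fraction of base radius per slice
    lobe_count: int = 3
    lobe_amplitude: float = 0.15
    taper_floor: float = 0.35
    contrast: float = 100.0        # target minus surrounding body, HU-like
    noise_sd: float = 20.0
    background_intensity: float = -1000.0
    body_intensity: float = 0.0

    def __post_init__(self) -> None:
        n_slices = self.shape[0]
        if not (0 <= self.target_start < self.target_end < n_slices):
            raise ValidationError(
                f"need 0 <= target_start < target_end < n_slices, got "
                f"[{self.target_start}, {self.target_end}] in {n_slices} slices"
            )
        if self.contrast < 0 or self.noise_sd < 0:
            raise ValidationError("contrast and noise_sd must be >= 0")
        if not 0 < self.taper_floor <= 1:
            raise ValidationError("taper_floor must be in (0, 1]")


@dataclass
class PhantomCase:
    """A generated case together with the spec that produced it."""

    case: Case
    spec: PhantomSpec
    seed: int = 0

    @property
    def volume(self) -> CTVolume:
        return self.case.volume

    @property
    def mask(self) -> BinaryMask:
        assert self.case.mask is not None
        return self.case.mask


def _body_ellipse(n_rows: int, n_cols: int, semiaxes_frac: tuple[float, float]) -> np.ndarray:
    cy, cx = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    ry = semiaxes_frac[0] * n_rows
    rx = semiaxes_frac[1] * n_cols
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _target_slice_mask(
    n_rows: int,
    n_cols: int,
    center: tuple[float, float],
    radius: float,
    amps: np.ndarray,
    phases: np.ndarray,
) -> np.ndarray:
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    dy = yy - center[0]
    dx = xx - center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    k = np.arange(2, 2 + len(amps))  # lobes start at harmonic 2 (no pure offset)
    modulation = 1.0 + np.sum(
        amps[:, None, None] * np.cos(k[:, None, None] * theta[None] + phases[:, None, None]),
        axis=0,
    )
    return rho <= radius * modulation


def _draw_target(spec: PhantomSpec, body2d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One attempt at a target mask volume; may leave the body (checked by caller)."""
    n_slices, n_rows, n_cols = spec.shape
    a, b = spec.target_start, spec.target_end
    n_target = b - a + 1

    base_r = spec.base_radius_frac * min(n_rows, n_cols)
    amps = rng.uniform(0.3, 1.0, size=spec.lobe_count)
    if amps.sum() > 0:
        amps *= spec.lobe_amplitude / amps.sum()  # total modulation capped
    phases = rng.uniform(0, 2 * np.pi, size=spec.lobe_count)

    center0 = np.array([(n_rows - 1) / 2.0, (n_cols - 1) / 2.0])
    center_steps = rng.normal(0.0, spec.center_drift_sd, size=(n_target, 2))
    center_steps[0] = 0.0
    centers = center0 + np.cumsum(center_steps, axis=0)

    radius_steps = rng.normal(0.0, spec.radius_drift_sd * base_r, size=n_target)
    radius_steps[0] = 0.0
    radii = base_r + np.cumsum(radius_steps)

    # cosine-smooth taper to a positive floor at both ends of the extent
    s = np.arange(n_target)
    taper = spec.taper_floor + (1.0 - spec.taper_floor) * np.sin(np.pi * (s + 0.5) / n_target)
    radii = np.maximum(radii * taper, 1.0)

    mask = np.zeros(spec.shape, dtype=bool)
    for i in range(n_target):
        mask[a + i] = _target_slice_mask(
            n_rows, n_cols, tuple(centers[i]), float(radii[i]), amps, phases
        )
    return mask


def generate_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> PhantomCase:
    """Generate one phantom case, deterministic given ``(spec, seed)``.

    If the drifting target leaves the body, the target is redrawn (up to
    100 attempts) before :class:`GenerationError` is raised.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_slices, n_rows, n_cols = spec.shape

    body2d = _body_ellipse(n_rows, n_cols, spec.body_semiaxes_frac)

    target = None
    for _ in range(100):
        candidate = _draw_target(spec, body2d, rng)
        if np.all(body2d[None] | ~candidate):  # candidate ⊆ body on every slice
            target = candidate
            break
    if target is None:
        raise GenerationError("target left the body in all 100 redraw attempts")

    image = np.full(spec.shape, spec.background_intensity, dtype=np.float32)
    image[:, body2d] = spec.body_intensity
    image[target] += spec.contrast

    if spec.couch:
        r0 = n_rows - spec.couch_rows
        c0, c1 = n_cols // 4, 3 * n_cols // 4
        image[:, r0:, c0:c1] = spec.couch_intensity

    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)

    vol = CTVolume(voxels=image, spacing=spec.spacing)
    mask = BinaryMask(voxels=target, spacing=spec.spacing)
    case = Case(volume=vol, mask=mask, case_id=f"phantom-{seed}")
    return PhantomCase(case=case, spec=spec, seed=seed)


#: per-case uniform ranges used by :func:`generate_cohort` by default
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "base_radius_frac": (0.13, 0.19),
    "center_drift_sd": (0.3, 0.7),
    "radius_drift_sd": (0.01, 0.03),
    "lobe_amplitude": (0.08, 0.18),
}


def generate_cohort(
    n_cases: int,
    spec: PhantomSpec | None = None,
    spec_ranges: Optional[dict[str, tuple[float, float]]] = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a cohort of distinct phantoms.

    Per-case scalar spec fields are drawn uniformly from ``spec_ranges``
    (default :data:`DEFAULT_COHORT_RANGES`) with a per-case seed derived
    from ``seed``; the whole cohort is deterministic.
    """
    if n_cases < 1:
        raise ValidationError(f"n_cases must be >= 1, got {n_cases}")
    base = spec or PhantomSpec()
    ranges = DEFAULT_COHORT_RANGES if spec_ranges is None else spec_ranges
    master = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for i in range(n_cases):
        draws = {k: float(master.uniform(lo, hi)) for k, (lo, hi) in ranges.items()}
        case_seed = int(master.integers(0, 2**31 - 1))
        case_spec = replace(base, **draws)
        try:
            ph = generate_phantom(case_spec, seed=case_seed)
        except GenerationError as e:
            raise GenerationError(f"case {i}: {e}") from e
        ph.case.case_id = f"phantom-{i:03d}"
        cases.append(ph)
    return cases


def low_contrast_variant(
    spec: PhantomSpec, contrast_factor: float = 0.25, noise_factor: float = 2.0
) -> PhantomSpec:
    """The low soft-tissue-contrast regime: reduced target contrast,
    raised noise.  This is where slice-to-slice continuity should matter
    most for segmentation."""
    return replace(
        spec,
        contrast=spec.contrast * contrast_factor,
        noise_sd=spec.noise_sd * noise_factor,
    )
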