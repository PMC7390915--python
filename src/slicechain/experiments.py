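"""End-to-end phantom experiments: cohort generation, training, iterative
inference and evaluation, wired together with one seed.

This module is the programmatic counterpart of the command-line pipeline:
it is what the acceptance script and the heavier tests run.  Problem sizes
default to desk scale (64×64×24 grids, small networks, tens of epochs) so
a full experiment fits in minutes on one CPU; every component scales to
the clinical geometry (512×512, deeper networks) through the same configs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phantom import PhantomSpec, generate_cohort, low_contrast_variant
from .preprocess import preprocess_case
from .propagation import PropagationConfig, segment_case
from .seg_metrics import MetricReport, evaluate_pair
from .sinet_model import NetworkConfig, build_sinet, build_unet
from .trainer import TrainConfig, make_slice_samples, make_triplets, train
from .volume_io import BinaryMask, Case

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """One trainable phantom experiment."""

    n_train: int = 12
    n_test: int = 4
    model: str = "sinet"              # "sinet" | "unet"
    direction: str = "forward"        # used by sinet only
    low_contrast: bool = False
    epochs: int = 30
    # Desk-scale optimization: with ~10^3 Nadam steps instead of the ~10^5
    # of a clinical-scale run, the learning rate is scaled up and the batch
    # kept small so the step budget is spent on more updates.
    batch_size: int = 2
    learning_rate: float = 1e-3
    # Scheduled sampling for the iterative model: with this probability a
    # training sample's teacher-forced contour is replaced by the model's
    # own prediction of it.  Teacher-forced-only training leaves an
    # exposure gap that lets autoregressive rollouts drift even when
    # per-transition accuracy is high.
    scheduled_sampling_p: float = 0.5
    network: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(in_plane_size=64, levels=3, base_channels=8)
    )
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    augmentation: bool = False
    mode: str = "extent"              # propagation protocol for evaluation


@dataclass
class ExperimentResult:
    reports: list[MetricReport]
    case_ids: list[str]
    train_loss: list[float]
    predictions: list[BinaryMask] = field(default_factory=list)

    def mean(self, attr: str) -> float:
        """Mean over test cases; NaN distance entries (empty predictions,
        see :func:`_evaluate_with_empty_policy`) are excluded."""
        return float(np.nanmean([getattr(r, attr) for r in self.reports]))

    def sd(self, attr: str) -> float:
        vals = [getattr(r, attr) for r in self.reports]
        return float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0


def _prepared_cohort(cfg: ExperimentConfig, seed: int) -> list[Case]:
    spec = low_contrast_variant(cfg.phantom) if cfg.low_contrast else cfg.phantom
    phantoms = generate_cohort(cfg.n_train + cfg.n_test, spec=spec, seed=seed)
    return [preprocess_case(ph.case) for ph in phantoms]


def run_experiment(cfg: ExperimentConfig, seed: int = 0) -> ExperimentResult:
    """Generate a cohort, train the configured model, evaluate on held-out
    cases, all deterministically derived from ``seed``.

    SI-Net cases are segmented by seeded contour propagation; the U-Net
    baseline segments every slice of the ground-truth extent
    independently.  Metrics are 3D DSC/JI/ASD/HD per test case.
    """
    rng = np.random.default_rng(seed)
    cohort_seed = int(rng.integers(0, 2**31 - 1))
    train_seed = int(rng.integers(0, 2**31 - 1))
    init_seed = int(rng.integers(0, 2**31 - 1))

    cases = _prepared_cohort(cfg, cohort_seed)
    train_cases = cases[: cfg.n_train]
    test_cases = cases[cfg.n_train :]

    tcfg = TrainConfig(
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        seed=train_seed,
        direction=cfg.direction,
        augmentation=cfg.augmentation,
        scheduled_sampling_p=cfg.scheduled_sampling_p if cfg.model == "sinet" else 0.0,
    )

    if cfg.model == "sinet":
        model = build_sinet(cfg.network, seed=init_seed)
        samples = [s for c in train_cases for s in make_triplets(c, cfg.direction)]
    elif cfg.model == "unet":
        model = build_unet(cfg.network, seed=init_seed)
        samples = [s for c in train_cases for s in make_slice_samples(c)]
    else:
        raise ValueError(f"unknown model kind {cfg.model}")

    logger.info("training %s on %d samples from %d cases (%d epochs)",
                cfg.model, len(samples), len(train_cases), cfg.epochs)
    model, history = train(model, samples, [], tcfg)

    reports, ids, predictions = [], [], []
    pcfg = PropagationConfig(direction=cfg.direction)
    for case in test_cases:
        assert case.mask is not None
        if cfg.model == "sinet":
            pred = segment_case(model, model, case, pcfg, mode=cfg.mode)
        else:
            pred = _segment_slicewise(model, case)
        reports.append(_evaluate_with_empty_policy(pred, case.mask, case.volume.spacing))
        ids.append(case.case_id)
        predictions.append(pred)
        logger.info("case %s: dsc=%.3f ji=%.3f asd=%.2f hd=%.2f", case.case_id,
                    reports[-1].dsc, reports[-1].ji, reports[-1].asd_mm, reports[-1].hd_mm)
    return ExperimentResult(reports=reports, case_ids=ids,
                            train_loss=history.train_loss, predictions=predictions)


def _evaluate_with_empty_policy(pred, truth, spacing) -> MetricReport:
    """Benchmark scoring policy for degenerate predictions: an empty
    prediction against a nonempty truth scores zero overlap, and its
    surface distances are undefined (NaN, excluded from means)."""
    if not pred.voxels.any():
        return MetricReport(dsc=0.0, ji=0.0, asd_mm=float("nan"), hd_mm=float("nan"))
    return evaluate_pair(pred, truth, spacing)


def _segment_slicewise(model, case: Case) -> BinaryMask:
    """U-Net protocol: segment each slice of the ground-truth extent
    independently (the baseline has no notion of slice continuity)."""
    assert case.mask is not None
    nz = np.flatnonzero(case.mask.voxels.reshape(case.mask.shape[0], -1).any(axis=1))
    a, b = int(nz[0]), int(nz[-1])
    out = np.zeros(case.volume.shape, dtype=bool)
    for i in range(a, b + 1):
        out[i] = model.predict(case.volume.voxels[i]) > 0.5
    return BinaryMask(voxels=out, spacing=case.volume.spacing)
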