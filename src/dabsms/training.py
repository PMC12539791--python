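"""Seeded self-supervised training loop, greedy weight sweep, trial protocol."""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import losses
from .losses import LossWeights, resolve_weights
from .network import DeformationModel
from .nn import Adam
from .volumes import AtlasBundle, ImageVolume
from .warp import DisplacementField, _identity_coords, trilinear_sample_with_grad

__all__ = [
    "TrainConfig",
    "SweepGrid",
    "TrialSet",
    "seed_everything",
    "train",
    "training_step",
    "greedy_sweep",
    "repeat_and_summarize",
]


@dataclass(frozen=True)
class TrainConfig:
    seed: int = 0
    epochs: int = 1
    batch_size: int = 1
    learning_rate: float = 1e-4
    weights: object = "iac"  # LossWeights, preset name, or dict
    optimizer: str = "adam"
    grad_clip: float = 0.0  # global grad-norm clip; 0 disables
    label: str = ""

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        resolve_weights(self.weights)  # validate eagerly


@dataclass(frozen=True)
class SweepGrid:
    values: tuple[float, ...] = (0.1, 0.5, 1.0, 2.0, 10.0)
    w_cc: float = 1.0  # held constant throughout the sweep

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("sweep grid must be nonempty")
        if any(v <= 0 for v in self.values):
            raise ValueError("sweep grid values must be positive")


@dataclass
class TrialSet:
    """Per-trial metric lists plus the median-of-trials summary."""

    per_trial: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.per_trial)

    def summary(self):
        """Per-case median across trials, then cohort median.

        Scalar trials reduce to the plain median across trials.  The
        median of an even count is the mid-mean (numpy convention).
        """
        if not self.per_trial:
            raise ValueError("no trials recorded")
        first = self.per_trial[0]
        if np.isscalar(first):
            return float(np.median(np.asarray(self.per_trial, dtype=np.float64)))
        out = {}
        for key in first:
            per_case = np.asarray([t[key] for t in self.per_trial], dtype=np.float64)  # (trials, cases)
            out[key] = float(np.median(np.median(per_case, axis=0)))
        return out


def seed_everything(seed: int) -> None:
    """Reseed every PRNG stream the artifact uses."""
    random.seed(seed)
    np.random.seed(seed % 2**32)


def _target_volume(item) -> ImageVolume:
    return item.target if hasattr(item, "target") else item


def training_step(
    model: DeformationModel,
    target: ImageVolume,
    atlas: AtlasBundle,
    weights: LossWeights,
    optimizer: Adam,
    grad_clip: float = 0.0,
) -> tuple[float, dict]:
    """One gradient step on one target; returns (total, component breakdown)."""
    x = np.asarray(target.voxels, dtype=np.float32)[None]
    u = model.forward(x).astype(np.float64)
    fld = DisplacementField(u=u, grid=atlas.grid)

    coords = _identity_coords(atlas.grid.shape) + u
    warped, spatial = trilinear_sample_with_grad(np.asarray(target.voxels, np.float64), coords)

    total, comps, d_warped, d_u = losses.total_loss_grad(warped, atlas, fld, weights)
    if not np.isfinite(total):
        raise RuntimeError(f"loss became non-finite: total={total}, components={comps}")
    d_u = d_u + spatial * d_warped[None]

    model.zero_grad()
    model.backward(d_u)
    grads = model.gradients()
    if grad_clip > 0:
        norm = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
        if norm > grad_clip:
            scale = grad_clip / norm
            for g in grads:
                g *= scale
    optimizer.step(grads)
    return total, comps


def train(
    model: DeformationModel,
    cohort: Sequence,
    atlas: AtlasBundle,
    config: TrainConfig,
    max_steps: Optional[int] = None,
) -> tuple[DeformationModel, list[dict]]:
    """Self-supervised training against a fixed atlas bundle.

    Per step: predict the field for one target, pull the target back onto
    the atlas grid, evaluate the combined loss, update parameters.  The
    history records the per-epoch mean of each unweighted component and
    the weighted total.  Deterministic given the config (single CPU).

    ``max_steps`` optionally caps the total number of gradient steps.
    """
    weights = resolve_weights(config.weights)
    if weights.w_wgrad > 0:
        atlas.ensure_weight_map()
    opt = Adam(model.parameters(), lr=config.learning_rate)
    order_rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    steps_done = 0
    for epoch in range(config.epochs):
        order = order_rng.permutation(len(cohort))
        totals: list[float] = []
        comp_sums: dict[str, float] = {}
        for i in order:
            if max_steps is not None and steps_done >= max_steps:
                break
            total, comps = training_step(
                model, _target_volume(cohort[i]), atlas, weights, opt, grad_clip=config.grad_clip
            )
            steps_done += 1
            totals.append(total)
            for k, v in comps.items():
                comp_sums[k] = comp_sums.get(k, 0.0) + v
        if not totals:
            break
        row = {"epoch": epoch, "steps": len(totals), "total": float(np.mean(totals))}
        for k in ("cc", "grad", "wgrad", "ms"):
            row[f"loss_{k}"] = comp_sums.get(k, 0.0) / len(totals) if k in comp_sums else 0.0
        history.append(row)
        if max_steps is not None and steps_done >= max_steps:
            break
    return model, history


def greedy_sweep(
    base: TrainConfig,
    grid: SweepGrid,
    eval_fn: Callable[[TrainConfig], float],
) -> tuple[LossWeights, list[dict]]:
    """Two-stage greedy weight search.

    Stage 1 sweeps the smoothness weight (the gradient term, or the
    weighted-gradient term if the base config uses it) with the
    region-variance weight at 0.  Stage 2 fixes the stage-1 winner and
    sweeps the region-variance weight over the same grid.  ``eval_fn``
    maps a config to a validation score (higher is better, e.g. median
    Dice); exactly ``2 * len(grid.values)`` evaluations are performed.
    """
    base_weights = resolve_weights(base.weights)
    smooth_key = "w_wgrad" if base_weights.w_wgrad > 0 else "w_grad"
    table: list[dict] = []

    def run(stage: int, w_smooth: float, w_ms: float) -> float:
        kwargs = {"w_cc": grid.w_cc, "w_grad": 0.0, "w_wgrad": 0.0, "w_ms": w_ms}
        kwargs[smooth_key] = w_smooth
        cfg = replace(base, weights=LossWeights(**kwargs))
        score = float(eval_fn(cfg))
        table.append({"stage": stage, "smooth_key": smooth_key, "w_smooth": w_smooth, "w_ms": w_ms, "score": score})
        return score

    stage1 = [(run(1, w, 0.0), w) for w in grid.values]
    best_smooth = max(stage1, key=lambda t: t[0])[1]
    stage2 = [(run(2, best_smooth, w), w) for w in grid.values]
    best_ms = max(stage2, key=lambda t: t[0])[1]

    kwargs = {"w_cc": grid.w_cc, "w_grad": 0.0, "w_wgrad": 0.0, "w_ms": best_ms}
    kwargs[smooth_key] = best_smooth
    return LossWeights(**kwargs), table


def repeat_and_summarize(
    config: TrainConfig,
    n_trials: int,
    eval_fn: Callable[[TrainConfig], object],
) -> TrialSet:
    """Run n trials with derived seeds (seed, seed+1, ...) and collect metrics.

    ``eval_fn`` performs one full train+evaluate cycle and returns either a
    scalar score or a dict of per-case metric lists.
    """
    trials = TrialSet()
    for i in range(n_trials):
        cfg = replace(config, seed=config.seed + i)
        trials.per_trial.append(eval_fn(cfg))
    return trials
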