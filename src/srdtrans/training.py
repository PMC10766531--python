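"""Dual-target loss and the self-supervised optimization loop.

The network prediction for the center substack S_c is compared against both
orthogonal neighbour substacks; each comparison is a sum of a mean-squared
(L2) and a mean-absolute (L1) term, and the total loss is their sum:

    L_ver   = ||F(S_c) - S_v||_2^2 + |F(S_c) - S_v|_1
    L_hor   = ||F(S_c) - S_h||_2^2 + |F(S_c) - S_h|_1
    L_total = L_ver + L_hor

Both norms are per-element means so the loss is patch-size invariant.
Training stacks are z-scored per stack; the statistics are stored in every
checkpoint so inference can invert the normalization.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import Checkpoint, ModelConfig, SRDTransNet, save_checkpoint
from .nn import Adam, Tensor
from .sampling import DEFAULT_SEED, SamplingTriplet, augment_eightfold, extract_training_pairs
from .stack import ImageStack

__all__ = ["TrainConfig", "LossReport", "loss_pair", "loss_total", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the published recipe)."""

    lr: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 1
    patch_shape: tuple[int, int, int] = (128, 128, 128)
    n_pairs: int = 6000
    epochs: int = 20
    seed: int = DEFAULT_SEED
    augment: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.patch_shape[0] % 2 or self.patch_shape[1] % 2:
            raise ValueError("patch height/width must be even")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class LossReport:
    """The two target losses; the total is exactly their sum."""

    l_ver: float
    l_hor: float

    @property
    def l_total(self) -> float:
        return self.l_ver + self.l_hor


def loss_pair(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared difference plus mean absolute difference."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")
    diff = pred - target
    return float(np.mean(diff**2) + np.mean(np.abs(diff)))


def loss_total(pred: np.ndarray, s_v: np.ndarray, s_h: np.ndarray) -> LossReport:
    return LossReport(l_ver=loss_pair(pred, s_v), l_hor=loss_pair(pred, s_h))


def _loss_graph(pred: Tensor, s_v: np.ndarray, s_h: np.ndarray) -> tuple[Tensor, float, float]:
    """Differentiable counterpart of :func:`loss_total`."""
    dv = pred - Tensor(s_v.astype(pred.data.dtype))
    dh = pred - Tensor(s_h.astype(pred.data.dtype))
    l_ver = (dv**2.0).mean() + dv.abs().mean()
    l_hor = (dh**2.0).mean() + dh.abs().mean()
    total = l_ver + l_hor
    return total, float(l_ver.data), float(l_hor.data)


def train(
    stacks: list[ImageStack] | ImageStack,
    mcfg: ModelConfig = ModelConfig(),
    tcfg: TrainConfig = TrainConfig(),
    outdir: str | Path | None = None,
) -> tuple[SRDTransNet, Checkpoint, list[dict]]:
    """Fit the transformer to one or more noisy stacks, self-supervised.

    Triplets (masks and patch origins) are redrawn every epoch.  One
    checkpoint per epoch is written to ``outdir`` (if given) as
    ``epoch_{k:03d}.ckpt`` together with a CSV training log; the final epoch
    is the designated inference model.

    Returns (model, final checkpoint, per-step log records).
    """
    if isinstance(stacks, ImageStack):
        stacks = [stacks]
    if not stacks:
        raise ValueError("empty stack list: nothing to train on")

    # z-score over all training stacks jointly; recorded for inversion
    all_vals = np.concatenate([s.data.ravel() for s in stacks])
    mean = float(all_vals.mean())
    std = float(all_vals.std())
    if std == 0:
        raise ValueError("training data is constant; nothing to learn")
    normed = [(s.data - mean) / std for s in stacks]

    model = SRDTransNet(mcfg)
    params = model.parameters()
    opt = Adam(params, lr=tcfg.lr, beta1=tcfg.beta1, beta2=tcfg.beta2)
    rng = np.random.default_rng(tcfg.seed)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    log: list[dict] = []
    step = 0
    ckpt = None
    for epoch in range(1, tcfg.epochs + 1):
        triplets = extract_training_pairs(
            normed, n_pairs=tcfg.n_pairs, patch_shape=tcfg.patch_shape,
            seed=int(rng.integers(2**31)),
        )
        if tcfg.augment:
            triplets = [augment_eightfold(t, int(rng.integers(8))) for t in triplets]
        for i in range(0, len(triplets), tcfg.batch_size):
            batch = triplets[i : i + tcfg.batch_size]
            s_c = np.stack([t.s_c for t in batch])  # (B, h/2, w/2, t)
            s_v = np.stack([t.s_v for t in batch])
            s_h = np.stack([t.s_h for t in batch])
            pred = model.forward(s_c)
            total, l_ver, l_hor = _loss_graph(pred, s_v, s_h)
            if not np.isfinite(total.data):
                raise FloatingPointError(f"non-finite loss at step {step} (epoch {epoch})")
            opt.zero_grad()
            total.backward()
            grad_norm = opt.grad_global_norm()
            opt.step()
            step += 1
            log.append(
                {"step": step, "epoch": epoch, "L_ver": l_ver, "L_hor": l_hor,
                 "L_total": l_ver + l_hor, "grad_norm": grad_norm}
            )
        ckpt = Checkpoint(config=mcfg, state=model.state(), norm_mean=mean, norm_std=std, epoch=epoch)
        if outdir is not None:
            save_checkpoint(ckpt, outdir / f"epoch_{epoch:03d}.ckpt")
    if outdir is not None:
        with open(outdir / "training_log.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
            writer.writeheader()
            writer.writerows(log)
    return model, ckpt, log
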