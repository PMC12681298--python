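"""Few-shot training protocol: pre-training on simulated acquisitions and
fine-tuning on a small measured set, with L1+SSIM loss, Adam, per-load mask
re-randomization and validation-based early stopping.

Everything is deterministic given (seed, config, data): per-item mask seeds
are derived from ``SeedSequence([seed, item_index, epoch])`` so "a fresh
mask each time a dataset is loaded" is reproducible across machines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import InvalidConfigError, TrainingDivergenceError
from .ksim import SamplingMask, SimulatedAcquisition, make_poisson_mask
from .mri_ops import ifftnc, rss
from .varnet.model import VarNetModel

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "loss_l1_ssim",
    "loss_l1_ssim_grad",
    "Adam",
    "pretrain",
    "finetune",
]

_SSIM_K1 = 0.01
_SSIM_K2 = 0.03


@dataclass
class TrainConfig:
    epochs: int = 50
    lr: float = 3e-4
    w_l1: float = 1.0
    w_ssim: float = 1.0
    R: float = 4.0
    calib: tuple[int, int] = (12, 6)
    early_stop_patience: int = 5
    seed: int = 0
    batch: int = 1
    ssim_window: int = 7

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise InvalidConfigError("lr must be > 0")
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")
        if self.R < 1:
            raise InvalidConfigError("R must be >= 1")


@dataclass
class Checkpoint:
    model: VarNetModel
    config: TrainConfig
    best_val_loss: float
    epoch: int
    history: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _ssim_stats(pred, target, win, data_range):
    def u(a):
        return uniform_filter(a, size=win, mode="constant")

    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    mx, my = u(pred), u(target)
    vx = u(pred * pred) - mx * mx
    vy = u(target * target) - my * my
    cxy = u(pred * target) - mx * my
    a1 = 2 * mx * my + c1
    a2 = 2 * cxy + c2
    b1 = mx * mx + my * my + c1
    b2 = vx + vy + c2
    s = (a1 * a2) / (b1 * b2)
    return s, (mx, my, a1, a2, b1, b2), u


def _effective_window(shape: tuple[int, ...], win: int) -> int:
    w = min(win, min(shape))
    if w % 2 == 0:
        w -= 1
    return max(w, 1)


def loss_l1_ssim(
    pred: np.ndarray,
    target: np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
    window: int = 7,
) -> float:
    """``w_l1 * mean|p - t| + w_ssim * (1 - SSIM(p, t))``; zero iff equal.

    SSIM uses a uniform window (zero-padded borders) with the standard
    constants and ``data_range = max(target)``.
    """
    w_l1, w_ssim = weights
    dr = float(np.max(target))
    if dr <= 0:
        dr = 1.0
    win = _effective_window(pred.shape, window)
    s, _, _ = _ssim_stats(pred, target, win, dr)
    return float(w_l1 * np.mean(np.abs(pred - target)) + w_ssim * (1.0 - np.mean(s)))


def loss_l1_ssim_grad(
    pred: np.ndarray,
    target: np.ndarray,
    weights: tuple[float, float] = (1.0, 1.0),
    window: int = 7,
) -> tuple[float, np.ndarray]:
    """Loss value and its exact gradient w.r.t. ``pred``."""
    w_l1, w_ssim = weights
    dr = float(np.max(target))
    if dr <= 0:
        dr = 1.0
    win = _effective_window(pred.shape, window)
    s, (mx, my, a1, a2, b1, b2), u = _ssim_stats(pred, target, win, dr)
    n = pred.size
    loss = float(w_l1 * np.mean(np.abs(pred - target)) + w_ssim * (1.0 - np.mean(s)))

    # partials of the per-voxel SSIM map w.r.t. the local statistics
    d = b1 * b2
    gm = (2 * my * a2) / d - s * (2 * mx) / b1
    gv = -s / b2
    gc = 2 * a1 / d
    # chain through mx = U p, vx = U(p^2) - mx^2, cxy = U(pt) - mx my
    # (U with zero padding is self-adjoint)
    ds_dp = (
        u(gm)
        + 2 * pred * u(gv)
        - 2 * u(gv * mx)
        + target * u(gc)
        - u(gc * my)
    )
    grad = w_l1 * np.sign(pred - target) / n - w_ssim * ds_dp / n
    return loss, grad


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=3e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _mask_seed(seed: int, item: int, epoch: int) -> int:
    return int(np.random.SeedSequence([seed, item, epoch + 1]).generate_state(1)[0])


def _draw_mask(acq: SimulatedAcquisition, cfg: TrainConfig, seed: int) -> SamplingMask:
    _, ny, nz = acq.shape
    calib = (min(cfg.calib[0], ny), min(cfg.calib[1], nz))
    return SamplingMask(
        pe_mask=make_poisson_mask(ny, nz, cfg.R, calib=calib, seed=seed),
        pf_mask=acq.mask.pf_mask,  # PF is part of the acquisition, fixed
        calib_extent=calib,
        target_R=cfg.R,
    )


def _prepare(acq: SimulatedAcquisition, mask: SamplingMask):
    """Undersample + per-item normalization (zero-filled RSS max -> 1)."""
    pattern = mask.combined().astype(bool)[None]
    k = np.where(pattern, acq.kspace, 0.0)
    zf = rss(ifftnc(k, axes=(-3, -2, -1)))
    scale = float(zf.max())
    if scale <= 0:
        scale = 1.0
    target = np.abs(acq.truth_image) / scale
    return k / scale, target, scale


def _item_loss(model, acq, mask, cfg, train: bool):
    k, target, _ = _prepare(acq, mask)
    pred = model.forward(k, mask, train=train)
    if train:
        loss, grad = loss_l1_ssim_grad(pred, target, (cfg.w_l1, cfg.w_ssim), cfg.ssim_window)
        model.backward(grad)
    else:
        loss = loss_l1_ssim(pred, target, (cfg.w_l1, cfg.w_ssim), cfg.ssim_window)
    return loss


def _validate(model, val_items, cfg) -> float:
    losses = [
        _item_loss(model, acq, _draw_mask(acq, cfg, _mask_seed(cfg.seed, i, -1)), cfg, False)
        for i, acq in enumerate(val_items)
    ]
    return float(np.mean(losses))


def _snapshot(model) -> list[np.ndarray]:
    return [p.value.copy() for p in model.param_list()]


def _restore(model, weights) -> None:
    for p, w in zip(model.param_list(), weights):
        p.value = w.copy()


def _train_loop(
    model: VarNetModel,
    train_items: list[SimulatedAcquisition],
    val_items: list[SimulatedAcquisition],
    cfg: TrainConfig,
    val_loss_override=None,
) -> Checkpoint:
    if not train_items or not val_items:
        raise InvalidConfigError("need at least one training and one validation item")
    opt = Adam(model.param_list(), lr=cfg.lr)
    history = {"train": [], "val": []}

    val0 = _validate(model, val_items, cfg)
    history["val"].append(val0)
    best_val, best_epoch, best_weights = val0, 0, _snapshot(model)
    since_best = 0

    for epoch in range(1, cfg.epochs + 1):
        order = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 917, epoch])
        ).permutation(len(train_items))
        epoch_losses = []
        for idx in order:
            acq = train_items[int(idx)]
            mask = _draw_mask(acq, cfg, _mask_seed(cfg.seed, int(idx), epoch))
            opt.zero_grad()
            loss = _item_loss(model, acq, mask, cfg, train=True)
            if not math.isfinite(loss):
                raise TrainingDivergenceError(f"non-finite loss at epoch {epoch}", epoch=epoch)
            opt.step()
            epoch_losses.append(loss)
        history["train"].append(float(np.mean(epoch_losses)))

        val = _validate(model, val_items, cfg)
        if val_loss_override is not None:
            val = float(val_loss_override(epoch, val))
        history["val"].append(val)
        if val < best_val:
            best_val, best_epoch, best_weights = val, epoch, _snapshot(model)
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break

    _restore(model, best_weights)
    return Checkpoint(
        model=model, config=cfg, best_val_loss=best_val, epoch=best_epoch, history=history
    )


def pretrain(
    model: VarNetModel,
    train_items: list[SimulatedAcquisition],
    val_items: list[SimulatedAcquisition],
    cfg: TrainConfig,
    val_loss_override=None,
) -> Checkpoint:
    """Pre-train on simulated acquisitions: per (item, epoch) a fresh seeded
    Poisson mask is drawn, the item undersampled, and one Adam step taken;
    the best-validation checkpoint is returned."""
    return _train_loop(model, train_items, val_items, cfg, val_loss_override)


def finetune(
    checkpoint: Checkpoint | VarNetModel,
    train_items: list[SimulatedAcquisition],
    val_items: list[SimulatedAcquisition],
    cfg: TrainConfig,
    val_loss_override=None,
) -> Checkpoint:
    """Identical loop to :func:`pretrain`, warm-started from ``checkpoint``.

    The initial weights are scored on validation first (epoch-0 entry of the
    history), so the returned best checkpoint never regresses below its own
    initialization.
    """
    model = checkpoint.model if isinstance(checkpoint, Checkpoint) else checkpoint
    return _train_loop(model, train_items, val_items, cfg, val_loss_override)
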