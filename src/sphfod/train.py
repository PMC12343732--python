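"""Spatial-domain loss, intensity normalization, and the training loop."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import sphharm
from .model import MLP, Module
from .nn import AdamW, StepLR, Tensor, clip_grad_norm

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "spatial_mse_loss",
    "train_model",
    "normalize_intensity",
]


def spatial_mse_loss(pred, target, sampling: sphharm.SphereSampling):
    """Mean squared amplitude difference after projecting SH onto the sphere.

    ``loss = 1/(N*B) * sum_ij (U p_i - U t_i)_j^2`` over a batch of B
    coefficient vectors and the sampling's N points.  Accepts autograd tensors
    (for training) or plain arrays (returns a float).
    """
    is_tensor = isinstance(pred, Tensor)
    p = pred if is_tensor else Tensor(np.asarray(pred, dtype=float))
    t = target if isinstance(target, Tensor) else Tensor(np.asarray(target))
    if p.shape != t.shape:
        raise ValueError(f"pred shape {p.shape} != target shape {t.shape}")
    if p.shape[-1] != sampling.n_coeffs:
        raise ValueError(
            f"coefficient length {p.shape[-1]} != basis size {sampling.n_coeffs}"
        )
    Ut = sampling.U.T.astype(p.dtype, copy=False)
    diff = (p - t) @ Ut
    loss = (diff * diff).mean()
    return loss if is_tensor else float(loss.data)


@dataclass
class TrainConfig:
    """Optimization hyperparameters (AdamW, step schedule, clipping)."""

    lr: float = 1e-4
    weight_decay: float = 1e-4
    lr_step_epochs: int = 17
    lr_gamma: float = 0.5
    grad_clip_max_norm: float = 10.0
    epochs: int = 80
    batch_size: int = 4096
    batch_multiplier: int = 1  # >1 repeats the training pass (MLP recipe: 5)
    seed: int = 0
    loss_points: int = 724
    loss_scheme: str = "fibonacci"

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.grad_clip_max_norm <= 0:
            raise ValueError("grad clip norm must be positive")


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    grad_norm_max: list[float] = field(default_factory=list)
    grad_norm_mean: list[float] = field(default_factory=list)

    def to_csv(self, path) -> None:
        rows = zip(self.epoch, self.train_loss, self.val_loss, self.lr,
                   self.grad_norm_max, self.grad_norm_mean)
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,val_loss,lr,grad_norm_max,grad_norm_mean\n")
            for r in rows:
                fh.write(",".join(f"{v:.10g}" for v in r) + "\n")


def _as_model_input(model: Module, X: np.ndarray) -> np.ndarray:
    if isinstance(model, MLP) and X.ndim == 3:
        return X.reshape(X.shape[0], -1)
    return X


def train_model(
    model: Module,
    train_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    val_data: tuple[np.ndarray, np.ndarray] | None = None,
    sampling: sphharm.SphereSampling | None = None,
    verbose: bool = False,
) -> tuple[Module, TrainHistory]:
    """Optimize ``model`` with AdamW, gradient clipping and the step schedule.

    ``train_data``/``val_data`` are (inputs, target SH) array pairs.  Gradient
    clipping is applied before every optimizer step; the learning rate is
    multiplied by ``lr_gamma`` every ``lr_step_epochs`` epochs.  Fixed
    ``config.seed`` makes shuffling (and hence the whole run) reproducible.
    """
    X, y = train_data
    X = _as_model_input(model, np.asarray(X))
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training dataset")
    if X.shape[0] != y.shape[0]:
        raise ValueError("inputs and targets disagree on the number of voxels")
    if sampling is None:
        sampling = sphharm.make_sampling(config.loss_points, config.loss_scheme)
    rng = np.random.default_rng(config.seed)
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    sched = StepLR(opt, step_size=config.lr_step_epochs, gamma=config.lr_gamma)
    history = TrainHistory()
    dtype = model.parameters()[0].dtype
    Xc = X.astype(dtype, copy=False)
    yc = y.astype(dtype, copy=False)
    for epoch in range(config.epochs):
        model.train()
        lr_now = opt.lr
        losses, norms = [], []
        for _ in range(config.batch_multiplier):
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], config.batch_size):
                idx = order[start : start + config.batch_size]
                pred = model(Tensor(Xc[idx]))
                loss = spatial_mse_loss(pred, Tensor(yc[idx]), sampling)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {float(loss.data)}"
                    )
                opt.zero_grad()
                loss.backward()
                norms.append(clip_grad_norm(model.parameters(), config.grad_clip_max_norm))
                opt.step()
                losses.append(float(loss.data))
        model.eval()
        if val_data is not None:
            Xv = _as_model_input(model, np.asarray(val_data[0])).astype(dtype, copy=False)
            pv = np.concatenate(
                [
                    model(Tensor(Xv[i : i + config.batch_size])).data
                    for i in range(0, Xv.shape[0], config.batch_size)
                ]
            )
            vloss = spatial_mse_loss(pv, np.asarray(val_data[1]), sampling)
        else:
            vloss = float("nan")
        history.epoch.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(float(vloss))
        history.lr.append(lr_now)
        history.grad_norm_max.append(float(np.max(norms)))
        history.grad_norm_mean.append(float(np.mean(norms)))
        sched.step()
        if verbose:
            print(
                f"epoch {epoch:3d}  train {history.train_loss[-1]:.6f}  "
                f"val {vloss:.6f}  lr {lr_now:.2e}"
            )
    return model, history


def normalize_intensity(values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Zero negatives, then clip above the 95th percentile of the masked data.

    The percentile uses the 'higher' order statistic so the clip level is an
    actual data value; at most 5% of entries are altered by the clip.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    out = np.where(values < 0, 0.0, values)
    sel = out[mask.astype(bool)] if mask is not None else out
    if not np.any(sel != 0):
        warnings.warn("all-zero input; normalization is a no-op", stacklevel=2)
        return out
    q95 = np.quantile(sel, 0.95, method="higher")
    return np.minimum(out, q95)
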