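"""Equivariant spherical convolution layers, shell attention, sCNN and MLP.

Features are stored as ``(batch, channels, K)`` arrays of even-degree SH
coefficients.  The spherical convolution applies one learnable scalar weight
per (output channel, input channel, degree), broadcast over all orders ``m``
of that degree, which commutes exactly with SH-domain rotations.  The
nonlinearity maps coefficients to amplitudes on a fixed sphere sampling,
applies a Leaky ReLU, and projects back (approximately equivariant).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from . import sphharm
from .nn import (
    BatchNorm1d,
    Linear,
    Module,
    Parameter,
    Tensor,
    concat,
    leaky_relu,
    relu,
    softmax,
)
from .nn.autograd import custom_op

__all__ = [
    "EquivariantConv",
    "SHNonlinearity",
    "ShellAttention",
    "SCNNConfig",
    "SCNN",
    "MLPConfig",
    "MLP",
    "save_checkpoint",
    "load_checkpoint",
]


class EquivariantConv(Module):
    """SH-domain spherical convolution with degree-wise scalar weights.

    Weight tensor shape is ``[L, C_in, C_out]`` with ``L`` the number of even
    degrees; a degree-expansion index broadcasts each scalar to all ``m`` of
    its degree.  An optional bias acts on the ``l = 0`` coefficient only (any
    other bias would break equivariance).  A residual connection is applied
    automatically when ``C_in == C_out``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        lmax: int,
        rng: np.random.Generator,
        bias: bool = True,
        residual: bool = True,
        dtype=np.float64,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.lmax = lmax
        self.deg_index = np.searchsorted(
            sphharm.sh_degrees(lmax), sphharm.degree_of_index(lmax)
        )
        L = len(sphharm.sh_degrees(lmax))
        # He-style: each output coefficient sums over C_in terms (degrees do
        # not mix), so Var(W) ~ 2/C_in keeps activations from collapsing
        scale = np.sqrt(6.0 / in_channels)
        self.W = Parameter(
            rng.uniform(-scale, scale, (L, in_channels, out_channels)).astype(dtype)
        )
        self.b = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.residual = residual and in_channels == out_channels
        K = sphharm.n_coeffs(lmax)
        self._l0_mask = np.zeros(K, dtype=dtype)
        self._l0_mask[0] = 1.0

    def _degree_slices(self) -> list[slice]:
        out, k = [], 0
        for l in sphharm.sh_degrees(self.lmax):
            out.append(slice(k, k + 2 * l + 1))
            k += 2 * l + 1
        return out

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected (B, {self.in_channels}, K) input, got {x.shape}"
            )
        if x.shape[2] != len(self.deg_index):
            raise ValueError(f"K = {x.shape[2]} does not match lmax = {self.lmax}")
        # fused degree-wise contraction: y[b,o,k] = sum_i W[l(k),i,o] x[b,i,k]
        xd, W = x.data, self.W.data
        B, Ci, K = xd.shape
        Co = self.out_channels
        slices = self._degree_slices()
        y = np.empty((B, Co, K), dtype=xd.dtype)
        x_l = []
        for l, sl in enumerate(slices):
            w = sl.stop - sl.start
            xl = np.ascontiguousarray(xd[:, :, sl].transpose(0, 2, 1)).reshape(-1, Ci)
            x_l.append(xl)  # kept for the weight gradient
            y[:, :, sl] = (xl @ W[l]).reshape(B, w, Co).transpose(0, 2, 1)
        if self.b is not None:
            y[:, :, 0] += self.b.data
        if self.residual:
            y += xd

        def backward(g):
            if self.W.requires_grad:
                gW = np.empty_like(W)
            gx = np.empty_like(xd) if x.requires_grad else None
            for l, sl in enumerate(slices):
                w = sl.stop - sl.start
                gl = np.ascontiguousarray(g[:, :, sl].transpose(0, 2, 1)).reshape(-1, Co)
                if self.W.requires_grad:
                    gW[l] = x_l[l].T @ gl
                if gx is not None:
                    gx[:, :, sl] = (gl @ W[l].T).reshape(B, w, Ci).transpose(0, 2, 1)
            if self.W.requires_grad:
                self.W._accumulate(gW)
            if self.b is not None and self.b.requires_grad:
                self.b._accumulate(g[:, :, 0].sum(axis=0))
            if gx is not None:
                if self.residual:
                    gx += g
                x._accumulate(gx)

        return custom_op(y, (x, self.W) + ((self.b,) if self.b is not None else ()),
                         backward)


class SHNonlinearity(Module):
    """ISFT -> Leaky ReLU -> SFT nonlinearity on a fixed sphere sampling."""

    def __init__(self, sampling: sphharm.SphereSampling, negative_slope: float = 0.1,
                 dtype=np.float64):
        super().__init__()
        self.negative_slope = negative_slope
        self._Ut = np.ascontiguousarray(sampling.U.T, dtype=dtype)
        self._Pt = np.ascontiguousarray(sampling.U_pinv.T, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        # fused ISFT -> LeakyReLU -> SFT with flat (B*C, .) gemms
        xd = x.data
        lead = xd.shape[:-1]
        K = xd.shape[-1]
        amp = xd.reshape(-1, K) @ self._Ut
        slope = xd.dtype.type(self.negative_slope)
        neg = amp <= 0  # boolean mask is 4x smaller than a float one
        np.multiply(amp, slope, where=neg, out=amp)
        out = (amp @ self._Pt).reshape(*lead, K)

        def backward(g):
            ga = g.reshape(-1, K) @ self._Pt.T
            np.multiply(ga, slope, where=neg, out=ga)
            x._accumulate((ga @ self._Ut.T).reshape(xd.shape))

        return custom_op(out, (x,), backward)


class ShellAttention(Module):
    """Softmax gating over the three b-value shells.

    Per-shell feature maps are mean-pooled over the SH axis, concatenated into
    a 48-vector, passed through a 48 -> 24 -> 3 feedforward network
    (Leaky ReLU slope 0.1), and softmax-normalized into simplex weights that
    multiply each shell's features before concatenation.
    """

    def __init__(self, channels: int, rng: np.random.Generator, hidden: int = 24,
                 n_shells: int = 3, dtype=np.float64):
        super().__init__()
        self.channels = channels
        self.n_shells = n_shells
        self.fc1 = Linear(n_shells * channels, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, n_shells, rng, dtype=dtype)

    def pool(self, shells: list[Tensor]) -> Tensor:
        """Global average pooling across the SH dimension, then concat."""
        return concat([s.mean(axis=2) for s in shells], axis=1)  # (B, 48)

    def weights(self, shells: list[Tensor]) -> Tensor:
        z = self.pool(shells)
        logits = self.fc2(leaky_relu(self.fc1(z), 0.1))
        return softmax(logits, axis=1)  # (B, n_shells) on the simplex

    def forward(self, shells: list[Tensor]) -> tuple[Tensor, Tensor]:
        if len(shells) != self.n_shells:
            raise ValueError(f"expected {self.n_shells} shell feature maps")
        for s in shells:
            if s.shape[1] != self.channels:
                raise ValueError(
                    f"expected {self.channels}-channel shell features, got {s.shape[1]}"
                )
        a = self.weights(shells)
        weighted = [
            s * a[:, i].reshape(-1, 1, 1) for i, s in enumerate(shells)
        ]
        return a, concat(weighted, axis=1)  # (B, n_shells * channels, K)


@dataclass
class SCNNConfig:
    lmax: int = 8
    n_shells: int = 3
    shell_channels: int = 16
    encoder_channels: tuple[int, ...] = (16, 32, 64)
    head_hidden: tuple[int, ...] = (128, 64)
    attention_hidden: int = 24
    nonlin_points: int = 724
    nonlin_scheme: str = "fibonacci"
    negative_slope: float = 0.1
    dtype: str = "float64"

    @property
    def n_coeffs(self) -> int:
        return sphharm.n_coeffs(self.lmax)


class SCNN(Module):
    """Shell-attention spherical CNN mapping per-shell SH stacks to FOD SH.

    Pipeline: per-shell equivariant conv (1 -> 16 channels) with nonlinearity,
    attention-weighted fusion (48 channels), fusing conv 48 -> 16, residual
    16 -> 16 conv, encoder convs 16 -> 32 -> 64, symmetric decoder
    64 -> 32 -> 16, then a fully connected head with batch normalization and
    ReLU producing the 45 output coefficients.
    """

    def __init__(self, config: SCNNConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config = config or SCNNConfig()
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype).type
        K = config.n_coeffs
        sampling = sphharm.make_sampling(
            config.nonlin_points, config.nonlin_scheme, config.lmax
        )
        ch = config.shell_channels

        def conv(cin, cout):
            return EquivariantConv(cin, cout, config.lmax, rng, dtype=dtype)

        self.nonlin = SHNonlinearity(sampling, config.negative_slope, dtype=dtype)
        self.shell_convs = [conv(1, ch) for _ in range(config.n_shells)]
        self.attention = ShellAttention(
            ch, rng, hidden=config.attention_hidden, n_shells=config.n_shells,
            dtype=dtype,
        )
        self.fuse = conv(config.n_shells * ch, config.encoder_channels[0])
        self.res = conv(config.encoder_channels[0], config.encoder_channels[0])
        enc = config.encoder_channels
        self.encoder = [conv(enc[i], enc[i + 1]) for i in range(len(enc) - 1)]
        dec = tuple(reversed(enc))
        self.decoder = [conv(dec[i], dec[i + 1]) for i in range(len(dec) - 1)]
        sizes = [enc[0] * K, *config.head_hidden]
        self.head_fc = [
            Linear(sizes[i], sizes[i + 1], rng, dtype=dtype)
            for i in range(len(sizes) - 1)
        ]
        self.head_bn = [BatchNorm1d(h, dtype=dtype) for h in config.head_hidden]
        self.head_out = Linear(sizes[-1], K, rng, dtype=dtype)
        self._dtype = dtype

    def forward(self, ms: Tensor | np.ndarray) -> Tensor:
        """(B, n_shells, K) multi-shell SH -> (B, K) FOD SH."""
        if not isinstance(ms, Tensor):
            ms = Tensor(np.asarray(ms, dtype=self._dtype))
        cfg = self.config
        if ms.ndim != 3 or ms.shape[1] != cfg.n_shells or ms.shape[2] != cfg.n_coeffs:
            raise ValueError(
                f"expected (B, {cfg.n_shells}, {cfg.n_coeffs}) input, got {ms.shape}"
            )
        shells = [
            self.nonlin(self.shell_convs[i](ms[:, i : i + 1, :]))
            for i in range(cfg.n_shells)
        ]
        _, fused = self.attention(shells)
        h = self.nonlin(self.fuse(fused))
        h = self.nonlin(self.res(h))
        for layer in self.encoder:
            h = self.nonlin(layer(h))
        for layer in self.decoder:
            h = self.nonlin(layer(h))
        h = h.reshape(h.shape[0], -1)
        for fc, bn in zip(self.head_fc, self.head_bn):
            h = relu(bn(fc(h)))
        return self.head_out(h)

    def predict(self, ms: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Evaluation-mode forward pass returning a numpy array."""
        self.eval()
        ms = np.asarray(ms, dtype=self._dtype)
        out = [
            self.forward(ms[i : i + batch_size]).data
            for i in range(0, ms.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)


@dataclass
class MLPConfig:
    in_features: int = 135  # three shells x 45 SH coefficients, flattened
    hidden: int = 256
    n_hidden_layers: int = 4
    out_features: int = 45
    dtype: str = "float64"


class MLP(Module):
    """Baseline: 4 fully connected layers (256 units, batch norm, ReLU)."""

    def __init__(self, config: MLPConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config = config or MLPConfig()
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype).type
        sizes = [config.in_features] + [config.hidden] * config.n_hidden_layers
        self.fcs = [
            Linear(sizes[i], sizes[i + 1], rng, dtype=dtype)
            for i in range(len(sizes) - 1)
        ]
        self.bns = [BatchNorm1d(config.hidden, dtype=dtype)
                    for _ in range(config.n_hidden_layers)]
        self.out = Linear(config.hidden, config.out_features, rng, dtype=dtype)
        self._dtype = dtype

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self._dtype))
        if x.ndim == 3:  # accept (B, n_shells, K) stacks and flatten
            x = x.reshape(x.shape[0], -1)
        if x.shape[1] != self.config.in_features:
            raise ValueError(
                f"expected input length {self.config.in_features}, got {x.shape[1]}"
            )
        for fc, bn in zip(self.fcs, self.bns):
            x = relu(bn(fc(x)))
        return self.out(x)

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        self.eval()
        x = np.asarray(x, dtype=self._dtype)
        out = [
            self.forward(x[i : i + batch_size]).data
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)


_MODEL_KINDS = {"scnn": (SCNN, SCNNConfig), "mlp": (MLP, MLPConfig)}


def save_checkpoint(model: Module, path: str) -> None:
    """Save config + parameters (+ batch-norm buffers) to a single .npz file."""
    if isinstance(model, SCNN):
        kind = "scnn"
    elif isinstance(model, MLP):
        kind = "mlp"
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    cfg = asdict(model.config)
    for key in ("encoder_channels", "head_hidden"):
        if key in cfg:
            cfg[key] = list(cfg[key])  # tuples do not round-trip through YAML
    meta = yaml.safe_dump({"kind": kind, "config": cfg})
    state = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path: str) -> Module:
    with np.load(path) as z:
        meta = yaml.safe_load(bytes(z["meta"]).decode())
        state = {k[len("state/"):]: z[k] for k in z.files if k.startswith("state/")}
    cls, cfg_cls = _MODEL_KINDS[meta["kind"]]
    cfg = meta["config"]
    for key in ("encoder_channels", "head_hidden"):
        if key in cfg:
            cfg[key] = tuple(cfg[key])
    model = cls(cfg_cls(**cfg))
    model.load_state_dict(state)
    return model
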