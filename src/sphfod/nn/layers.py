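"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, custom_op, relu

__all__ = ["Parameter", "Module", "Linear", "BatchNorm1d", "Sequential", "ReLU"]


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = []
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((full, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(f"{full}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def _apply_mode(self, training: bool) -> None:
        self.training = training
        for _, val in vars(self).items():
            if isinstance(val, Module):
                val._apply_mode(training)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item._apply_mode(training)

    def train(self) -> "Module":
        self._apply_mode(True)
        return self

    def eval(self) -> "Module":
        self._apply_mode(False)
        return self

    # -- checkpoint support ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update(self._buffers())
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = self._buffer_refs()
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = value.astype(params[name].data.dtype, copy=True)
            elif name in buffers:
                obj, attr = buffers[name]
                setattr(obj, attr, np.asarray(value).copy())
            else:
                raise KeyError(f"unexpected key {name} in state dict")

    def _buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, (obj, attr) in self._buffer_refs(prefix).items():
            out[name] = np.asarray(getattr(obj, attr)).copy()
        return out

    def _buffer_refs(self, prefix: str = "") -> dict[str, tuple["Module", str]]:
        out = {}
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Module):
                out.update(val._buffer_refs(f"{full}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item._buffer_refs(f"{full}.{i}."))
        if isinstance(self, BatchNorm1d):
            out[f"{prefix}running_mean"] = (self, "running_mean")
            out[f"{prefix}running_var"] = (self, "running_var")
        return out


class Linear(Module):
    """Dense layer with Kaiming-uniform initialization."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float64):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.W = Parameter(rng.uniform(-bound, bound, (in_features, out_features)).astype(dtype))
        self.b = Parameter(np.zeros(out_features, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        out = xd @ self.W.data
        out += self.b.data

        def backward(g):
            if self.W.requires_grad:
                self.W._accumulate(xd.T @ g)
            if self.b.requires_grad:
                self.b._accumulate(g.sum(axis=0))
            if x.requires_grad:
                x._accumulate(g @ self.W.data.T)

        return custom_op(out, (x, self.W, self.b), backward)


class BatchNorm1d(Module):
    """Batch normalization over the leading (batch) axis of (B, F) inputs."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        if self.training:
            n = xd.shape[0]
            mu = xd.mean(axis=0)
            xc = xd - mu
            var = np.mean(xc * xc, axis=0)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var * (n / max(n - 1, 1))
            )
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = xc * inv
            out = xhat * self.gamma.data + self.beta.data

            def backward(g):
                if self.gamma.requires_grad:
                    self.gamma._accumulate(np.sum(g * xhat, axis=0))
                if self.beta.requires_grad:
                    self.beta._accumulate(g.sum(axis=0))
                if x.requires_grad:
                    gxhat = g * self.gamma.data
                    # standard batch-norm gradient through mu and var
                    gx = (
                        gxhat
                        - gxhat.mean(axis=0)
                        - xhat * np.mean(gxhat * xhat, axis=0)
                    ) * inv
                    x._accumulate(gx)

            return custom_op(out, (x, self.gamma, self.beta), backward)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean) * inv
        return xhat * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)
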