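"""Neural-network building blocks on top of the autograd engine.

Conventions follow the common deep-learning frameworks: batch-norm keeps
running statistics with momentum 0.1 and eps 1e-5, dropout uses inverted
scaling, and weights get fan-based uniform (Glorot) initialization from a
seeded generator.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv1d

DTYPE = np.float32


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Module:
    """Base class: parameter/buffer registry, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True
        self._buffer_names: list[str] = []

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = ""):
        state = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        state.update(self._named_buffers(prefix))
        return state

    def _named_buffers(self, prefix: str = ""):
        out = {}
        for name in self._buffer_names:
            out[prefix + name] = getattr(self, name).copy()
        for name, child in self._children():
            out.update(child._named_buffers(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = self._named_buffers()
        missing = (set(params) | set(buffers)) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")
        for name, p in params.items():
            p.data = np.array(state[name], dtype=p.data.dtype)
        self._load_buffers(state, "")

    def _load_buffers(self, state: dict, prefix: str):
        for name in self._buffer_names:
            setattr(self, name, np.array(state[prefix + name]))
        for name, child in self._children():
            child._load_buffers(state, prefix + name + ".")


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True, bias_init: float = 0.0):
        super().__init__()
        self.weight = Tensor(
            glorot_uniform(rng, (in_features, out_features), in_features, out_features),
            requires_grad=True,
        )
        self.bias = None
        if bias:
            self.bias = Tensor(
                np.full(out_features, bias_init, dtype=DTYPE), requires_grad=True
            )

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class ConvTime(Module):
    """1-D convolution along the time axis of (N, depth, T) maps.

    padding: "same" (stride-1 length-preserving) or "causal" (left-only, so
    output at time t depends on inputs at times <= t).
    """

    def __init__(self, in_depth: int, out_depth: int, kernel: int,
                 rng: np.random.Generator, padding: str = "same",
                 dilation: int = 1, groups: int = 1):
        super().__init__()
        fan_in = (in_depth // groups) * kernel
        fan_out = (out_depth // groups) * kernel
        self.weight = Tensor(
            glorot_uniform(rng, (out_depth, in_depth // groups, kernel), fan_in, fan_out),
            requires_grad=True,
        )
        self.kernel = kernel
        self.dilation = dilation
        self.groups = groups
        span = (kernel - 1) * dilation
        if padding == "same":
            self.pad_left, self.pad_right = span // 2, span - span // 2
        elif padding == "causal":
            self.pad_left, self.pad_right = span, 0
        elif padding == "valid":
            self.pad_left = self.pad_right = 0
        else:
            raise ValueError(f"unknown padding {padding!r}")

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(
            x, self.weight, dilation=self.dilation,
            pad_left=self.pad_left, pad_right=self.pad_right, groups=self.groups,
        )


class BatchNorm(Module):
    """Batch normalization over all axes except axis 1 (the depth axis)."""

    def __init__(self, depth: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(depth, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(depth, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(depth, dtype=DTYPE)
        self.running_var = np.ones(depth, dtype=DTYPE)
        self._buffer_names = ["running_mean", "running_var"]
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        from .tensor import fused_norm

        running = None
        if not self.training:
            running = (
                self.running_mean.reshape(shape),
                self.running_var.reshape(shape),
            )
        out, mu, var = fused_norm(
            x, self.gamma.reshape(shape), self.beta.reshape(shape),
            axes, self.eps, running,
        )
        if self.training:
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.reshape(-1)
        return out


class LayerNorm(Module):
    """Normalization over the trailing (embedding) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        from .tensor import fused_norm

        out, _, _ = fused_norm(x, self.gamma, self.beta, (-1,), self.eps)
        return out


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Draws masks from `rng`."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * Tensor(mask)


def avg_pool_time(x: Tensor, width: int) -> Tensor:
    """Average pooling with kernel = stride = width along the last axis.

    Trailing samples that do not fill a window are dropped (floor division),
    so an input of length T yields T // width output steps.
    """
    t = x.shape[-1]
    t_out = t // width
    if t_out < 1:
        raise ValueError(f"time extent {t} shorter than pool width {width}")
    x = x[..., : t_out * width]
    return x.reshape(x.shape[:-1] + (t_out, width)).mean(axis=-1)
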