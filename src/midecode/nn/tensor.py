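"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

Only the operations needed by the decoder are implemented: broadcasting
arithmetic, (batched) matrix products, a generic two-operand einsum, a
grouped/dilated 1-D convolution primitive, reductions, shape manipulation,
and the ELU nonlinearity. Gradients of every primitive are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(x, like: "Tensor | None" = None) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        # keep python scalars from silently promoting float32 graphs to float64
        if like is not None and isinstance(x, (int, float)):
            return Tensor(np.asarray(x, dtype=like.data.dtype))
        return Tensor(np.asarray(x))

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg

    # -- basic properties ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other, self)
        a, b = self, other
        return Tensor._make(
            a.data + b.data,
            (a, b),
            lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._wrap(other, self))

    def __rsub__(self, other):
        return Tensor._wrap(other, self) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other, self)
        a, b = self, other
        return Tensor._make(
            a.data * b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other, self)
        a, b = self, other
        return Tensor._make(
            a.data / b.data,
            (a, b),
            lambda g: (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return Tensor._wrap(other, self) / self

    def __pow__(self, exponent: float):
        a = self
        return Tensor._make(
            a.data**exponent,
            (a,),
            lambda g: (g * exponent * a.data ** (exponent - 1),),
        )

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def elu(self, alpha: float = 1.0):
        x = self.data
        neg = alpha * (np.exp(np.minimum(x, 0.0)) - 1.0)
        out_data = np.where(x > 0, x, neg)
        dx = np.where(x > 0, 1.0, neg + alpha)
        return Tensor._make(out_data, (self,), lambda g: (g * dx,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                return (np.broadcast_to(g, a.data.shape).copy(),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.data.shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor._make(
            self.data.reshape(shape), (a,), lambda g: (g.reshape(a.data.shape),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (a,), bwd)


# -- n-ary / free-function primitives -----------------------------------------


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )


def einsum2(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with automatically derived backward contractions.

    Valid whenever each input index also appears in the output or the other
    operand (true for all contractions used here).
    """
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    ins, out = spec.replace(" ", "").split("->")
    sa, sb = ins.split(",")
    for s_in, s_other in ((sa, sb), (sb, sa)):
        missing = set(s_in) - set(out) - set(s_other)
        if missing:
            raise ValueError(f"einsum2 cannot differentiate spec {spec!r}: {missing}")

    def bwd(g):
        ga = np.einsum(f"{out},{sb}->{sa}", g, b.data, optimize=True)
        gb = np.einsum(f"{out},{sa}->{sb}", g, a.data, optimize=True)
        return ga, gb

    return Tensor._make(
        np.einsum(spec, a.data, b.data, optimize=True), (a, b), bwd
    )


def _window_view(xp: np.ndarray, k: int, dilation: int) -> np.ndarray:
    """Read-only sliding view (N, C, T_out, K) over the last axis of xp."""
    n, c, tp = xp.shape
    t_out = tp - (k - 1) * dilation
    s0, s1, s2 = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, t_out, k), strides=(s0, s1, s2, s2 * dilation), writeable=False
    )


def conv1d(
    x: Tensor,
    w: Tensor,
    dilation: int = 1,
    pad_left: int = 0,
    pad_right: int = 0,
    groups: int = 1,
) -> Tensor:
    """Grouped, dilated 1-D convolution (cross-correlation), stride 1, no bias.

    x: (N, C_in, T), w: (C_out, C_in // groups, K) -> (N, C_out, T_out) with
    T_out = T + pad_left + pad_right - (K - 1) * dilation.
    """
    x, w = Tensor._wrap(x), Tensor._wrap(w)
    n, c_in, t = x.data.shape
    c_out, c_ing, k = w.data.shape
    if c_in % groups or c_out % groups or c_ing != c_in // groups:
        raise ValueError(
            f"conv1d group mismatch: x depth {c_in}, kernel {w.data.shape}, groups {groups}"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad_left, pad_right)))
    view = _window_view(xp, k, dilation)  # (N, C_in, T_out, K)
    t_out = view.shape[2]

    if groups == 1:
        # im2col GEMM: (N*T_out, C_in*K) @ (C_in*K, C_out)
        col = np.ascontiguousarray(view.transpose(0, 2, 1, 3)).reshape(
            n * t_out, c_in * k
        )
        wmat = w.data.reshape(c_out, c_in * k)
        out = (col @ wmat.T).reshape(n, t_out, c_out).transpose(0, 2, 1)

        def bwd(g):
            gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(n * t_out, c_out)
            gw = (gmat.T @ col).reshape(w.data.shape)
            gcol = (gmat @ wmat).reshape(n, t_out, c_in, k).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            for tap in range(k):
                gxp[:, :, tap * dilation : tap * dilation + t_out] += gcol[..., tap]
            return gxp[:, :, pad_left : pad_left + t], gw

        return Tensor._make(out, (x, w), bwd)

    vg = np.ascontiguousarray(view).reshape(n, groups, c_ing, t_out, k)
    wg = w.data.reshape(groups, c_out // groups, c_ing, k)
    out = np.einsum("ngitk,goik->ngot", vg, wg, optimize=True).reshape(n, c_out, t_out)

    def bwd(g):
        gg = g.reshape(n, groups, c_out // groups, t_out)
        gw = np.einsum("ngot,ngitk->goik", gg, vg, optimize=True).reshape(w.data.shape)
        # scatter grad back through each kernel tap
        tmp = np.einsum("ngot,goik->ngitk", gg, wg, optimize=True)
        gxp = np.zeros_like(xp).reshape(n, groups, c_ing, -1)
        for tap in range(k):
            gxp[:, :, :, tap * dilation : tap * dilation + t_out] += tmp[..., tap]
        gxp = gxp.reshape(xp.shape)
        gx = gxp[:, :, pad_left : pad_left + t]
        return gx, gw

    return Tensor._make(out, (x, w), bwd)


def fused_norm(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple, eps: float,
               running=None):
    """Affine normalization (batch-norm / layer-norm core) as one primitive.

    Normalizes over `axes` with batch statistics, or with the provided
    `running = (mean, var)` arrays (eval mode). gamma/beta must be shaped to
    broadcast against x. Returns (out, batch_mean, batch_var); the statistics
    are keepdims arrays for the caller's running-estimate update.
    """
    x, gamma, beta = Tensor._wrap(x), Tensor._wrap(gamma), Tensor._wrap(beta)
    xd = x.data
    if running is None:
        mu = xd.mean(axis=axes, keepdims=True)
        var = xd.var(axis=axes, keepdims=True)
        training = True
    else:
        mu, var = (np.asarray(r, dtype=xd.dtype) for r in running)
        training = False
    s = np.sqrt(var + np.asarray(eps, dtype=xd.dtype))
    xhat = (xd - mu) / s
    out = gamma.data * xhat + beta.data

    def bwd(g):
        ggamma = _unbroadcast(g * xhat, gamma.data.shape)
        gbeta = _unbroadcast(g, beta.data.shape)
        gxhat = g * gamma.data
        if training:
            gx = (
                gxhat
                - gxhat.mean(axis=axes, keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
            ) / s
        else:
            gx = gxhat / s
        return gx, ggamma, gbeta

    return Tensor._make(out, (x, gamma, beta), bwd), mu, var


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant."""
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    return (x - shift).exp().sum(axis=axis, keepdims=True).log() + shift
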