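"""Minimal reverse-mode automatic differentiation over numpy arrays.

This engine exists to support backpropagation-through-time on small spiking
networks: a :class:`Tensor` wraps an ``ndarray`` and records the operations
applied to it on a tape, and :meth:`Tensor.backward` walks the tape in
reverse topological order.  Only the operations the spiking layers need are
implemented (elementwise arithmetic, matmul, same-padded stride-1
convolution, 2x2 max pooling, reductions, and a hard-threshold spike with a
SuperSpike surrogate derivative).  Gradients of every primitive are checked
against central finite differences in the test suite.

All ops accept plain ``ndarray``/scalar operands and promote them to
non-differentiable constants, so the same layer code runs inside and outside
a gradient tape.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "astensor",
    "heaviside",
    "clamp_min",
    "where_scalar",
    "cross_entropy_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # defer mixed ndarray/Tensor arithmetic to the reflected operators
    __array_ufunc__ = None

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd ------------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded tape."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator overloads --------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent: float):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, *shape)

    def abs(self):
        return tabs(self)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _binary(a, b, fwd, bwd_a, bwd_b) -> Tensor:
    a, b = astensor(a), astensor(b)
    out_data = fwd(a.data, b.data)
    req = a.requires_grad or b.requires_grad
    if not req:
        return Tensor(out_data)

    def _backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accumulate(bwd_a(g, a.data, b.data))
        if b.requires_grad:
            b._accumulate(bwd_b(g, a.data, b.data))

    return Tensor(out_data, True, (a, b), _backward)


def add(a, b) -> Tensor:
    return _binary(a, b, np.add, lambda g, x, y: g, lambda g, x, y: g)


def mul(a, b) -> Tensor:
    return _binary(a, b, np.multiply, lambda g, x, y: g * y, lambda g, x, y: g * x)


def div(a, b) -> Tensor:
    return _binary(
        a,
        b,
        np.divide,
        lambda g, x, y: g / y,
        lambda g, x, y: -g * x / (y * y),
    )


def power(a, exponent: float) -> Tensor:
    a = astensor(a)
    out_data = a.data**exponent
    if not a.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        a._accumulate(g * exponent * a.data ** (exponent - 1))

    return Tensor(out_data, True, (a,), _backward)


def sqrt(a) -> Tensor:
    a = astensor(a)
    out_data = np.sqrt(a.data)
    if not a.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        a._accumulate(g * (0.5 / out_data))

    return Tensor(out_data, True, (a,), _backward)


def tabs(a) -> Tensor:
    """|a|; subgradient 0 at exactly 0."""
    a = astensor(a)
    out_data = np.abs(a.data)
    if not a.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        a._accumulate(g * np.sign(a.data))

    return Tensor(out_data, True, (a,), _backward)


def matmul(a, b) -> Tensor:
    return _binary(
        a,
        b,
        np.matmul,
        lambda g, x, y: g @ y.T,
        lambda g, x, y: x.T @ g,
    )


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    if not a.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return Tensor(out_data, True, (a,), _backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, *shape) -> Tensor:
    a = astensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    out_data = a.data.reshape(shape)
    if not a.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return Tensor(out_data, True, (a,), _backward)


def clamp_min(a, lo: float) -> Tensor:
    """max(a, lo); the gradient passes only where a > lo."""
    if not isinstance(a, Tensor):
        return np.maximum(a, lo)
    out_data = np.maximum(a.data, lo)
    if not a.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        a._accumulate(g * (a.data > lo))

    return Tensor(out_data, True, (a,), _backward)


def where_scalar(mask: np.ndarray, a, b) -> Tensor:
    """mask ? a : b with a constant (non-differentiated) mask."""
    a, b = astensor(a), astensor(b)
    m = np.asarray(mask)
    out_data = np.where(m, a.data, b.data)
    req = a.requires_grad or b.requires_grad
    if not req:
        return Tensor(out_data)

    def _backward(g):
        if a.requires_grad:
            a._accumulate(g * m)
        if b.requires_grad:
            b._accumulate(g * (1 - m))

    return Tensor(out_data, True, (a, b), _backward)


def heaviside(x, beta: float = 100.0):
    """Hard spike Θ(x) forward; SuperSpike surrogate 1/(β|x|+1)² backward.

    Accepts an ``ndarray`` (plain Heaviside, no tape) or a :class:`Tensor`.
    Θ(0) = 0: a membrane exactly at threshold does not fire.
    """
    if not isinstance(x, Tensor):
        return (np.asarray(x) > 0).astype(np.result_type(x, np.float32))
    out_data = (x.data > 0).astype(x.data.dtype)
    if not x.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        surrogate = 1.0 / (beta * np.abs(x.data) + 1.0) ** 2
        x._accumulate(g * surrogate)

    return Tensor(out_data, True, (x,), _backward)


# -- convolution and pooling ------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N*H*W, C*kh*kw) for stride-1 valid windows."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    n, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw), (n, h, w)


def _conv2d_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 cross-correlation, odd kernels only."""
    kh, kw = w.shape[2], w.shape[3]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols, (n, h, ww) = _im2col(xp, kh, kw)
    out = cols @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, h, ww, w.shape[0]).transpose(0, 3, 1, 2)


def conv2d(x, w) -> Tensor:
    """Same-padded stride-1 2-D convolution; x (N,C,H,W), w (O,C,kh,kw)."""
    x, w = astensor(x), astensor(w)
    kh, kw = w.data.shape[2], w.data.shape[3]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d supports odd kernel sizes only")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols, (n, h, ww) = _im2col(xp, kh, kw)
    o = w.data.shape[0]
    out_data = (cols @ w.data.reshape(o, -1).T).reshape(n, h, ww, o)
    out_data = out_data.transpose(0, 3, 1, 2)
    req = x.requires_grad or w.requires_grad
    if not req:
        return Tensor(out_data)

    def _backward(g):
        if w.requires_grad:
            go = g.transpose(0, 2, 3, 1).reshape(-1, o)
            gw = (go.T @ cols).reshape(w.data.shape)
            w._accumulate(gw)
        if x.requires_grad:
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            x._accumulate(_conv2d_raw(g, w_flip))

    return Tensor(out_data, True, (x, w), _backward)


def maxpool2d(x, k: int = 2) -> Tensor:
    """Non-overlapping k x k max pooling; spatial dims must divide k."""
    x = astensor(x)
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims ({h},{w}) not divisible by pool size {k}")
    win = x.data.reshape(n, c, h // k, k, w // k, k).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // k, w // k, k * k)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    if not x.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gx.reshape(n, c, h, w))

    return Tensor(out_data, True, (x,), _backward)


def lif_fused(v, input_current, a, v_th, v_leak: float = 0.0,
              v_reset: float = 0.0, beta: float = 100.0):
    """One fused LIF update returning (v_new, z).

    Computes vd = v + a*(v_leak - v + I), z = Θ(vd - v_th), and
    v_new = vd*(1-z) + z*v_reset in a single tape node pair with an
    analytic backward (SuperSpike surrogate through both the spike output
    and the reset), avoiding the per-op overhead of composing the update
    from primitives inside the BPTT loop.  ``a`` is dt/tau_eff and ``v_th``
    the effective threshold; either may be a Tensor (modulated layers,
    gradient flows to p) or a plain scalar/array.
    """
    vt, it, at, tht = astensor(v), astensor(input_current), astensor(a), astensor(v_th)
    drive = v_leak - vt.data + it.data
    vd = vt.data + at.data * drive
    x = vd - tht.data
    z_data = (x > 0).astype(vd.dtype)
    keep = 1.0 - z_data
    v_new_data = vd * keep + z_data * v_reset
    parents = tuple(t for t in (vt, it, at, tht) if t.requires_grad)
    if not parents:
        return Tensor(v_new_data), Tensor(z_data)

    s_cell: list[np.ndarray] = []

    def _s() -> np.ndarray:
        # surrogate is only needed if backward actually runs
        if not s_cell:
            s_cell.append(1.0 / (beta * np.abs(x) + 1.0) ** 2)
        return s_cell[0]

    def _scatter(gvd, gth):
        if vt.requires_grad:
            vt._accumulate(gvd * (1.0 - at.data))
        if it.requires_grad:
            it._accumulate(gvd * at.data)
        if at.requires_grad:
            at._accumulate(gvd * drive)
        if tht.requires_grad:
            tht._accumulate(gth)

    def _backward_v(g):
        s = _s()
        gvd = g * (keep + (v_reset - vd) * s)
        _scatter(gvd, g * (vd - v_reset) * s)

    def _backward_z(g):
        gs = g * _s()
        _scatter(gs, -gs)

    v_new = Tensor(v_new_data, True, parents, _backward_v)
    z_new = Tensor(z_data, True, parents, _backward_z)
    return v_new, z_new


def batchnorm2d(x, gamma, beta_p, eps: float = 1.0e-5):
    """Training-mode batch normalization over (N, H, W) per channel.

    Returns (out, batch_mean, batch_var) with the batch statistics as plain
    arrays for running-average updates; the backward is the standard
    batch-stat gradient.
    """
    xt, gt, bt = astensor(x), astensor(gamma), astensor(beta_p)
    axes = (0, 2, 3)
    mu = xt.data.mean(axis=axes, keepdims=True)
    var = xt.data.var(axis=axes, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = (xt.data - mu) / std
    g_r = gt.data.reshape(1, -1, 1, 1)
    out_data = xhat * g_r + bt.data.reshape(1, -1, 1, 1)
    parents = tuple(t for t in (xt, gt, bt) if t.requires_grad)
    if not parents:
        return Tensor(out_data), mu.ravel(), var.ravel()

    n = xt.data.shape[0] * xt.data.shape[2] * xt.data.shape[3]

    def _backward(g):
        if gt.requires_grad:
            gt._accumulate((g * xhat).sum(axis=axes))
        if bt.requires_grad:
            bt._accumulate(g.sum(axis=axes))
        if xt.requires_grad:
            gxhat = g * g_r
            term = (
                gxhat
                - gxhat.mean(axis=axes, keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True)
            )
            xt._accumulate(term / std)

    out = Tensor(out_data, True, parents, _backward)
    return out, mu.ravel(), var.ravel()


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy from raw logits (N, K); fused stable softmax."""
    logits = astensor(logits)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out_data = np.asarray(loss, dtype=logits.data.dtype)
    if not logits.requires_grad:
        return Tensor(out_data)

    def _backward(g):
        softmax = np.exp(logp)
        softmax[np.arange(n), labels] -= 1.0
        logits._accumulate(g * softmax / n)

    return Tensor(out_data, True, (logits,), _backward)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis, differentiably."""
    ts = [astensor(t) for t in tensors]
    out_data = np.stack([t.data for t in ts], axis=axis)
    if not any(t.requires_grad for t in ts):
        return Tensor(out_data)

    def _backward(g):
        pieces = np.split(g, len(ts), axis=axis)
        for t, piece in zip(ts, pieces):
            if t.requires_grad:
                t._accumulate(np.squeeze(piece, axis=axis))

    return Tensor(out_data, True, tuple(ts), _backward)
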