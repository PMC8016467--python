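"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operation that produced
it; calling :meth:`Tensor.backward` on a scalar loss propagates gradients to
every reachable parameter.  The op set is exactly what the encoder/decoder
architectures in this package need: broadcast arithmetic, (batched) matmul,
elementwise nonlinearities, reductions, indexing/gather, concatenation,
reshaping and a 1-D convolution primitive.

Float64 throughout: CPU-sized models where reproducibility across runs
matters more than raw speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "softmax", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, requires_grad=self.requires_grad,
                     _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.outer(g, other.data) if self.data.ndim == 2 else g * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    if self.data.ndim == 1:
                        ga = ga.sum(axis=tuple(range(ga.ndim - 1)))
                self._accumulate(_unbroadcast(np.asarray(ga), self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.outer(self.data, g) if other.data.ndim == 2 else g * self.data
                else:
                    a_t = np.swapaxes(self.data, -1, -2)
                    if np.asarray(g).ndim == 1:
                        gb = a_t @ g
                    else:
                        gb = a_t @ g
                other._accumulate(_unbroadcast(np.asarray(gb), other.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * (1 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * s * (1 - s))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * mask)
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max over one axis; gradient flows to the (first) argmax entries."""
        idx = np.argmax(self.data, axis=axis)
        val = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if keepdims:
                g = np.squeeze(g, axis=axis)
            full = np.zeros_like(self.data)
            grid = np.ogrid[tuple(slice(s) for s in idx.shape)]
            sel = list(grid)
            sel.insert(axis, idx)
            full[tuple(sel)] = g
            self._accumulate(full)

        out._backward = bw
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad,
                     _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            np.asarray(g).reshape(self.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     _parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            np.asarray(g).transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    def __getitem__(self, key):
        out = Tensor(self.data[key], requires_grad=self.requires_grad, _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, key, np.asarray(g))
            self._accumulate(full)

        out._backward = bw
        return out

    # -- convolution -------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Valid 1-D convolution.

        self: (batch, in_ch, length); weight: (out_ch, in_ch, k);
        bias: (out_ch,).  Output: (batch, out_ch, length - k + 1).
        """
        x, w = self.data, weight.data
        batch, in_ch, length = x.shape
        out_ch, _, k = w.shape
        out_len = length - k + 1
        if out_len < 1:
            raise ValueError(f"conv1d input length {length} shorter than kernel {k}")
        # im2col: (batch, in_ch, k, out_len)
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (b, c, out_len, k)
        cols = cols.transpose(0, 1, 3, 2)
        y = np.einsum("bckl,ock->bol", cols, w, optimize=True) + bias.data[None, :, None]
        req = self.requires_grad or weight.requires_grad or bias.requires_grad
        out = Tensor(y, requires_grad=req, _parents=(self, weight, bias))

        def bw(g):
            g = np.asarray(g)
            if weight.requires_grad:
                gw = np.einsum("bol,bckl->ock", g, cols, optimize=True)
                weight._accumulate(gw)
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))
            if self.requires_grad:
                gx = np.zeros_like(x)
                # scatter each kernel offset back
                contrib = np.einsum("bol,ock->bckl", g, w, optimize=True)
                for kk in range(k):
                    gx[:, :, kk:kk + out_len] += contrib[:, :, kk, :]
                self._accumulate(gx)

        out._backward = bw
        return out

    # -- backward ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def Parameter(data) -> Tensor:
    """A trainable tensor (gradient always recorded)."""
    t = Tensor(np.asarray(data, dtype=np.float64))
    t.requires_grad = True
    return t


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, requires_grad=req, _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        g = np.asarray(g)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-shift treated as a constant)."""
    shifted = t - Tensor(np.max(t.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
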