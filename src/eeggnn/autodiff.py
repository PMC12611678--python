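"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine in the spirit of micrograd, but tensor-valued and
with only the operations the classifier needs: broadcast arithmetic, matmul,
two-operand einsum, FFT-based valid 1-D convolution, reductions, shape ops,
and pointwise nonlinearities.  Gradients are accumulated into ``Tensor.grad``
by :meth:`Tensor.backward` in reverse topological order.

Everything is plain float32/float64 NumPy; determinism follows from NumPy's.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data)
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g)
                elif other.data.ndim == 1:
                    n = self.data.shape[-1]
                    gb = np.einsum("ri,r->i", self.data.reshape(-1, n),
                                   np.asarray(g).reshape(-1))
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- pointwise ------------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g_arr = np.asarray(g)
            if axis is not None and not keepdims:
                g_arr = np.expand_dims(g_arr, axis)
            self._accumulate(np.broadcast_to(g_arr, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inverse = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inverse))

        return self._make(out_data, (self,), backward)

    def take(self, indices, axis: int):
        """Fancy integer indexing along one axis (scatter-add backward)."""
        indices = np.asarray(indices, dtype=np.intp)
        out_data = np.take(self.data, indices, axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            full = np.zeros(self.shape, dtype=g.dtype)
            sl = [slice(None)] * self.data.ndim
            sl[axis] = indices
            np.add.at(full, tuple(sl), g)
            self._accumulate(full)

        return self._make(out_data, (self,), backward)

    # -- autodiff machinery ---------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free interior gradients to bound memory
                if node is not self and node._parents:
                    node.grad = None


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._wrap(t)
        shape = list(t.shape)
        shape.insert(axis, 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)


def einsum(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum.

    Every index of each operand must appear in the output or in the other
    operand, and no operand may repeat an index — which holds for all
    contractions used in this package.
    """
    a = Tensor._wrap(a)
    b = Tensor._wrap(b)
    lhs, out_sub = subscripts.split("->")
    a_sub, b_sub = lhs.split(",")
    out_data = np.einsum(subscripts, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(np.einsum(f"{out_sub},{b_sub}->{a_sub}", g, b.data))
        if b.requires_grad:
            b._accumulate(np.einsum(f"{out_sub},{a_sub}->{b_sub}", g, a.data))

    return Tensor._make(out_data, (a, b), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant shift: grad-exact
    e = (x - Tensor(shift)).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv1d_valid(x: Tensor, w: Tensor) -> Tensor:
    """Valid, stride-1 cross-correlation of ``x`` (..., T) with kernels ``w`` (K, O).

    Each leading-dim row of ``x`` is treated as an independent single-channel
    series; output shape is (..., O, T - K + 1).  Implemented with real FFTs so
    both passes are O(T log T) per row.
    """
    x = Tensor._wrap(x)
    w = Tensor._wrap(w)
    T = x.shape[-1]
    K, n_out = w.shape
    if K > T:
        raise ValueError(f"kernel size {K} exceeds series length {T}")
    L = T - K + 1
    nfft = sfft.next_fast_len(T)
    Xf = sfft.rfft(x.data, n=nfft, axis=-1)  # (..., F)
    # correlation == convolution with reversed kernel
    Wf = sfft.rfft(w.data[::-1].T, n=nfft, axis=-1)  # (O, F)
    prod = Xf[..., None, :] * Wf  # (..., O, F)
    full = sfft.irfft(prod, n=nfft, axis=-1)
    out_data = np.ascontiguousarray(full[..., K - 1 : K - 1 + L])
    if np.issubdtype(x.data.dtype, np.floating):
        out_data = out_data.astype(x.data.dtype, copy=False)

    def backward(g):
        Gf = sfft.rfft(g, n=nfft, axis=-1)  # (..., O, F) spectrum of grad at lag K-1..
        if x.requires_grad:
            # grad_x = sum_o full-convolution(g_o, w_o); in frequency domain
            # conv with (unreversed) kernel at offset K-1 cancels the shift.
            Wf_fwd = sfft.rfft(w.data.T, n=nfft, axis=-1)  # (O, F)
            acc = np.einsum("...of,of->...f", Gf, Wf_fwd)
            gx_full = sfft.irfft(acc, n=nfft, axis=-1)
            # g sits at lags [K-1, K-1+L); conv by w spreads back onto [0, T)
            gx = gx_full[..., : T]
            # circular wrap cannot occur: (K-1+L-1)+(K-1) = T+K-2 <= nfft+... guard:
            x._accumulate(gx.astype(x.data.dtype, copy=False))
        if w.requires_grad:
            # grad_w[k, o] = sum_rows sum_l x[l + k] g[o, l]  (correlation)
            n_freq = Xf.shape[-1]
            acc = np.einsum(
                "rf,rof->of",
                Xf.reshape(-1, n_freq),
                Gf.conj().reshape(-1, n_out, n_freq),
            )
            gw_full = sfft.irfft(acc, n=nfft, axis=-1)  # (O, nfft)
            gw = gw_full[:, :K].T
            w._accumulate(gw.astype(w.data.dtype, copy=False))

    out = Tensor._make(out_data, (x, w), backward)
    return out


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    out = x @ weight
    if bias is not None:
        out = out + bias
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    normed = centered / (var + eps).sqrt()
    return normed * gamma + beta


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(mask)


class Adam:
    """Adam optimizer over a name → Tensor parameter mapping."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
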