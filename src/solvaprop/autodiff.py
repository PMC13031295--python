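"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the tensor operations the message-passing encoder, the
invariant attention backbone and the training loop need: broadcasting
arithmetic, (batched) matmul, elementwise nonlinearities, reductions,
shape manipulation, gather / segment-sum for graph batching, and a
numerically stable softmax.  Gradients flow only into tensors created
with ``requires_grad=True`` (parameters); everything runs in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "frozen")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()
        self.frozen = False

    # -- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _needs(self):
        return self.requires_grad or self._prev

    def _accum(self, g):
        g = np.asarray(g, dtype=np.float64)
        fresh = g.shape != self.data.shape   # _unbroadcast returns a new array
        if fresh:
            g = _unbroadcast(g, self.data.shape)
        if self.grad is None:
            self.grad = g if fresh else g.copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break the node <-> closure reference cycles so the graph is
        # freed by refcounting, not delayed cyclic GC (large arrays)
        for t in topo:
            t._backward = None
            t._prev = ()

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data)
        if self._needs() or other._needs():
            out._prev = (self, other)

            def _bw():
                if self._needs():
                    self._accum(out.grad)
                if other._needs():
                    other._accum(out.grad)

            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data)
        if self._needs() or other._needs():
            out._prev = (self, other)

            def _bw():
                if self._needs():
                    self._accum(out.grad * other.data)
                if other._needs():
                    other._accum(out.grad * self.data)

            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p)
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad * p * self.data ** (p - 1.0))

            out._backward = _bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        # (..., m, k) @ (k, n): flatten to one large GEMM instead of a
        # loop of small batched products (large speedup for BLAS)
        if self.data.ndim > 2 and other.data.ndim == 2:
            lead = self.data.shape[:-1]
            flat = self.reshape(int(np.prod(lead)), self.data.shape[-1])
            return (flat @ other).reshape(*lead, other.data.shape[1])
        out = Tensor(self.data @ other.data)
        if self._needs() or other._needs():
            out._prev = (self, other)

            def _bw():
                # promote 1-D operands to 2-D so one rule covers all cases
                a, b = self.data, other.data
                g = out.grad
                a2 = a[None, :] if a.ndim == 1 else a
                b2 = b[:, None] if b.ndim == 1 else b
                g2 = g
                if a.ndim == 1:
                    g2 = np.expand_dims(g2, -2)
                if b.ndim == 1:
                    g2 = np.expand_dims(g2, -1)
                if self._needs():
                    ga = g2 @ np.swapaxes(b2, -1, -2)
                    if a.ndim == 1:
                        ga = ga.reshape(-1, a.shape[0]).sum(0)
                    self._accum(_unbroadcast(ga, a.shape))
                if other._needs():
                    gb = np.swapaxes(a2, -1, -2) @ g2
                    if b.ndim == 1:
                        gb = gb.reshape(-1, b.shape[0]).sum(0)
                    other._accum(_unbroadcast(gb, b.shape))

            out._backward = _bw
        return out

    # -- elementwise -----------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data))
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad * out.data)

            out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data))
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad / self.data)

            out._backward = _bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data))
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad * 0.5 / np.maximum(out.data, 1e-300))

            out._backward = _bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0))
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad * (self.data > 0.0))

            out._backward = _bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data))
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad * (1.0 - out.data ** 2))

            out._backward = _bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data))
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad * np.sign(self.data))

            out._backward = _bw
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        if self._needs():
            out._prev = (self,)

            def _bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))

            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape))
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad.reshape(self.data.shape))

            out._backward = _bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes))
        inv = np.argsort(axes)
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(out.grad.transpose(inv))

            out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx])
        if self._needs():
            out._prev = (self,)

            def _bw():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

            out._backward = _bw
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s)
        if self._needs():
            out._prev = (self,)

            def _bw():
                g = out.grad
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

            out._backward = _bw
        return out

    # -- graph batching ---------------------------------------------------
    def gather(self, index, axis: int = 0):
        """Rows of self selected by integer array `index` along `axis`."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(np.take(self.data, index, axis=axis))
        if self._needs():
            out._prev = (self,)

            def _bw():
                g = np.zeros_like(self.data)
                if axis == 0:
                    np.add.at(g, index, out.grad)
                else:  # pragma: no cover - axis 0 is the only use in-package
                    sl = [slice(None)] * g.ndim
                    sl[axis] = index
                    np.add.at(g, tuple(sl), out.grad)
                self._accum(g)

            out._backward = _bw
        return out

    def segment_sum(self, segment_ids, num_segments: int):
        """Sum rows sharing a segment id: out[s] = sum_{i: seg[i]=s} self[i]."""
        seg = np.asarray(segment_ids, dtype=np.intp)
        shape = (num_segments,) + self.data.shape[1:]
        acc = np.zeros(shape, dtype=np.float64)
        np.add.at(acc, seg, self.data)
        out = Tensor(acc)
        if self._needs():
            out._prev = (self,)

            def _bw():
                self._accum(np.take(out.grad, seg, axis=0))

            out._backward = _bw
        return out


def Parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t._needs() for t in tensors):
        out._prev = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t._needs():
                    t._accum(g)

        out._backward = _bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis))
    if any(t._needs() for t in tensors):
        out._prev = tuple(tensors)

        def _bw():
            parts = np.split(out.grad, len(tensors), axis=axis)
            for t, g in zip(tensors, parts):
                if t._needs():
                    t._accum(np.squeeze(g, axis=axis))

        out._backward = _bw
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of Parameters.

    Tensors whose ``frozen`` flag is set receive no update (and their
    moment buffers do not advance), which is how phase-1 training keeps
    pretrained encoders bit-identical.
    """

    def __init__(self, params, lr: float = 3e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, clip_norm: float | None = 5.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
        self.update_counts = [0] * len(self.params)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        if self.clip_norm is not None:
            total = np.sqrt(sum(
                float((p.grad ** 2).sum()) for p in self.params
                if p.grad is not None and not p.frozen))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                for p in self.params:
                    if p.grad is not None and not p.frozen:
                        p.grad *= scale
        for i, p in enumerate(self.params):
            if p.frozen or p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)
            self.update_counts[i] += 1
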