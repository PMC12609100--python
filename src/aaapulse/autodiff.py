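"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients into every reachable tensor with
``requires_grad=True``. The op set is exactly what the severity-estimation
network needs: broadcast arithmetic, matmul, a dilated row-wise 1-D
convolution (im2col), reductions, the usual nonlinearities and batch-norm
building blocks. Gradients are validated against central finite differences
in the test suite.

The graph is retained after ``backward`` so a multi-objective training step
can run several backward passes (zeroing gradients in between) over one
forward pass.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node on the autodiff tape.

    ``Tensor.DTYPE`` sets the working precision globally: float32 (default)
    halves memory traffic during training; switch to float64 when validating
    gradients against finite differences.
    """

    DTYPE = np.float32

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=Tensor.DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad=None) -> None:
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
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad_tree(self) -> None:
        stack = [self]
        seen: set[int] = set()
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            seen.add(id(node))
            node.grad = None
            stack.extend(node._parents)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(*axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        mask = self.data == self.data.max(axis=axis, keepdims=True)
        # split gradient evenly across ties (ties are measure-zero in practice)
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not self.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(mask * (g / counts))

        return Tensor._from_op(out_data, (self,), backward)

    # -- nonlinearities ------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._from_op(out_data, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._from_op(np.abs(self.data), (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def softplus(self):
        """log(1 + exp(x)), computed stably (used by the disturbance loss)."""
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor._from_op(out_data, (self,), backward)

    # -- structured ops ------------------------------------------------------
    def conv1d_row(self, weight: "Tensor", bias: "Tensor | None", dilation: int = 1):
        """Row-wise dilated 1-D convolution with length-preserving zero padding.

        Input (N, C, H, W), weight (C_out, C_in, K): each of the H rows is
        convolved independently along W. Stride 1.
        """
        x, w = self.data, weight.data
        n, c, h, wd = x.shape
        cout, cin, k = w.shape
        if cin != c:
            raise ValueError("channel mismatch in conv1d_row")
        span = (k - 1) * dilation
        pl = span // 2
        pr = span - pl
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        # (N, C, H, W, K) from K contiguous slices (cheaper than fancy indexing)
        patches = np.stack(
            [xp[:, :, :, i * dilation : i * dilation + wd] for i in range(k)], axis=-1
        )
        cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4)).reshape(
            n * h * wd, c * k
        )
        wmat = w.reshape(cout, c * k).T
        out = cols @ wmat
        if bias is not None:
            out = out + bias.data[None, :]
        out_data = np.ascontiguousarray(out.reshape(n, h, wd, cout).transpose(0, 3, 1, 2))

        def backward(g):
            gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, cout)
            if weight.requires_grad:
                gw = (cols.T @ gcols).T.reshape(cout, c, k)
                weight._accum(gw)
            if bias is not None and bias.requires_grad:
                bias._accum(gcols.sum(axis=0))
            if self.requires_grad:
                gpatch = (gcols @ wmat.T).reshape(n, h, wd, c, k).transpose(0, 3, 1, 2, 4)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    gxp[:, :, :, i * dilation : i * dilation + wd] += gpatch[..., i]
                self._accum(gxp[:, :, :, pl : pl + wd])

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._from_op(out_data, parents, backward)

    def avgpool_w(self, factor: int):
        """Average pooling along the last axis by an integer factor."""
        n, c, h, w = self.data.shape
        if w % factor:
            raise ValueError("width not divisible by pooling factor")
        out_data = self.data.reshape(n, c, h, w // factor, factor).mean(axis=4)

        def backward(g):
            if self.requires_grad:
                gx = np.repeat(g[..., None], factor, axis=4) / factor
                self._accum(gx.reshape(n, c, h, w))

        return Tensor._from_op(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


class Adam:
    """Adam optimizer over a fixed list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads: list[np.ndarray] | None = None) -> None:
        """Apply one update from ``grads`` (defaults to the stored ``.grad``)."""
        if grads is None:
            grads = [p.grad for p in self.params]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v, g in zip(self.params, self.m, self.v, grads):
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
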