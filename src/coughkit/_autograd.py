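"""A minimal reverse-mode automatic-differentiation engine on numpy arrays.

Provides exactly the operations the convolutional-recurrent classifier
needs: broadcasting arithmetic, matrix products, reductions, slicing,
pointwise nonlinearities, 3x3 same-padding convolution (via im2col) and
2x pooling along one spatial axis.  Gradients are accumulated by a
topological backward sweep; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over axes that numpy broadcasting introduced."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # -- graph mechanics ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming array may be shared with another closure
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def _lift(self, x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        # plain numbers adopt this tensor's dtype so float32 graphs stay float32
        return Tensor(np.asarray(x, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (self.requires_grad
                                   and self._accumulate(-g)) or None
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / other.data ** 2, other.data.shape))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g.reshape(self.data.shape))
                                   ) or None
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g.transpose(inv))) or None
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities -----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g * mask)) or None
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g * s * (1 - s))) or None
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, _parents=(self,))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g * (1 - t * t))) or None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g / self.data)) or None
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, _parents=(self,))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g * 0.5 / r)) or None
        return out

    def softplus(self):
        """log(1 + exp(x)), computed stably."""
        x = self.data
        sp = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        out = Tensor(sp, _parents=(self,))
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        out._backward = lambda g: (self.requires_grad and
                                   self._accumulate(g * sig)) or None
        return out


# ---------------------------------------------------------------------------
# convolution and pooling
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, pad: int) -> np.ndarray:
    """(B, C, H, W) → (B*H*W, C*kh*kw) patches for stride-1 same convolution."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw),
                                                       axis=(2, 3))
    b, c, oh, ow = windows.shape[:4]
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * kh * kw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Stride-1, same-padding 2-D convolution.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, kh, kw) with odd kernel;
    ``bias``: (C_out,).  Output (B, C_out, H, W).  The input gradient is
    computed as a correlation of the output gradient with the spatially
    flipped, channel-transposed kernel (the adjoint of same-pad convolution),
    so both passes run through the same im2col matmul.
    """
    b, c_in, h, w = x.data.shape
    c_out, _, kh, kw = weight.data.shape
    pad = kh // 2
    cols = _im2col(x.data, kh, kw, pad)
    wmat = weight.data.reshape(c_out, -1)
    out_data = (cols @ wmat.T + bias.data).reshape(b, h, w, c_out)
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    out = Tensor(out_data, _parents=(x, weight, bias))

    def bwd(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, c_out)
        if weight.requires_grad:
            weight._accumulate((g2.T @ cols).reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accumulate(g2.sum(axis=0))
        if x.requires_grad:
            flipped = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            wmat_t = flipped.reshape(c_in, -1)
            gcols = _im2col(np.ascontiguousarray(g), kh, kw, pad)
            gx = (gcols @ wmat_t.T).reshape(b, h, w, c_in)
            x._accumulate(gx.transpose(0, 3, 1, 2))

    out._backward = bwd
    return out


def max_pool_axis2(x: Tensor, factor: int = 2) -> Tensor:
    """Max pooling by ``factor`` along axis 2 of a (B, C, H, W) tensor."""
    b, c, h, w = x.data.shape
    if h % factor:
        raise ValueError(f"axis-2 size {h} not divisible by pool factor {factor}")
    grouped = x.data.reshape(b, c, h // factor, factor, w)
    out_data = grouped.max(axis=3)
    mask = grouped == out_data[:, :, :, None, :]
    # break ties: keep only the first max in each group
    first = np.cumsum(mask, axis=3) == 1
    mask = mask & first
    out = Tensor(out_data, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate((mask * g[:, :, :, None, :]).reshape(b, c, h, w))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
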