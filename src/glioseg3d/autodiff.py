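"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the segmentation network and its training
objective need: broadcasting arithmetic, reductions, pointwise nonlinearities,
3D convolution (stride / dilation, "same" padding), instance normalization,
trilinear resizing, channel concatenation and dropout.  Layout is
channel-first without a batch axis: feature maps are (C, D, H, W).

Gradients propagate through a topologically sorted tape; ``no_grad()``
disables taping entirely so inference allocates no graph.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np

_GRAD_ENABLED = True

_ALLOCATOR_TUNED = False


def tune_allocator() -> bool:
    """Keep freed large buffers inside the process heap (glibc mallopt).

    The training loop allocates and frees hundreds of megabytes of im2col
    and activation buffers per step; by default glibc hands those back to
    the kernel, so every step pays the page-fault cost again.  Disabling
    mmap'd allocations and heap trimming makes steps several times faster.
    Best-effort: returns False on non-glibc platforms.
    """
    global _ALLOCATOR_TUNED
    if _ALLOCATOR_TUNED:
        return True
    try:
        import ctypes

        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-1, 256 << 20)  # M_TRIM_THRESHOLD: keep freed blocks around
        libc.mallopt(-3, 64 << 20)   # M_MMAP_THRESHOLD: medium blocks via heap
        _ALLOCATOR_TUNED = True
        return True
    except Exception:
        return False


@contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], tuple]) -> "Tensor":
        """Create an op output.  ``backward(g)`` must return one gradient per
        parent (or None for parents that do not require grad)."""
        needs = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=needs)
        if needs:
            parents_t = tuple(parents)
            out._parents = parents_t

            # NB: the closure must not capture ``out`` — that would create a
            # reference cycle and leave whole graphs to the cyclic GC.
            def _bw(g: np.ndarray) -> None:
                grads = backward(g)
                for p, pg in zip(parents_t, grads):
                    if pg is None or not p.requires_grad:
                        continue
                    # out-of-place accumulation: results are never mutated, so
                    # freshly produced gradient arrays can be adopted directly
                    p.grad = pg if p.grad is None else p.grad + pg

            out._backward = _bw
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward pass -------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        seed = np.asarray(grad)
        self.grad = seed if self.grad is None else self.grad + seed
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate gradients/closures as soon as they are
                # consumed so peak memory tracks graph depth, not size
                node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic ----------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._result(
            self.data + o.data, (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._result(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._result(
            self.data * o.data, (self, o),
            lambda g: (_unbroadcast(g * o.data, self.shape),
                       _unbroadcast(g * self.data, o.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return Tensor._result(
            self.data / o.data, (self, o),
            lambda g: (_unbroadcast(g / o.data, self.shape),
                       _unbroadcast(-g * self.data / (o.data ** 2), o.shape)),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._result(
            self.data ** e, (self,),
            lambda g: (g * e * self.data ** (e - 1.0),),
        )

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._result(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        shape = shape[0] if len(shape) == 1 and isinstance(shape[0], tuple) else shape
        return Tensor._result(
            self.data.reshape(shape), (self,),
            lambda g: (np.asarray(g).reshape(self.shape),),
        )

    # -- pointwise nonlinearities ---------------------------------------------

    def log(self):
        return Tensor._result(np.log(self.data), (self,), lambda g: (g / self.data,))

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._result(out_data, (self,), lambda g: (g * out_data,))

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        return Tensor._result(
            np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,)
        )

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._result(s, (self,), lambda g: (g * s * (1.0 - s),))

    def relu(self):
        mask = self.data > 0
        return Tensor._result(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, negative_slope: float = 0.01):
        factor = np.where(self.data > 0, 1.0, negative_slope)
        return Tensor._result(self.data * factor, (self,), lambda g: (g * factor,))


# ---------------------------------------------------------------------------
# composite / structured ops
# ---------------------------------------------------------------------------


def softmax(x: Tensor, axis: int = 0) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return Tensor._result(s, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        outs = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            outs.append(np.ascontiguousarray(g[tuple(sl)]))
        return tuple(outs)

    return Tensor._result(data, tuple(tensors), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(x.data.dtype) / (1.0 - rate)
    return x * Tensor(mask)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """y = w @ x (+ b) for 1-D inputs; w is (n_out, n_in)."""
    data = w.data @ x.data
    if b is not None:
        data = data + b.data

    def backward(g):
        gx = w.data.T @ g
        gw = np.outer(g, x.data)
        gb = g if b is not None else None
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._result(data, parents, backward)


def _pad_channels(xd: np.ndarray, pad: int) -> np.ndarray:
    """Zero-pad the three spatial axes (calloc + interior assign beats np.pad)."""
    if pad == 0:
        return xd
    c, d0, h0, w0 = xd.shape
    xp = np.zeros((c, d0 + 2 * pad, h0 + 2 * pad, w0 + 2 * pad), dtype=xd.dtype)
    xp[:, pad:pad + d0, pad:pad + h0, pad:pad + w0] = xd
    return xp


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    dilation: int = 1,
) -> Tensor:
    """3D convolution with "same" padding on a (Cin, D, H, W) map.

    ``w`` is (Cout, Cin, k, k, k) with odd k.  Computed as k^3 shifted GEMMs
    over transient contiguous slabs: peak extra memory stays at one padded
    copy of the input (which the backward pass reuses), so deep graphs with
    many taped convolutions remain small and allocation churn is bounded.
    """
    xd, wd = x.data, w.data
    c_in, d0, h0, w0 = xd.shape
    c_out, c_in_w, k = wd.shape[0], wd.shape[1], wd.shape[2]
    if c_in_w != c_in:
        raise ValueError(f"weight expects {c_in_w} input channels, got {c_in}")
    pad = dilation * (k // 2)
    out_shape = tuple((n + 2 * pad - dilation * (k - 1) - 1) // stride + 1 for n in (d0, h0, w0))
    n_out = int(np.prod(out_shape))
    n_off = k ** 3
    xp = _pad_channels(xd, pad)
    # offset-major weight layout so im2col writes are contiguous per offset
    w2d = np.ascontiguousarray(wd.transpose(2, 3, 4, 1, 0).reshape(n_off * c_in, c_out))

    offset_slices = []
    for i in range(k):
        for j in range(k):
            for l in range(k):
                offset_slices.append(tuple(
                    slice(off * dilation, off * dilation + stride * (o - 1) + 1, stride)
                    for off, o in zip((i, j, l), out_shape)
                ))

    w3 = w2d.reshape(n_off, c_in, c_out)
    acc = np.zeros((c_out, n_out), dtype=xd.dtype)
    xs_buf = np.empty((c_in,) + out_shape, dtype=xd.dtype)
    for o, sl in enumerate(offset_slices):
        np.copyto(xs_buf, xp[(slice(None),) + sl])
        acc += w3[o].T @ xs_buf.reshape(c_in, n_out)
    out = acc.reshape((c_out,) + out_shape)
    if b is not None:
        out += b.data.reshape(c_out, 1, 1, 1)

    if not (_GRAD_ENABLED and (x.requires_grad or w.requires_grad
                               or (b is not None and b.requires_grad))):
        return Tensor(out)  # inference: no buffers retained

    def backward(g):
        g = np.ascontiguousarray(g, dtype=xd.dtype)
        gflat = g.reshape(c_out, n_out)
        dw = None
        if w.requires_grad:
            dw2d = np.empty((n_off, c_in, c_out), dtype=wd.dtype)
            buf = np.empty((c_in,) + out_shape, dtype=xd.dtype)
            for o, sl in enumerate(offset_slices):
                np.copyto(buf, xp[(slice(None),) + sl])
                dw2d[o] = buf.reshape(c_in, n_out) @ gflat.T
            dw = np.ascontiguousarray(
                dw2d.reshape(k, k, k, c_in, c_out).transpose(4, 3, 0, 1, 2)
            )
        dx = None
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            contrib = np.empty((c_in, n_out), dtype=xd.dtype)
            for o, sl in enumerate(offset_slices):
                np.matmul(w3[o], gflat, out=contrib)
                dxp[(slice(None),) + sl] += contrib.reshape((c_in,) + out_shape)
            dx = dxp[:, pad:pad + d0, pad:pad + h0, pad:pad + w0] if pad else dxp
        grads = [dx, dw]
        if b is not None:
            grads.append(g.sum(axis=(1, 2, 3)) if b.requires_grad else None)
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out, parents, backward)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes of a (C, D, H, W) map."""
    xd = x.data
    axes = (1, 2, 3)
    mu = xd.mean(axis=axes, keepdims=True)
    var = xd.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    gr = gamma.data.reshape(-1, 1, 1, 1)
    out = gr * xhat + beta.data.reshape(-1, 1, 1, 1)

    def backward(g):
        dxhat = g * gr
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = inv * (dxhat - m1 - xhat * m2) if x.requires_grad else None
        dgamma = (g * xhat).sum(axis=axes) if gamma.requires_grad else None
        dbeta = g.sum(axis=axes) if beta.requires_grad else None
        return dx, dgamma, dbeta

    return Tensor._result(out, (x, gamma, beta), backward)


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Linear-interpolation matrix (n_out, n_in), align_corners convention."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_out == 1 or n_in == 1:
        m[:, 0] = 1.0
        return m
    src = np.arange(n_out, dtype=np.float64) * (n_in - 1) / (n_out - 1)
    i0 = np.floor(src).astype(int)
    i0 = np.minimum(i0, n_in - 2)
    frac = src - i0
    m[np.arange(n_out), i0] = 1.0 - frac
    m[np.arange(n_out), i0 + 1] = frac
    return m


def resize_trilinear(x: Tensor, out_shape: tuple[int, int, int]) -> Tensor:
    """Trilinear resize of a (C, D, H, W) map to (C, *out_shape); the
    backward pass is the exact adjoint (transposed interpolation)."""
    mats = [
        _interp_matrix(out_shape[a], x.shape[1 + a], x.data.dtype) for a in range(3)
    ]

    def apply(arr, matrices):
        for axis, m in enumerate(matrices):
            arr = np.moveaxis(np.tensordot(m, arr, axes=(1, axis + 1)), 0, axis + 1)
        return arr

    data = apply(x.data, mats)

    def backward(g):
        return (apply(np.asarray(g), [m.T for m in mats]),)

    return Tensor._result(data, (x,), backward)


# ---------------------------------------------------------------------------
# parameters / modules
# ---------------------------------------------------------------------------


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Lightweight layer container mirroring the torch.nn.Module contract."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for _, v in vars(self).items():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for _, v in vars(self).items():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


def kaiming_conv_weight(
    rng: np.random.Generator, c_out: int, c_in: int, k: int, negative_slope: float = 0.01
) -> np.ndarray:
    fan_in = c_in * k ** 3
    gain = math.sqrt(2.0 / (1.0 + negative_slope ** 2))
    std = gain / math.sqrt(fan_in)
    return rng.normal(0.0, std, size=(c_out, c_in, k, k, k)).astype(np.float32)
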