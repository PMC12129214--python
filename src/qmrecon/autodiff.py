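"""Minimal reverse-mode automatic differentiation over numpy arrays.

The unrolled reconstruction network alternates a convolutional denoiser with a
conjugate-gradient data-consistency solve; training it requires gradients that
flow through both, including the CG recursion itself. This module provides the
tape-based autodiff core sized to that model family: elementwise arithmetic on
real and complex arrays, reductions, 2D convolution, the centered orthonormal
FFT pair, and a ``checkpoint`` combinator that implements gradient
checkpointing (recompute-on-backward) with bit-identical forward results.

Complex gradients use the steepest-ascent convention: for a real-valued loss
``L`` and a complex tensor ``z``, ``z.grad == dL/dRe(z) + 1j*dL/dIm(z)``
(twice the conjugate Wirtinger derivative). Under this convention the
vector-Jacobian product of a C-linear map ``A`` is its Hermitian adjoint, and
gradients of real tensors are the ordinary real gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add", "sub", "mul", "div", "neg",
    "conj", "real", "imag", "make_complex", "absolute", "sqrt", "relu",
    "tsum", "reshape", "matmul", "conv2d",
    "fft2c", "ifft2c",
    "complex_to_channels", "channels_to_complex",
    "checkpoint", "graph_size",
]

_grad_enabled = True


class no_grad:
    """Context manager that suppresses graph recording."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype.kind == "f" and data.dtype != np.float64:
            data = data.astype(np.float64)
        elif data.dtype.kind == "c" and data.dtype != np.complex128:
            data = data.astype(np.complex128)
        elif data.dtype.kind in "iub":
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._vjp = None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def zero_grad(self):
        self.grad = None

    def item(self):
        return self.data.item()

    def __float__(self):
        d = self.data
        return float(d.real) if d.dtype.kind == "c" else float(d)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    # operators route through the module-level functions
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor.

        ``grad`` seeds the output gradient (defaults to ones, which is the
        usual scalar-loss case).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        _accum(self, grad)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            gs = node._vjp(node.grad)
            for p, g in zip(node._parents, gs):
                if p.requires_grad and g is not None:
                    _accum(p, g)
            if node is not self:
                # free intermediate gradients; leaves keep theirs
                if node._parents:
                    node.grad = None


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _accum(t: Tensor, g) -> None:
    g = _unbroadcast(np.asarray(g), t.data.shape)
    if t.data.dtype.kind != "c" and np.iscomplexobj(g):
        g = g.real
    t.grad = g if t.grad is None else t.grad + g


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _node(data, parents, vjp):
    # `vjp` must return one gradient per entry of `parents`, tensor or not;
    # constants are dropped here so the backward sweep only sees live tensors.
    keep = [_is_tensor(p) and p.requires_grad for p in parents]
    rg = _grad_enabled and any(keep)
    out = Tensor(data, requires_grad=rg)
    if rg:
        out._parents = tuple(p for p, k in zip(parents, keep) if k)

        def _filtered(g, vjp=vjp, keep=keep):
            gs = vjp(g)
            if len(gs) != len(keep):
                raise RuntimeError("vjp arity mismatch")
            return tuple(gv for gv, k in zip(gs, keep) if k)

        out._vjp = _filtered
    return out


# -- elementwise ----------------------------------------------------------

def add(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.add(a, b)
    da, db = _data(a), _data(b)
    return _node(da + db, (a, b), lambda g: (g, g))


def sub(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.subtract(a, b)
    da, db = _data(a), _data(b)
    return _node(da - db, (a, b), lambda g: (g, -g))


def neg(a):
    if not _is_tensor(a):
        return -np.asarray(a)
    return _node(-a.data, (a,), lambda g: (-g,))


def mul(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.multiply(a, b)
    da, db = _data(a), _data(b)
    return _node(da * db, (a, b), lambda g: (np.conj(db) * g, np.conj(da) * g))


def div(a, b):
    """Elementwise a / b."""
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.divide(a, b)
    da, db = _data(a), _data(b)

    def vjp(g):
        ga = g / np.conj(db)
        gb = -np.conj(da / (db * db)) * g
        return ga, gb

    return _node(da / db, (a, b), vjp)


def conj(a):
    if not _is_tensor(a):
        return np.conj(a)
    return _node(np.conj(a.data), (a,), lambda g: (np.conj(g),))


def real(a):
    if not _is_tensor(a):
        return np.real(a)
    return _node(a.data.real.copy(), (a,), lambda g: (g,))


def imag(a):
    if not _is_tensor(a):
        return np.imag(a)
    return _node(a.data.imag.copy(), (a,), lambda g: (1j * g,))


def make_complex(re, im):
    if not (_is_tensor(re) or _is_tensor(im)):
        return np.asarray(re) + 1j * np.asarray(im)
    dr, di = _data(re), _data(im)
    return _node(dr + 1j * di, (re, im), lambda g: (np.real(g), np.imag(g)))


def absolute(a):
    """Elementwise modulus; subgradient 0 at the origin."""
    if not _is_tensor(a):
        return np.abs(a)
    da = a.data
    mag = np.abs(da)

    def vjp(g):
        safe = np.where(mag == 0.0, 1.0, mag)
        return (g * da / safe,)

    return _node(mag, (a,), vjp)


def sqrt(a):
    if not _is_tensor(a):
        return np.sqrt(a)
    out = np.sqrt(a.data)

    def vjp(g):
        safe = np.where(out == 0.0, np.inf, out)
        return (g / (2.0 * safe),)

    return _node(out, (a,), vjp)


def relu(a):
    if not _is_tensor(a):
        return np.maximum(a, 0.0)
    mask = a.data > 0
    return _node(np.where(mask, a.data, 0.0), (a,), lambda g: (g * mask,))


# -- shape / reductions ---------------------------------------------------

def tsum(a, axis=None):
    if not _is_tensor(a):
        return np.sum(a, axis=axis)
    shape = a.data.shape

    def vjp(g):
        if axis is None:
            return (np.broadcast_to(g, shape),)
        gx = np.expand_dims(g, axis)
        return (np.broadcast_to(gx, shape),)

    return _node(np.sum(a.data, axis=axis), (a,), vjp)


def reshape(a, shape):
    if not _is_tensor(a):
        return np.reshape(a, shape)
    old = a.data.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def matmul(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.matmul(a, b)
    da, db = _data(a), _data(b)

    def vjp(g):
        return (g @ np.conj(db).T, np.conj(da).T @ g)

    return _node(da @ db, (a, b), vjp)


# -- convolution ----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(C, H+kh-1, W+kw-1) padded input -> (C*kh*kw, H*W) patch matrix."""
    c, hp, wp = x.shape
    h, w = hp - kh + 1, wp - kw + 1
    s0, s1, s2 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, shape=(c, kh, kw, h, w), strides=(s0, s1, s2, s1, s2), writeable=False
    )
    return view.reshape(c * kh * kw, h * w)


def conv2d(x, w, b):
    """Same-padded 2D cross-correlation.

    x: (Cin, H, W) real; w: (Cout, Cin, kh, kw) real (odd kernel); b: (Cout,).
    """
    dx, dw, db_ = _data(x), _data(w), _data(b)
    cout, cin, kh, kw = dw.shape
    if dx.shape[0] != cin:
        raise ValueError(f"conv2d: input has {dx.shape[0]} channels, weight expects {cin}")
    h, wd = dx.shape[1], dx.shape[2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(dx, ((0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw)  # (Cin*kh*kw, H*W)
    wmat = dw.reshape(cout, cin * kh * kw)
    out = (wmat @ cols).reshape(cout, h, wd) + db_[:, None, None]
    if not (_is_tensor(x) or _is_tensor(w) or _is_tensor(b)):
        return out

    def vjp(g):
        gf = g.reshape(cout, h * wd)
        gw = (gf @ cols.T).reshape(dw.shape)
        gb = gf.sum(axis=1)
        gcols = wmat.T @ gf  # (Cin*kh*kw, H*W)
        gxp = np.zeros_like(xp)
        gc = gcols.reshape(cin, kh, kw, h, wd)
        for i in range(kh):
            for j in range(kw):
                gxp[:, i:i + h, j:j + wd] += gc[:, i, j]
        gx = gxp[:, ph:ph + h, pw:pw + wd]
        return gx, gw, gb

    return _node(out, (x, w, b), vjp)


# -- Fourier --------------------------------------------------------------

_AXES = (-2, -1)


def _fft2c_np(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def _ifft2c_np(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def fft2c(a):
    """Centered orthonormal 2D DFT over the trailing two axes (unitary)."""
    if not _is_tensor(a):
        return _fft2c_np(np.asarray(a, dtype=np.complex128))
    return _node(_fft2c_np(a.data.astype(np.complex128)), (a,), lambda g: (_ifft2c_np(g),))


def ifft2c(a):
    """Inverse (= adjoint) of :func:`fft2c`."""
    if not _is_tensor(a):
        return _ifft2c_np(np.asarray(a, dtype=np.complex128))
    return _node(_ifft2c_np(a.data.astype(np.complex128)), (a,), lambda g: (_fft2c_np(g),))


# -- complex <-> channel packing ------------------------------------------

def complex_to_channels(a):
    """(P, H, W) complex -> (2P, H, W) real: real parts then imaginary parts."""
    da = _data(a)
    out = np.concatenate([da.real, da.imag], axis=0)
    if not _is_tensor(a):
        return out
    p = da.shape[0]
    return _node(out, (a,), lambda g: (g[:p] + 1j * g[p:],))


def channels_to_complex(a):
    """(2P, H, W) real -> (P, H, W) complex."""
    da = _data(a)
    p = da.shape[0] // 2
    out = da[:p] + 1j * da[p:]
    if not _is_tensor(a):
        return out
    return _node(out, (a,), lambda g: (np.concatenate([g.real, g.imag], axis=0),))


# -- gradient checkpointing ------------------------------------------------

def checkpoint(fn, *args):
    """Run ``fn(*args)`` without retaining its internal graph.

    The forward pass executes under ``no_grad`` (the identical numpy call
    sequence, hence bit-identical outputs) and only the segment inputs are
    kept. During the backward sweep the segment is recomputed with recording
    enabled and back-propagated locally, so peak retained state is the stored
    checkpoints plus one segment's activations.
    """
    tensor_args = [a if _is_tensor(a) else None for a in args]
    needs = _grad_enabled and any(t is not None and t.requires_grad for t in tensor_args)
    if not needs:
        with no_grad():
            return fn(*args)
    with no_grad():
        out = fn(*args)
    out_data = out.data if _is_tensor(out) else np.asarray(out)

    def vjp(g):
        leaves = []
        call_args = []
        for a, t in zip(args, tensor_args):
            if t is None:
                call_args.append(a)
            else:
                leaf = Tensor(t.data, requires_grad=t.requires_grad)
                call_args.append(leaf)
                leaves.append(leaf)
        out2 = fn(*call_args)
        out2.backward(grad=g)
        return tuple(leaf.grad for leaf in leaves)

    parents = tuple(t for t in tensor_args if t is not None)
    return _node(out_data, parents, vjp)


def graph_size(t: Tensor) -> int:
    """Number of recorded (non-leaf) nodes reachable from ``t``.

    Proxy for retained intermediate activations: under checkpointing this is
    bounded by the number of segments, independent of the work inside each.
    """
    seen = set()
    stack = [t]
    count = 0
    while stack:
        node = stack.pop()
        if id(node) in seen or not isinstance(node, Tensor):
            continue
        seen.add(id(node))
        if node._parents:
            count += 1
            stack.extend(node._parents)
    return count
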