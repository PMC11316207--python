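"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for a 3D segmentation network: tensors carry a value
and an optional gradient; operations record backward closures on a tape and
``backward()`` walks the graph in reverse topological order.  Activations
are float32 throughout; gradient accumulation happens in float32 as well.

Ops provided: 3D convolution (im2col + GEMM, odd kernels, "same" padding),
batch normalization, ReLU, sigmoid, cubic max-pooling, nearest-neighbour
upsampling, channel concatenation, elementwise multiply by a constant
(used for DropConnect weight masking), addition, and the F(beta) overlap
loss as a fused op with an analytic derivative.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph: ndarray value + optional grad."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs are deep
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


def _node(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
    if out.requires_grad:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> offset-major columns (k^3 * C, N*D*H*W).

    Row index runs (offset, channel); this layout copies simple strided
    slices, which is considerably faster than window-view transposes.
    """
    n, c, d, h, w = x.shape
    if k == 1:
        return x.transpose(1, 0, 2, 3, 4).reshape(c, -1)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    cols = np.empty((k**3, c, n * d * h * w), dtype=x.dtype)
    o = 0
    for di in range(k):
        for dj in range(k):
            for dl in range(k):
                cols[o] = (
                    xp[:, :, di : di + d, dj : dj + h, dl : dl + w]
                    .transpose(1, 0, 2, 3, 4)
                    .reshape(c, -1)
                )
                o += 1
    return cols.reshape(k**3 * c, -1)


def _w_mat(w: np.ndarray) -> np.ndarray:
    """(Cout, Cin, k, k, k) -> (Cout, k^3 * Cin) matching _im2col's row order."""
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    return np.ascontiguousarray(w.transpose(0, 2, 3, 4, 1)).reshape(co, k**3 * ci)


def _mat_w(wm: np.ndarray, shape) -> np.ndarray:
    co, ci, k = shape[0], shape[1], shape[2]
    return np.ascontiguousarray(wm.reshape(co, k, k, k, ci).transpose(0, 4, 1, 2, 3))


def conv3d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None) -> np.ndarray:
    """Plain forward convolution; w is (Cout, Cin, k, k, k)."""
    n, _, d, h, wd = x.shape
    co = w.shape[0]
    out = _w_mat(w) @ _im2col(x, w.shape[2])  # (Co, N*P)
    if b is not None:
        out += b[:, None]
    return np.ascontiguousarray(out.reshape(co, n, d, h, wd).transpose(1, 0, 2, 3, 4))


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same'-padded stride-1 3D convolution with an odd cubic kernel."""
    co, ci, k = w.shape[0], w.shape[1], w.shape[2]
    if x.shape[1] != ci:
        raise ValueError(f"conv3d: input has {x.shape[1]} channels, kernel expects {ci}")
    n, _, d, h, wd = x.shape
    cols = _im2col(x.data, k)
    out = _w_mat(w.data) @ cols
    if b is not None:
        out += b.data[:, None]
    out = np.ascontiguousarray(out.reshape(co, n, d, h, wd).transpose(1, 0, 2, 3, 4))

    def backward(g: np.ndarray) -> None:
        gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3, 4)).reshape(co, -1)
        if w.requires_grad:
            w.accumulate(_mat_w(gm @ cols.T, w.shape))
        if b is not None and b.requires_grad:
            b.accumulate(gm.sum(axis=1))
        if x.requires_grad:
            # full correlation: convolve grad with flipped, channel-transposed kernel
            wt = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            x.accumulate(conv3d_raw(g, wt, None))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


# ---------------------------------------------------------------------------
# pointwise and normalization ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * mask)

    return _node(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    s = s.astype(np.float32)

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * s * (1.0 - s))

    return _node(s, (x,), backward)


def mul_const(x: Tensor, c: np.ndarray) -> Tensor:
    """Elementwise multiply by a constant array (DropConnect masks)."""
    out = x.data * c

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(g * c)

    return _node(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return _node(out, (a, b), backward)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (batch, spatial) axes.

    In training mode the batch statistics are used and the running
    estimates are updated in place; in eval mode the running estimates are
    used (a fixed affine map, so inference is deterministic).
    """
    c = x.shape[1]
    axes = (0, 2, 3, 4)
    gshape = (1, c, 1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(gshape)) * inv.reshape(gshape)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    m = x.data.size // c  # elements per channel

    def backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gi = g * gamma.data.reshape(gshape)
            if training:
                gx = (
                    gi
                    - gi.mean(axis=axes).reshape(gshape)
                    - xhat * (gi * xhat).mean(axis=axes).reshape(gshape)
                ) * inv.reshape(gshape)
            else:
                gx = gi * inv.reshape(gshape)
            x.accumulate(gx.astype(np.float32))

    return _node(out.astype(np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# resolution ops
# ---------------------------------------------------------------------------

def maxpool(x: Tensor, k: int) -> Tensor:
    """k x k x k max pooling with stride k (k = 2 or 4 here)."""
    n, c, d, h, w = x.shape
    if d % k or h % k or w % k:
        raise ValueError(
            f"spatial shape {(d, h, w)} is not divisible by the pooling factor {k}; "
            "choose patch sizes compatible with the downsampling stack"
        )
    do, ho, wo = d // k, h // k, w // k
    xr = x.data.reshape(n, c, do, k, ho, k, wo, k).transpose(0, 1, 2, 4, 6, 3, 5, 7)
    xr = np.ascontiguousarray(xr).reshape(n, c, do, ho, wo, k**3)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gwin = np.zeros((n, c, do, ho, wo, k**3), dtype=np.float32)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gx = gwin.reshape(n, c, do, ho, wo, k, k, k).transpose(0, 1, 2, 5, 3, 6, 4, 7)
            x.accumulate(np.ascontiguousarray(gx).reshape(n, c, d, h, w))

    return _node(out, (x,), backward)


def upsample_nearest(x: Tensor, k: int = 2) -> Tensor:
    out = x.data.repeat(k, axis=2).repeat(k, axis=3).repeat(k, axis=4)
    n, c, d, h, w = x.shape

    def backward(g: np.ndarray) -> None:
        if x.requires_grad:
            gr = g.reshape(n, c, d, k, h, k, w, k).sum(axis=(3, 5, 7))
            x.accumulate(gr)

    return _node(out, (x,), backward)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    splits = np.cumsum([t.shape[1] for t in tensors])[:-1]

    def backward(g: np.ndarray) -> None:
        parts = np.split(g, splits, axis=1)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(p)

    return _node(out, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def fbeta_loss_op(y: np.ndarray, yhat: Tensor, beta: float, epsilon: float = 1e-3) -> Tensor:
    """F(beta) overlap loss, fused with its analytic gradient.

        F = 1 - ((1+beta) * sum(y*yhat) + eps) / (beta * sum(y) + sum(yhat) + eps)

    beta > 1 weights recall, beta < 1 precision.  The loss lies in [0, 1)
    for binary y and probabilities yhat.
    """
    y = np.asarray(y, dtype=np.float32)
    if y.shape != yhat.shape:
        raise ValueError(f"label shape {y.shape} != prediction shape {yhat.shape}")
    s_inter = float((y * yhat.data).sum(dtype=np.float64))
    s_y = float(y.sum(dtype=np.float64))
    s_hat = float(yhat.data.sum(dtype=np.float64))
    num = (1.0 + beta) * s_inter + epsilon
    den = beta * s_y + s_hat + epsilon
    loss = 1.0 - num / den

    def backward(g: np.ndarray) -> None:
        if yhat.requires_grad:
            gs = float(g)
            d = (-(1.0 + beta) * y / den + num / den**2) * gs
            yhat.accumulate(d.astype(np.float32))

    return _node(np.float32(loss), (yhat,), backward)
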