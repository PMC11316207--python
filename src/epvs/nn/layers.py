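"""Layer modules wrapping the autograd ops, with parameter registries.

Every convolutional block follows the quoted encoder recipe: 3x3x3 kernels,
stride 1, zero padding, ReLU, then batch normalization.  DropConnect masks
individual convolution weights with Bernoulli(1-p) noise during training
(rescaled by 1/(1-p)); at inference weights are used as-is, so prediction
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, batchnorm, conv3d, mul_const, relu


@dataclass
class ForwardContext:
    """Per-forward-pass state: mode, DropConnect rate and its RNG."""

    training: bool = False
    dropconnect_p: float = 0.0
    rng: np.random.Generator | None = None


class Layer:
    def params(self) -> dict[str, Tensor]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        return {}

    def kernels(self) -> list[Tensor]:
        """Convolution weight tensors (targets of L2 decay and DropConnect)."""
        return []


class Conv3d(Layer):
    """Stride-1, same-padded 3D convolution with He-initialized weights."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, bias: bool = True):
        fan_in = c_in * k**3
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, size=(c_out, c_in, k, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        w = self.w
        if ctx.training and ctx.dropconnect_p > 0:
            keep = 1.0 - ctx.dropconnect_p
            mask = (ctx.rng.random(self.w.shape) < keep).astype(np.float32) / keep
            w = mul_const(self.w, mask)
        return conv3d(x, w, self.b)

    def params(self) -> dict[str, Tensor]:
        p = {"w": self.w}
        if self.b is not None:
            p["b"] = self.b
        return p

    def kernels(self) -> list[Tensor]:
        return [self.w]


class BatchNorm3d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        return batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=ctx.training,
            momentum=self.momentum,
            eps=self.eps,
        )

    def params(self) -> dict[str, Tensor]:
        return {"gamma": self.gamma, "beta": self.beta}

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ConvBlock(Layer):
    """conv 3x3x3 -> ReLU -> BN."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = Conv3d(c_in, c_out, 3, rng)
        self.bn = BatchNorm3d(c_out)

    def forward(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        return self.bn.forward(relu(self.conv.forward(x, ctx)), ctx)

    def params(self) -> dict[str, Tensor]:
        out = {f"conv.{k}": v for k, v in self.conv.params().items()}
        out.update({f"bn.{k}": v for k, v in self.bn.params().items()})
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        return {f"bn.{k}": v for k, v in self.bn.buffers().items()}

    def kernels(self) -> list[Tensor]:
        return self.conv.kernels()


class BlockChain(Layer):
    """A fixed sequence of ConvBlocks (the per-level stack)."""

    def __init__(self, c_in: int, c_out: int, n_blocks: int, rng: np.random.Generator):
        self.blocks = [
            ConvBlock(c_in if i == 0 else c_out, c_out, rng) for i in range(n_blocks)
        ]

    def forward(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        for blk in self.blocks:
            x = blk.forward(x, ctx)
        return x

    def params(self) -> dict[str, Tensor]:
        out = {}
        for i, blk in enumerate(self.blocks):
            out.update({f"{i}.{k}": v for k, v in blk.params().items()})
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for i, blk in enumerate(self.blocks):
            out.update({f"{i}.{k}": v for k, v in blk.buffers().items()})
        return out

    def kernels(self) -> list[Tensor]:
        return [t for blk in self.blocks for t in blk.kernels()]
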