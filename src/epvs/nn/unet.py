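"""The two-stage triple-U-Net segmentation network.

Three structurally identical U-Nets: A and B sit in parallel in stage 1 and
receive the same 19-channel input (normalized image, 12 PCA feature maps,
white-matter mask, five lobar masks); C sits in stage 2 and consumes
stage-1 feature maps, concatenated at every encoder and decoder level.
Each U-Net has four resolution levels (three 2x2x2 max-pool downsamplings).
The first two level transitions run a dual path — convolution-then-pool in
parallel with pool-then-convolution — fused by concatenation, and a 4x4x4
stride-4 pool of the network input feeds directly into the third-resolution
encoder level.  Decoding uses nearest-neighbour 2x2x2 upsampling with
same-level encoder skips.  Each U-Net ends in a 1x1x1 convolution and a
sigmoid, producing a voxel-wise probability map; training uses all three
heads, inference the stage-2 head only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, concat, maxpool, sigmoid, upsample_nearest
from .layers import BlockChain, Conv3d, ForwardContext, Layer

#: channels of the default pipeline input:
#: 1 image + 12 PCA maps + 1 WM mask + 5 lobar masks
DEFAULT_IN_CHANNELS = 19


@dataclass
class NetworkConfig:
    in_channels: int = DEFAULT_IN_CHANNELS
    base_channels: int = 64
    n_downsamplings: int = 3
    convs_per_level: int = 2
    betas: tuple[float, float, float] = (10.0, 0.1, 1.0)
    epsilon: float = 1e-3
    dropconnect_p: float = 0.3
    l2_weight: float = 0.001

    def __post_init__(self) -> None:
        self.betas = tuple(float(b) for b in self.betas)
        if len(self.betas) != 3 or any(b <= 0 for b in self.betas):
            raise ValueError(f"betas must be 3 positive reals, got {self.betas}")
        if not (0.0 <= self.dropconnect_p < 1.0):
            raise ValueError(f"dropconnect_p must be in [0, 1), got {self.dropconnect_p}")
        if self.n_downsamplings != 3:
            raise ValueError("the architecture is defined for exactly 3 downsamplings")
        if self.in_channels < 1 or self.base_channels < 1 or self.convs_per_level < 1:
            raise ValueError("in_channels, base_channels and convs_per_level must be >= 1")

    @property
    def downsample_factor(self) -> int:
        return 2**self.n_downsamplings


class UNet(Layer):
    """One encoder-decoder with the dual-path multi-scale encoder.

    ``cross_channels`` gives the extra channel count concatenated at each
    encoder level (1..3) and decoder level (2..0) — zero for stage-1 nets,
    2 * base_channels for the stage-2 net.
    """

    def __init__(
        self,
        c_in: int,
        width: int,
        convs_per_level: int,
        rng: np.random.Generator,
        cross_channels: int = 0,
    ):
        w, nb, cc = width, convs_per_level, cross_channels
        self.cross_channels = cc
        self.enc0a = BlockChain(c_in, w, nb, rng)
        self.enc0b = BlockChain(c_in, w, nb, rng)
        c1 = 2 * w + cc
        self.enc1a = BlockChain(c1, w, nb, rng)
        self.enc1b = BlockChain(c1, w, nb, rng)
        c2 = 2 * w + c_in + cc  # dual path + stride-4 pooled input
        self.enc2 = BlockChain(c2, w, nb, rng)
        self.enc3 = BlockChain(w + cc, w, nb, rng)
        self.dec2 = BlockChain(2 * w + cc, w, nb, rng)
        self.dec1 = BlockChain(2 * w + cc, w, nb, rng)
        self.dec0 = BlockChain(2 * w + cc, w, nb, rng)
        self.head = Conv3d(w, 1, 1, rng)
        # start the sigmoid head at a background prior (~12% foreground):
        # EPVS occupy a tiny voxel fraction, and a sparse initial
        # prediction keeps the overlap-loss denominator informative
        self.head.b.data[...] = -2.0

    def forward(
        self,
        x: Tensor,
        ctx: ForwardContext,
        cross_e: dict[int, Tensor] | None = None,
        cross_d: dict[int, Tensor] | None = None,
    ) -> dict[str, Tensor]:
        ce = cross_e or {}
        cd = cross_d or {}

        def cat(parts, extra):
            return concat(parts + [extra]) if extra is not None else (
                concat(parts) if len(parts) > 1 else parts[0]
            )

        s0 = self.enc0a.forward(x, ctx)
        u1 = cat([maxpool(s0, 2), self.enc1_dual_b(x, ctx)], ce.get(1))
        s1 = self.enc1a.forward(u1, ctx)
        u2 = cat(
            [maxpool(s1, 2), self.enc1b.forward(maxpool(u1, 2), ctx), maxpool(x, 4)],
            ce.get(2),
        )
        e2 = self.enc2.forward(u2, ctx)
        u3 = cat([maxpool(e2, 2)], ce.get(3))
        e3 = self.enc3.forward(u3, ctx)

        d2 = self.dec2.forward(cat([upsample_nearest(e3), e2], cd.get(2)), ctx)
        d1 = self.dec1.forward(cat([upsample_nearest(d2), s1], cd.get(1)), ctx)
        d0 = self.dec0.forward(cat([upsample_nearest(d1), s0], cd.get(0)), ctx)
        prob = sigmoid(self.head.forward(d0, ctx))
        return {"s0": s0, "s1": s1, "e2": e2, "e3": e3, "d2": d2, "d1": d1, "d0": d0, "prob": prob}

    def enc1_dual_b(self, x: Tensor, ctx: ForwardContext) -> Tensor:
        """Pool-then-convolve branch of the first dual-path transition."""
        return self.enc0b.forward(maxpool(x, 2), ctx)

    def _children(self) -> dict[str, Layer]:
        return {
            "enc0a": self.enc0a,
            "enc0b": self.enc0b,
            "enc1a": self.enc1a,
            "enc1b": self.enc1b,
            "enc2": self.enc2,
            "enc3": self.enc3,
            "dec2": self.dec2,
            "dec1": self.dec1,
            "dec0": self.dec0,
            "head": self.head,
        }

    def params(self) -> dict[str, Tensor]:
        out = {}
        for name, child in self._children().items():
            out.update({f"{name}.{k}": v for k, v in child.params().items()})
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for name, child in self._children().items():
            out.update({f"{name}.{k}": v for k, v in child.buffers().items()})
        return out

    def kernels(self) -> list[Tensor]:
        return [t for child in self._children().values() for t in child.kernels()]


class SegModel(Layer):
    """The full two-stage model: stage-1 U-Nets A and B, stage-2 U-Net C."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        init_rng = np.random.default_rng(seed)
        w = config.base_channels
        self.unet_a = UNet(config.in_channels, w, config.convs_per_level, init_rng)
        self.unet_b = UNet(config.in_channels, w, config.convs_per_level, init_rng)
        self.unet_c = UNet(2 * w, w, config.convs_per_level, init_rng, cross_channels=2 * w)
        #: RNG driving DropConnect masks during training
        self.dropout_rng = np.random.default_rng(seed + 1)

    # -- forward -----------------------------------------------------------
    def _check_spatial(self, shape) -> None:
        f = self.config.downsample_factor
        if any(s % f for s in shape[2:]):
            raise ValueError(
                f"spatial shape {tuple(shape[2:])} is not divisible by the downsampling "
                f"factor {f}; choose a compatible patch size (default 64x64x24 is)"
            )

    def forward(self, x, training: bool = False) -> tuple[Tensor, Tensor, Tensor]:
        """Return the three sigmoid heads' probability maps (A, B, C)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.data.ndim == 4:
            x = Tensor(x.data[None])
        self._check_spatial(x.shape)
        ctx = ForwardContext(
            training=training,
            dropconnect_p=self.config.dropconnect_p if training else 0.0,
            rng=self.dropout_rng,
        )
        fa = self.unet_a.forward(x, ctx)
        fb = self.unet_b.forward(x, ctx)
        xc = concat([fa["d0"], fb["d0"]])
        cross_e = {
            1: concat([fa["s1"], fb["s1"]]),
            2: concat([fa["e2"], fb["e2"]]),
            3: concat([fa["e3"], fb["e3"]]),
        }
        cross_d = {
            2: concat([fa["d2"], fb["d2"]]),
            1: concat([fa["d1"], fb["d1"]]),
            0: concat([fa["d0"], fb["d0"]]),
        }
        fc = self.unet_c.forward(xc, ctx, cross_e, cross_d)
        return fa["prob"], fb["prob"], fc["prob"]

    # -- bookkeeping -------------------------------------------------------
    def _children(self) -> dict[str, UNet]:
        return {"unet_a": self.unet_a, "unet_b": self.unet_b, "unet_c": self.unet_c}

    def params(self) -> dict[str, Tensor]:
        out = {}
        for name, child in self._children().items():
            out.update({f"{name}.{k}": v for k, v in child.params().items()})
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for name, child in self._children().items():
            out.update({f"{name}.{k}": v for k, v in child.buffers().items()})
        return out

    def kernels(self) -> list[Tensor]:
        return [t for child in self._children().values() for t in child.kernels()]

    @property
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params().values()))

    def zero_grad(self) -> None:
        for p in self.params().values():
            p.zero_grad()

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {f"param:{k}": v.data.copy() for k, v in self.params().items()}
        out.update({f"buffer:{k}": v.copy() for k, v in self.buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.params()
        buffers = self.buffers()
        for key, val in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data[...] = val
            else:
                buffers[name][...] = val

    def save(self, path) -> None:
        np.savez_compressed(
            str(path),
            __config__=np.frombuffer(json.dumps(asdict(self.config)).encode(), dtype=np.uint8),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "SegModel":
        with np.load(str(path)) as data:
            cfg = json.loads(bytes(data["__config__"]).decode())
            cfg["betas"] = tuple(cfg["betas"])
            model = cls(NetworkConfig(**cfg))
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


def build_model(config: NetworkConfig | None = None, seed: int = 0) -> SegModel:
    """Construct the triple U-Net from a configuration."""
    return SegModel(config or NetworkConfig(), seed=seed)


# ---------------------------------------------------------------------------
# whole-volume inference
# ---------------------------------------------------------------------------

def _window_starts(extent: int, size: int, step: int) -> list[int]:
    starts = list(range(0, max(extent - size, 0) + 1, step))
    if starts[-1] + size < extent:
        starts.append(extent - size)
    return starts


def predict_volume(
    model: SegModel,
    inputs: np.ndarray,
    patch_size: tuple[int, int, int] = (64, 64, 24),
    overlap_fraction: float = 0.5,
) -> np.ndarray:
    """Sliding-window stage-2 probabilities over a full volume.

    Windows overlap by ``overlap_fraction`` and per-voxel probabilities are
    averaged over all covering windows.  Volumes smaller than the patch in
    some axis are reflect-padded, predicted, and cropped back.
    """
    inputs = np.asarray(inputs, dtype=np.float32)
    if inputs.ndim != 4:
        raise ValueError(f"expected (channels, X, Y, Z) inputs, got shape {inputs.shape}")
    if inputs.shape[0] != model.config.in_channels:
        raise ValueError(
            f"model expects {model.config.in_channels} channels, got {inputs.shape[0]}"
        )
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must be in [0, 1)")
    shape = inputs.shape[1:]
    pad = [(0, max(p - s, 0)) for p, s in zip(patch_size, shape)]
    if any(p[1] for p in pad):
        inputs = np.pad(inputs, [(0, 0)] + pad, mode="reflect")
    padded_shape = inputs.shape[1:]

    acc = np.zeros(padded_shape, dtype=np.float64)
    cnt = np.zeros(padded_shape, dtype=np.float64)
    steps = [max(int(round(p * (1.0 - overlap_fraction))), 1) for p in patch_size]
    for sx in _window_starts(padded_shape[0], patch_size[0], steps[0]):
        for sy in _window_starts(padded_shape[1], patch_size[1], steps[1]):
            for sz in _window_starts(padded_shape[2], patch_size[2], steps[2]):
                sl = (
                    slice(sx, sx + patch_size[0]),
                    slice(sy, sy + patch_size[1]),
                    slice(sz, sz + patch_size[2]),
                )
                patch = inputs[(slice(None),) + sl]
                _, _, pc = model.forward(patch[None], training=False)
                acc[sl] += pc.data[0, 0]
                cnt[sl] += 1.0
    prob = acc / cnt
    prob = prob[: shape[0], : shape[1], : shape[2]]
    return np.clip(prob, 0.0, 1.0).astype(np.float32)
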