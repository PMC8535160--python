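"""The density-map predictor: a lightweight U-net with residual blocks and a
dot-product nonlocal bottleneck.

The network maps an image to a non-negative density map at the same
resolution; the map's integral estimates the nucleus count and its local
maxima mark centroids. Residual blocks are distributed over the encoder
levels and the bottleneck, a self-attention (nonlocal) block sits at the
bottom of the U, ReLU is the activation everywhere including the output, so
predicted densities are non-negative by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import Conv2d, NonLocalBlock, Param, ReLU, ReLUWithRecovery, ResidualBlock, Upsample2x

__all__ = [
    "NetworkConfig",
    "DensityMap",
    "LIRNet",
    "build_model",
    "predict_density",
    "nonlocal_attention",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``blocks_per_level`` (optional) gives the residual-block count per slot
    (``depth`` encoder levels then the bottleneck); when omitted,
    ``n_residual_blocks`` is spread as evenly as possible with the remainder
    assigned to the bottleneck. ``dtype`` is float32 for training speed;
    gradient checks use float64 instances.
    """

    in_channels: int = 3
    base_channels: int = 32
    depth: int = 3
    n_residual_blocks: int = 9
    blocks_per_level: tuple[int, ...] | None = None
    nonlocal_enabled: bool = True
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.in_channels not in (1, 3):
            raise ValueError("in_channels must be 1 or 3")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_residual_blocks < 0:
            raise ValueError("n_residual_blocks must be >= 0")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.blocks_per_level is not None:
            bpl = tuple(int(b) for b in self.blocks_per_level)
            if len(bpl) != self.depth + 1:
                raise ValueError("blocks_per_level must have depth + 1 entries")
            if sum(bpl) != self.n_residual_blocks:
                raise ValueError("blocks_per_level must sum to n_residual_blocks")
            object.__setattr__(self, "blocks_per_level", bpl)

    def resolved_blocks(self) -> tuple[int, ...]:
        if self.blocks_per_level is not None:
            return self.blocks_per_level
        slots = self.depth + 1
        base, rem = divmod(self.n_residual_blocks, slots)
        bpl = [base] * slots
        bpl[-1] += rem  # leftovers go to the bottleneck
        return tuple(bpl)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "blocks_per_level" in raw and raw["blocks_per_level"] is not None:
            raw["blocks_per_level"] = tuple(raw["blocks_per_level"])
        return cls(**raw)


@dataclass
class DensityMap:
    """Non-negative H x W density; the sum estimates the nucleus count."""

    values: np.ndarray
    image_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("density map must be 2-D")
        if v.size and v.min() < 0:
            raise ValueError("density values must be non-negative")
        self.values = v

    @property
    def total(self) -> float:
        return float(self.values.sum())


class LIRNet:
    """Encoder-decoder density regressor.

    Downsampling uses stride-2 convolutions and channel doubling; upsampling
    uses nearest-neighbor interpolation followed by a convolution (avoids
    checkerboard artifacts in the density map); skip connections are
    concatenated and fused by a 3x3 convolution. The head convolution's bias
    starts slightly positive so the output ReLU is not dead at
    initialization.

    Nonlocal-block parameters come from a seed stream separate from the rest
    of the network, so the with/without-attention variants share identical
    initialization everywhere else.
    """

    HEAD_BIAS_INIT = 0.05

    def __init__(self, config: NetworkConfig):
        self.config = config
        dtype = np.dtype(config.dtype)
        ss_main, ss_nl = np.random.SeedSequence(config.seed).spawn(2)
        rng = np.random.default_rng(ss_main)
        bpl = config.resolved_blocks()
        ch = [config.base_channels * 2**i for i in range(config.depth + 1)]

        self.stem = Conv2d(config.in_channels, ch[0], 3, 1, rng, dtype)
        self.stem_act = ReLU()
        self.enc_blocks = [
            [ResidualBlock(ch[i], rng, dtype) for _ in range(bpl[i])]
            for i in range(config.depth)
        ]
        self.down = [Conv2d(ch[i], ch[i + 1], 3, 2, rng, dtype) for i in range(config.depth)]
        self.down_act = [ReLU() for _ in range(config.depth)]
        self.bott_blocks = [ResidualBlock(ch[-1], rng, dtype) for _ in range(bpl[-1])]
        self.nonlocal_block = (
            NonLocalBlock(ch[-1], np.random.default_rng(ss_nl), dtype)
            if config.nonlocal_enabled
            else None
        )
        self.upsample = [Upsample2x() for _ in range(config.depth)]
        self.up_conv = [Conv2d(ch[i + 1], ch[i], 3, 1, rng, dtype) for i in range(config.depth)]
        self.up_act = [ReLU() for _ in range(config.depth)]
        self.fuse = [Conv2d(2 * ch[i], ch[i], 3, 1, rng, dtype) for i in range(config.depth)]
        self.fuse_act = [ReLU() for _ in range(config.depth)]
        self.head = Conv2d(ch[0], 1, 3, 1, rng, dtype)
        self.head.b.data[:] = self.HEAD_BIAS_INIT
        self.head_act = ReLUWithRecovery()
        self._ch = ch

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[Param]:
        out = self.stem.params()
        for level in self.enc_blocks:
            for blk in level:
                out += blk.params()
        for conv in self.down:
            out += conv.params()
        for blk in self.bott_blocks:
            out += blk.params()
        if self.nonlocal_block is not None:
            out += self.nonlocal_block.params()
        for conv in self.up_conv:
            out += conv.params()
        for conv in self.fuse:
            out += conv.params()
        out += self.head.params()
        return out

    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params()
        if len(arrays) != len(params):
            raise ValueError("state does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state does not match architecture")
            p.data[...] = a

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W) image batch -> (N, 1, H, W) non-negative density batch."""
        n, c, h, w = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} channels, got {c}")
        stride = 2**self.config.depth
        if h % stride or w % stride:
            raise ValueError(f"H and W must be divisible by {stride}")
        x = x.astype(np.dtype(self.config.dtype), copy=False)
        x = self.stem_act.forward(self.stem.forward(x))
        skips = []
        for i in range(self.config.depth):
            for blk in self.enc_blocks[i]:
                x = blk.forward(x)
            skips.append(x)
            x = self.down_act[i].forward(self.down[i].forward(x))
        for blk in self.bott_blocks:
            x = blk.forward(x)
        if self.nonlocal_block is not None:
            x = self.nonlocal_block.forward(x)
        for i in reversed(range(self.config.depth)):
            x = self.upsample[i].forward(x)
            x = self.up_act[i].forward(self.up_conv[i].forward(x))
            x = np.concatenate([x, skips[i]], axis=1)
            x = self.fuse_act[i].forward(self.fuse[i].forward(x))
        return self.head_act.forward(self.head.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.head.backward(self.head_act.backward(dout))
        dskips: dict[int, np.ndarray] = {}
        for i in range(self.config.depth):  # reverse of the decoder's i = depth-1 .. 0
            d = self.fuse[i].backward(self.fuse_act[i].backward(d))
            ch_i = self._ch[i]
            d, dskips[i] = d[:, :ch_i], d[:, ch_i:]
            d = self.up_conv[i].backward(self.up_act[i].backward(d))
            d = self.upsample[i].backward(d)
        if self.nonlocal_block is not None:
            d = self.nonlocal_block.backward(d)
        for blk in reversed(self.bott_blocks):
            d = blk.backward(d)
        for i in reversed(range(self.config.depth)):
            d = self.down[i].backward(self.down_act[i].backward(d))
            d = d + dskips[i]
            for blk in reversed(self.enc_blocks[i]):
                d = blk.backward(d)
        return self.stem.backward(self.stem_act.backward(d))


def build_model(config: NetworkConfig) -> LIRNet:
    """Build a seeded network; two builds from the same config are identical."""
    return LIRNet(config)


def _image_to_batch(image: np.ndarray, in_channels: int) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if img.ndim != 3:
        raise ValueError("image must be H x W or H x W x C")
    if img.shape[2] != in_channels:
        raise ValueError(f"image has {img.shape[2]} channels, model expects {in_channels}")
    return img.transpose(2, 0, 1)[None]


def predict_density(model: LIRNet, image: np.ndarray, image_id: str = "") -> DensityMap:
    """Run inference on one H x W (x C) image; deterministic for a fixed model."""
    batch = _image_to_batch(image, model.config.in_channels)
    out = model.forward(batch)
    return DensityMap(out[0, 0].astype(np.float64), image_id=image_id)


def nonlocal_attention(block: NonLocalBlock, features: np.ndarray) -> np.ndarray:
    """Apply a nonlocal block to a single C x H x W feature map."""
    f = np.asarray(features)
    if f.ndim != 3:
        raise ValueError("features must be C x H x W")
    return block.forward(f[None])[0]


# ---------------------------------------------------------------------------
# Checkpoints (npz with the architecture config embedded)
# ---------------------------------------------------------------------------


def save_checkpoint(model: LIRNet, path: str | Path) -> None:
    arrays = {f"p{i:04d}": p.data for i, p in enumerate(model.params())}
    cfg = asdict(model.config)
    np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> LIRNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        if cfg.get("blocks_per_level") is not None:
            cfg["blocks_per_level"] = tuple(cfg["blocks_per_level"])
        model = LIRNet(NetworkConfig(**cfg))
        arrays = [data[k] for k in sorted(k for k in data.files if k.startswith("p"))]
    model.load_state_arrays(arrays)
    return model
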