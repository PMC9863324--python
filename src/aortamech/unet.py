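"""U-Net with instance normalisation for ascending-aorta segmentation.

Symmetric encoder-decoder with skip connections: each level is a pair of 3x3
convolutions, every convolution followed by instance normalisation and ReLU;
channels double per encoder level; 2x2 max-pooling down, nearest-neighbour
upsampling + convolution up; a final 1x1 convolution and sigmoid give a
single-channel probability map. A ``residual_blocks`` toggle turns every
level into a residual block (identity / 1x1-projected shortcut added before
the closing ReLU), giving the Residual-U-Net variant.

The engine is the package's own numpy backprop implementation
(:mod:`aortamech.nn`); training is in :mod:`aortamech.training`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, Conv2d, InstanceNorm, MaxPool2, Param, ReLU, Upsample2, sigmoid, soft_dice_loss_and_grad

__all__ = ["UNetConfig", "UNet", "build_unet", "dice_loss", "DICE_SMOOTH"]

#: Smoothing constant of the soft Dice loss (stability on empty masks).
DICE_SMOOTH = 1e-6


@dataclass(frozen=True)
class UNetConfig:
    """Architecture settings.

    ``input_size`` must be divisible by ``2**depth``; channels start at
    ``base_channels`` and double each level. Only instance normalisation is
    implemented (the variant the segmentation model uses).
    """

    input_size: int = 256
    depth: int = 4
    base_channels: int = 32
    normalization: str = "instance"
    residual_blocks: bool = False

    def __post_init__(self) -> None:
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^depth = {2**self.depth}"
            )
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.normalization != "instance":
            raise ValueError(
                f"normalization {self.normalization!r} not available; this engine "
                "implements instance normalisation"
            )


class ConvBlock:
    """(conv -> IN -> ReLU) x2, optionally with a residual shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, residual: bool):
        self.conv1 = Conv2d(in_ch, out_ch, rng)
        self.norm1 = InstanceNorm(out_ch)
        self.act1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, rng)
        self.norm2 = InstanceNorm(out_ch)
        self.act2 = ReLU()
        self.residual = residual
        self.shortcut = Conv2d(in_ch, out_ch, rng, kernel=1) if residual and in_ch != out_ch else None

    @property
    def params(self) -> list[Param]:
        layers = [self.conv1, self.norm1, self.conv2, self.norm2]
        if self.shortcut is not None:
            layers.append(self.shortcut)
        return [p for layer in layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.act1.forward(self.norm1.forward(self.conv1.forward(x)))
        h = self.norm2.forward(self.conv2.forward(h))
        if self.residual:
            h = h + (self.shortcut.forward(x) if self.shortcut is not None else x)
        return self.act2.forward(h)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.act2.backward(dout)
        d_short = None
        if self.residual:
            d_short = self.shortcut.backward(d) if self.shortcut is not None else d
        d = self.conv2.backward(self.norm2.backward(d))
        d = self.conv1.backward(self.norm1.backward(self.act1.backward(d)))
        if d_short is not None:
            d = d + d_short
        return d


class UNet:
    """Forward/backward U-Net over ``(N, 1, H, W)`` float32 inputs."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.base_channels
        res = config.residual_blocks

        self.enc_blocks: list[ConvBlock] = []
        self.pools: list[MaxPool2] = []
        in_ch = 1
        channels = []
        for level in range(config.depth):
            out_ch = ch * 2**level
            self.enc_blocks.append(ConvBlock(in_ch, out_ch, rng, res))
            self.pools.append(MaxPool2())
            channels.append(out_ch)
            in_ch = out_ch
        self.bottleneck = ConvBlock(in_ch, ch * 2**config.depth, rng, res)

        self.ups: list[Upsample2] = []
        self.dec_blocks: list[ConvBlock] = []
        deep_ch = ch * 2**config.depth
        for skip_ch in reversed(channels):
            self.ups.append(Upsample2())
            self.dec_blocks.append(ConvBlock(deep_ch + skip_ch, skip_ch, rng, res))
            deep_ch = skip_ch
        self.head = Conv2d(deep_ch, 1, rng, kernel=1)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        out = []
        for block in [*self.enc_blocks, self.bottleneck, *self.dec_blocks]:
            out.extend(block.params)
        out.extend(self.head.params)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability maps in [0, 1], same spatial size as the input."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        h, w = x.shape[2:]
        if h != w or h % (2**self.config.depth) != 0:
            raise ValueError(
                f"spatial size {h}x{w} incompatible with depth {self.config.depth}"
            )
        skips = []
        out = x
        for block, pool in zip(self.enc_blocks, self.pools):
            out = block.forward(out)
            skips.append(out)
            out = pool.forward(out)
        out = self.bottleneck.forward(out)
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            out = up.forward(out)
            out = np.concatenate([skip, out], axis=1)
            out = block.forward(out)
        logits = self.head.forward(out)
        probs = sigmoid(logits)
        self._cache = (probs,)
        return probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(probabilities)."""
        (probs,) = self._cache
        self._cache = None
        dlogits = (dprobs * probs * (1.0 - probs)).astype(np.float32)
        d = self.head.backward(dlogits)
        d_skips = []
        for up, block in zip(reversed(self.ups), reversed(self.dec_blocks)):
            d = block.backward(d)
            # concat was [skip, upsampled]; the skip carries out_ch channels
            skip_ch = block.conv1.w.value.shape[0]
            d_skip, d_up = d[:, :skip_ch], d[:, skip_ch:]
            d_skips.append(d_skip)
            d = up.backward(d_up)
        d = self.bottleneck.backward(d)
        for pool, block, d_skip in zip(
            reversed(self.pools), reversed(self.enc_blocks), reversed(d_skips)
        ):
            d = pool.backward(d)
            d = block.backward(d + d_skip)

    # --- checkpointing -----------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.params
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match this architecture")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value[...] = a


def build_unet(config: UNetConfig, seed: int = 0) -> UNet:
    """Construct an untrained U-Net with seeded weight initialisation."""
    return UNet(config, seed=seed)


def dice_loss(probabilities: np.ndarray, mask: np.ndarray, smooth: float = DICE_SMOOTH) -> float:
    """Soft Dice loss 1 - (2 sum(p g)+s)/(sum(p)+sum(g)+s) for one frame or batch.

    On hard (0/1) predictions this equals 1 minus the Dice coefficient up to
    the smoothing constant.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if probabilities.shape != mask.shape:
        raise ValueError(f"shape mismatch {probabilities.shape} vs {mask.shape}")
    if probabilities.ndim == 2:
        probabilities, mask = probabilities[None], mask[None]
    loss, _ = soft_dice_loss_and_grad(probabilities, mask, smooth)
    return loss


def save_checkpoint(model: UNet, path: str | Path) -> Path:
    """Write weights (.npz) plus a JSON sidecar of the architecture config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **{f"p{i}": a for i, a in enumerate(model.state_arrays())})
    path.with_suffix(".json").write_text(json.dumps(asdict(model.config), indent=2))
    return path


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    cfg = UNetConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = UNet(cfg)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model
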