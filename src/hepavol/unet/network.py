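"""3D U-Net: configuration, network assembly, forward/backward, and loss.

The encoder comprises ``n_levels`` resolutions (so ``n_levels - 1``
2 x 2 x 2 max-poolings); each resolution is a block of two 3 x 3 x 3
convolutions with group normalisation and ReLU, channel width doubling per
level from ``base_channels``. The decoder mirrors the encoder with
nearest-neighbour upsampling and concatenating skip connections; a final
1 x 1 x 1 convolution maps to per-voxel class scores of the input's
spatial shape.

The training objective is the sum of per-voxel cross-entropy and a soft
multi-class Dice loss, the standard pairing for highly class-imbalanced
vessel maps (configurable to either term alone).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .layers import Adam, Conv3d, ConvBlock, MaxPool3d, UpsampleNearest


@dataclass(frozen=True)
class UNetConfig:
    n_levels: int = 3
    base_channels: int = 16
    n_classes: int = 3
    in_channels: int = 1
    group_norm_groups: int = 8
    patch_size: tuple[int, int, int] = (64, 48, 32)
    stride: tuple[int, int, int] = (16, 12, 8)
    learning_rate: float = 1e-3
    batch_size: int = 1
    epochs: int = 200
    loss: str = "ce_dice"  # "ce", "dice", or "ce_dice"
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("need at least 2 resolution levels")
        factor = 2 ** (self.n_levels - 1)
        for axis, (p, s) in enumerate(zip(self.patch_size, self.stride)):
            if p % factor:
                raise ValueError(
                    f"patch_size[{axis}]={p} not divisible by the pooling factor {factor}"
                )
            if s > p:
                raise ValueError(f"stride[{axis}]={s} exceeds patch_size[{axis}]={p}")
        if self.loss not in ("ce", "dice", "ce_dice"):
            raise ValueError(f"unknown loss: {self.loss}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "UNetConfig":
        d = json.loads(text)
        for key in ("patch_size", "stride"):
            d[key] = tuple(d[key])
        return cls(**d)


class UNet3D:
    """Encoder-decoder network with concatenating skip connections."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * 2**i for i in range(config.n_levels)]
        g = config.group_norm_groups
        self.enc_blocks = []
        c_in = config.in_channels
        for level in range(config.n_levels - 1):
            self.enc_blocks.append(ConvBlock(c_in, ch[level], g, rng))
            c_in = ch[level]
        self.pools = [MaxPool3d() for _ in range(config.n_levels - 1)]
        self.bottom = ConvBlock(c_in, ch[-1], g, rng)
        self.ups = [UpsampleNearest() for _ in range(config.n_levels - 1)]
        self.dec_blocks = []
        c_in = ch[-1]
        for level in reversed(range(config.n_levels - 1)):
            self.dec_blocks.append(ConvBlock(c_in + ch[level], ch[level], g, rng))
            c_in = ch[level]
        self.final = Conv3d(c_in, config.n_classes, kernel=1, rng=rng)

    # -- parameters ------------------------------------------------------
    def params(self):
        out = []
        for i, block in enumerate(self.enc_blocks):
            out += [(f"enc{i}.{n}", v, d) for n, v, d in block.params()]
        out += [(f"bottom.{n}", v, d) for n, v, d in self.bottom.params()]
        for i, block in enumerate(self.dec_blocks):
            out += [(f"dec{i}.{n}", v, d) for n, v, d in block.params()]
        out += [(f"final.{n}", v, d) for n, v, d in self.final.params()]
        return out

    def make_optimizer(self, lr: float | None = None) -> Adam:
        return Adam(self.params(), lr=self.config.learning_rate if lr is None else lr)

    # -- passes ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Map a patch ``(D, H, W)`` or ``(C_in, D, H, W)`` to class scores
        ``(n_classes, D, H, W)``."""
        if x.ndim == 3:
            x = x[None]
        x = np.ascontiguousarray(x, dtype=np.float32)
        factor = 2 ** (self.config.n_levels - 1)
        for axis, extent in enumerate(x.shape[1:]):
            if extent % factor:
                raise ValueError(
                    f"input extent {extent} on axis {axis} not divisible by {factor}"
                )
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottom.forward(x)
        self._skip_channels = [s.shape[0] for s in skips]
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([skip, x], axis=0)
            x = block.forward(x)
        return self.final.forward(x)

    def backward(self, dscores: np.ndarray) -> None:
        dx = self.final.backward(dscores)
        dskips = []
        for up, block, c_skip in zip(
            reversed(self.ups), reversed(self.dec_blocks), self._skip_channels
        ):
            dcat = block.backward(dx)
            dskips.append(dcat[:c_skip])
            dx = up.backward(dcat[c_skip:])
        dx = self.bottom.backward(dx)
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            dx = pool.backward(dx)
            dx = block.backward(dx + dskip)

    # -- serialisation ---------------------------------------------------
    def save(self, weights_path: str | Path, config_path: str | Path | None = None) -> None:
        """Single-file weights (.npz) plus a JSON config sidecar."""
        weights_path = Path(weights_path)
        arrays = {name: value for name, value, _ in self.params()}
        np.savez(weights_path, **arrays)
        sidecar = Path(config_path) if config_path else weights_path.with_suffix(".json")
        sidecar.write_text(self.config.to_json())

    @classmethod
    def load(cls, weights_path: str | Path, config_path: str | Path | None = None) -> "UNet3D":
        weights_path = Path(weights_path)
        sidecar = Path(config_path) if config_path else weights_path.with_suffix(".json")
        net = cls(UNetConfig.from_json(sidecar.read_text()))
        with np.load(weights_path) as data:
            for name, value, _ in net.params():
                value[...] = data[name]
        return net


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=0, keepdims=True)


def segmentation_loss(
    scores: np.ndarray, labels: np.ndarray, kind: str = "ce_dice", eps: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the class scores.

    ``scores``: (C, D, H, W); ``labels``: integer (D, H, W).
    Cross-entropy is averaged per voxel; the soft Dice term is
    ``1 - mean_c (2 sum(p_c g_c) + eps) / (sum(p_c) + sum(g_c) + eps)``.
    """
    c = scores.shape[0]
    n = labels.size
    p = softmax(scores)
    onehot = np.zeros_like(p)
    flat = labels.reshape(-1)
    onehot.reshape(c, n)[flat, np.arange(n)] = 1.0
    loss = 0.0
    dp = np.zeros_like(p)
    if kind in ("ce", "ce_dice"):
        picked = p.reshape(c, n)[flat, np.arange(n)]
        loss += float(-np.log(np.clip(picked, 1e-12, None)).mean())
        # CE gradient taken directly w.r.t. scores below
    if kind in ("dice", "ce_dice"):
        pg = (p * onehot).sum(axis=(1, 2, 3))
        ps = p.sum(axis=(1, 2, 3))
        gs = onehot.sum(axis=(1, 2, 3))
        num = 2.0 * pg + eps
        den = ps + gs + eps
        loss += float(1.0 - (num / den).mean())
        ddice_dp = (2.0 * onehot * den[:, None, None, None] - num[:, None, None, None]) / (
            den[:, None, None, None] ** 2
        )
        dp += -ddice_dp / c
    # chain dp through softmax; add the closed-form CE-term gradient
    inner = (dp * p).sum(axis=0, keepdims=True)
    dscores = p * (dp - inner)
    if kind in ("ce", "ce_dice"):
        dscores += (p - onehot) / n
    return loss, dscores.astype(np.float32)
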