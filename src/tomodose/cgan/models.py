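"""pix2pix generator and discriminator.

The generator is a U-Net: a strided-convolution encoder, a decoder built
from nearest-neighbor upsampling plus 3x3 convolutions (a standard
checkerboard-free alternative to transposed convolutions), skip
connections at every resolution, and a sigmoid output bounded to [0, 1].
The random conditioning noise ``z`` is realized as dropout in the deepest
decoder stage, active at both training and inference time, which is the
conventional pix2pix treatment.

The discriminator is a PatchGAN: a small strided convolutional classifier
over the channel-concatenated (input, candidate) pair emitting a
probability score map whose spatial extent is smaller than the image, so
each score judges one local patch.
"""

from __future__ import annotations

import numpy as np

from .nn import (
    Adam,
    Conv2d,
    Dropout,
    InstanceNorm2d,
    Layer,
    LeakyReLU,
    Param,
    ReLU,
    Sequential,
    Sigmoid,
    UpsampleNearest2,
)


class UNetGenerator:
    """Encoder-decoder with skip connections, 1 channel in and out.

    A stride-1 stem keeps a full-resolution feature map that joins the
    decoder output through the last skip, so the network has an
    identity-capable pixel-scale path — essential for a denoiser whose
    output must track the input texture.
    """

    def __init__(
        self,
        base_channels: int = 8,
        depth: int = 3,
        dropout_p: float = 0.5,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        self.base_channels = base_channels
        b = base_channels
        chans = [b * 2**i for i in range(depth + 1)]  # stem + encoder stages

        self.stem = Sequential(
            Conv2d(1, b, 3, stride=1, pad=1, rng=rng, dtype=dtype), LeakyReLU(0.2)
        )
        self.enc: list[Sequential] = []
        for i in range(depth):
            block = [Conv2d(chans[i], chans[i + 1], 4, stride=2, pad=1, rng=rng,
                            dtype=dtype)]
            if i > 0:
                block.append(InstanceNorm2d(chans[i + 1], dtype=dtype))
            block.append(LeakyReLU(0.2))
            self.enc.append(Sequential(*block))

        # decoder stage j consumes the features at resolution H/2^(depth-j)
        # (concatenated with the skip of that resolution except at the
        # bottleneck) and emits features at H/2^(depth-j-1)
        self.dec: list[Sequential] = []
        for j in range(depth):
            level = depth - j  # channel index of the incoming resolution
            cin_dec = chans[level] if j == 0 else 2 * chans[level]
            cout = chans[level - 1]
            block: list[Layer] = [
                UpsampleNearest2(),
                Conv2d(cin_dec, cout, 3, stride=1, pad=1, rng=rng, dtype=dtype),
            ]
            if level - 1 > 0:
                block.append(InstanceNorm2d(cout, dtype=dtype))
            block.append(ReLU())
            if j == 0 and dropout_p > 0:
                block.append(Dropout(dropout_p, rng))
            self.dec.append(Sequential(*block))

        self.head = Sequential(
            Conv2d(2 * b, 1, 3, stride=1, pad=1, rng=rng, dtype=dtype),
            Sigmoid(),
        )

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in [self.stem] + self.enc + self.dec + [self.head]:
            out.extend(blk.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (1, H, W) with H, W divisible by 2**depth; returns (1, H, W)."""
        if x.ndim != 3 or x.shape[0] != 1:
            raise ValueError("generator input must be (1, H, W)")
        if x.shape[1] % 2**self.depth or x.shape[2] % 2**self.depth:
            raise ValueError(
                f"spatial size {x.shape[1:]} not divisible by 2**{self.depth}"
            )
        skips = [self.stem.forward(x)]  # resolution H
        cur = skips[0]
        for blk in self.enc:
            cur = blk.forward(cur)
            skips.append(cur)
        # skips[i] lives at resolution H / 2^i; skips[depth] is the bottleneck
        self._splits = []
        for j, blk in enumerate(self.dec):
            if j == 0:
                inp = cur
                self._splits.append(None)
            else:
                skip = skips[self.depth - j]
                self._splits.append(cur.shape[0])
                inp = np.concatenate([cur, skip], axis=0)
            cur = blk.forward(inp)
        self._head_split = cur.shape[0]
        out = self.head.forward(np.concatenate([cur, skips[0]], axis=0))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        ghead = self.head.backward(grad)
        gcur = ghead[: self._head_split]
        gskips: list[np.ndarray | None] = [None] * (self.depth + 1)
        gskips[0] = ghead[self._head_split :]
        for j in reversed(range(len(self.dec))):
            ginp = self.dec[j].backward(gcur)
            if j == 0:
                gcur = ginp  # gradient w.r.t. the bottleneck output
            else:
                split = self._splits[j]
                gcur = ginp[:split]
                level = self.depth - j
                gskips[level] = (
                    ginp[split:] if gskips[level] is None
                    else gskips[level] + ginp[split:]
                )
        # walk back through the encoder, folding in skip gradients
        for i in reversed(range(self.depth)):
            if gskips[i + 1] is not None:
                gcur = gcur + gskips[i + 1]
            gcur = self.enc[i].backward(gcur)
        if gskips[0] is not None:
            gcur = gcur + gskips[0]
        return self.stem.backward(gcur)


class PatchDiscriminator:
    """Convolutional patch classifier on a 2-channel (input, candidate) pair.

    Exposes both probability outputs (``forward``) and the pre-sigmoid
    logits (``forward_logits``) so losses can be computed stably.
    """

    def __init__(
        self,
        base_channels: int = 8,
        n_layers: int = 2,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng or np.random.default_rng(0)
        layers: list[Layer] = []
        cin = 2
        c = base_channels
        for i in range(n_layers):
            layers.append(Conv2d(cin, c, 4, stride=2, pad=1, rng=rng, dtype=dtype))
            if i > 0:
                layers.append(InstanceNorm2d(c, dtype=dtype))
            layers.append(LeakyReLU(0.2))
            cin = c
            c *= 2
        layers.append(Conv2d(cin, 1, 4, stride=1, pad=1, rng=rng, dtype=dtype))
        self.body = Sequential(*layers)
        self.sigmoid = Sigmoid()

    def params(self) -> list[Param]:
        return self.body.params()

    def forward_logits(self, cond: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        x = np.concatenate([cond, candidate], axis=0)
        return self.body.forward(x)

    def forward(self, cond: np.ndarray, candidate: np.ndarray) -> np.ndarray:
        return self.sigmoid.forward(self.forward_logits(cond, candidate))

    def backward_logits(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient w.r.t. (cond, candidate) given d(loss)/d(logits)."""
        gx = self.body.backward(grad)
        return gx[:1], gx[1:]


def build_models(cfg, rng: np.random.Generator | None = None):
    """Construct the (generator, discriminator) pair from a TrainConfig."""
    if cfg.patch_px % 2**cfg.gen_depth:
        raise ValueError(
            f"patch_px={cfg.patch_px} not divisible by 2**gen_depth={2**cfg.gen_depth}"
        )
    rng = rng or np.random.default_rng(cfg.seed)
    gen = UNetGenerator(
        base_channels=cfg.gen_base_channels, depth=cfg.gen_depth, rng=rng
    )
    disc = PatchDiscriminator(base_channels=cfg.gen_base_channels, rng=rng)
    return gen, disc
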