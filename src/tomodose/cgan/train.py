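"""Training, epoch selection and inference for the pix2pix denoiser.

Training alternates single-sample Adam steps on the discriminator and the
generator (learning rate 2e-4, betas (0.5, 0.999), batch size 1, L1 weight
50) over paired (low-dose, reference-dose) projection patches.  At
checkpoint epochs the generator is evaluated on the zero-degree validation
view by MSE and mean SSIM; the operating epoch is the one that minimizes
MSE and maximizes MSSIM (rank-sum compromise when they disagree, ties to
the later epoch).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ..metrics import mse as _mse
from ..metrics import mssim as _mssim
from .losses import (
    d_fake_term_from_logits,
    d_real_term_from_logits,
    g_adv_loss_and_grad_from_logits,
    l1_loss_and_grad,
)
from .models import UNetGenerator, PatchDiscriminator, build_models
from .nn import Adam


@dataclass
class TrainConfig:
    alpha_l1: float = 50.0
    lr: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    epochs: int = 100
    patch_px: int = 64
    gen_base_channels: int = 16
    gen_depth: int = 3
    seed: int = 0
    checkpoint_every: int = 10

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        for name in ("alpha_l1", "lr", "epochs", "patch_px", "gen_base_channels",
                     "gen_depth", "checkpoint_every"):
            if getattr(self, name) is not None and getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class PairedDataset:
    """Paired (low-dose, reference) images in the [0, 1] domain."""

    pairs: list[tuple[np.ndarray, np.ndarray]]
    split: list[str] = field(default_factory=list)  # "train" / "val" per pair

    def __post_init__(self) -> None:
        if not self.split:
            self.split = ["train"] * len(self.pairs)
        if len(self.split) != len(self.pairs):
            raise ValueError("one split tag per pair")
        for low, ref in self.pairs:
            if low.shape != ref.shape:
                raise ValueError("paired images must share a shape")

    def subset(self, tag: str) -> list[tuple[np.ndarray, np.ndarray]]:
        return [p for p, s in zip(self.pairs, self.split) if s == tag]


@dataclass
class Checkpoint:
    epoch: int
    config: TrainConfig
    weights: list[np.ndarray]

    def save(self, path) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez(path, epoch=self.epoch, config=json.dumps(asdict(self.config)),
                 **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        data = np.load(path, allow_pickle=False)
        cfg = TrainConfig(**json.loads(str(data["config"])))
        n = len([k for k in data.files if k.startswith("w")])
        return cls(int(data["epoch"]), cfg, [data[f"w{i}"] for i in range(n)])

    def build_generator(self) -> UNetGenerator:
        gen, _ = build_models(self.config, np.random.default_rng(self.config.seed))
        load_weights(gen, self.weights)
        return gen


def snapshot_weights(model) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def load_weights(model, weights: list[np.ndarray]) -> None:
    params = model.params()
    if len(params) != len(weights):
        raise ValueError("checkpoint/config mismatch: parameter count differs")
    for p, w in zip(params, weights):
        if p.value.shape != w.shape:
            raise ValueError("checkpoint/config mismatch: parameter shape differs")
        p.value[...] = w


def _as_chw(img: np.ndarray) -> np.ndarray:
    return img[None].astype(np.float32) if img.ndim == 2 else img.astype(np.float32)


def train(
    dataset: PairedDataset,
    cfg: TrainConfig,
    val_pair: tuple[np.ndarray, np.ndarray] | None = None,
):
    """Train the cGAN; returns (checkpoints, EpochCurve DataFrame).

    ``val_pair`` is the (low-dose, reference) zero-degree view used for the
    epoch-selection curve; when omitted the dataset's "val" split (or, as a
    last resort, the first training pair) is used.
    """
    train_pairs = dataset.subset("train")
    if not train_pairs:
        raise ValueError("need at least one training pair")
    if val_pair is None:
        val = dataset.subset("val")
        val_pair = val[0] if val else train_pairs[0]

    rng = np.random.default_rng(cfg.seed)
    gen, disc = build_models(cfg, np.random.default_rng(cfg.seed + 1))
    opt_g = Adam(gen.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)
    opt_d = Adam(disc.params(), lr=cfg.lr, beta1=cfg.beta1, beta2=cfg.beta2)

    checkpoints: list[Checkpoint] = []
    curve_rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_pairs))
        for idx in order:
            low, ref = train_pairs[idx]
            x = _as_chw(low)
            y = _as_chw(ref)

            fake = gen.forward(x)

            # --- discriminator step (fake detached) ---
            opt_d.zero_grad()
            logit_real = disc.forward_logits(x, y)
            loss_real, grad_real = d_real_term_from_logits(logit_real)
            disc.backward_logits(grad_real)
            logit_fake = disc.forward_logits(x, fake)
            loss_fake, grad_fake = d_fake_term_from_logits(logit_fake)
            disc.backward_logits(grad_fake)
            loss_d = loss_real + loss_fake
            if not np.isfinite(loss_d):
                raise FloatingPointError(f"NaN discriminator loss at epoch {epoch}")
            opt_d.step()

            # --- generator step ---
            opt_g.zero_grad()
            logit_fake = disc.forward_logits(x, fake)
            loss_adv, grad_logit = g_adv_loss_and_grad_from_logits(logit_fake)
            _, grad_fake_adv = disc.backward_logits(grad_logit)
            loss_l1, grad_l1 = l1_loss_and_grad(y, fake)
            if not np.isfinite(loss_adv + loss_l1):
                raise FloatingPointError(f"NaN generator loss at epoch {epoch}")
            gen.backward((grad_fake_adv + cfg.alpha_l1 * grad_l1).astype(np.float32))
            opt_g.step()

        if epoch % cfg.checkpoint_every == 0 or epoch == cfg.epochs:
            low_v, ref_v = val_pair
            pred = apply_generator(gen, np.asarray(low_v))
            row = {
                "epoch": epoch,
                "mse": _mse(pred, ref_v),
                "mssim": _mssim(pred, ref_v),
            }
            curve_rows.append(row)
            checkpoints.append(Checkpoint(epoch, cfg, snapshot_weights(gen)))

    curve = pd.DataFrame(curve_rows).drop_duplicates(subset="epoch")
    return checkpoints, curve


def select_epoch(curve: pd.DataFrame) -> int:
    """Operating-epoch selection from the (epoch, MSE, MSSIM) curve.

    Returns the epoch with both minimum MSE and maximum MSSIM when one
    exists; otherwise the epoch minimizing the sum of the two ranks, ties
    resolved toward the later epoch.
    """
    if curve is None or len(curve) == 0:
        raise ValueError("empty epoch curve")
    c = curve.sort_values("epoch").reset_index(drop=True)
    best_mse = int(c.loc[c["mse"].idxmin(), "epoch"])
    best_ssim = int(c.loc[c["mssim"].idxmax(), "epoch"])
    if best_mse == best_ssim:
        return best_mse
    ranks = c["mse"].rank(method="min") + (-c["mssim"]).rank(method="min")
    best = ranks.min()
    candidates = c.loc[ranks == best, "epoch"]
    return int(candidates.max())


def _tile_starts(size: int, patch: int, overlap: int) -> list[int]:
    if size <= patch:
        return [0]
    step = patch - overlap
    starts = list(range(0, size - patch, step))
    starts.append(size - patch)
    return starts


def apply_generator(gen: UNetGenerator, image: np.ndarray, overlap: int = 16) -> np.ndarray:
    """Run the generator on an image of arbitrary size.

    Images larger than the training patch are processed in overlapping
    tiles blended with linear ramps; smaller images are reflect-padded up
    to the divisibility constraint.  Output clipped to [0, 1].
    """
    H, W = image.shape
    mult = 2**gen.depth
    ph = max(int(np.ceil(H / mult)) * mult, mult)
    pw = max(int(np.ceil(W / mult)) * mult, mult)
    if (ph, pw) != (H, W):
        padded = np.pad(image, ((0, ph - H), (0, pw - W)), mode="reflect")
        out = apply_generator(gen, padded, overlap)[:H, :W]
        return out

    patch = _patch_size_for(gen, H, W)
    if patch >= max(H, W):
        pred = gen.forward(image[None].astype(np.float32))[0]
        return np.clip(pred, 0.0, 1.0)

    acc = np.zeros((H, W))
    wsum = np.zeros((H, W))
    ramp = np.minimum(np.arange(patch) + 1, np.arange(patch)[::-1] + 1).astype(float)
    wt = np.minimum(ramp[:, None], ramp[None, :])
    for r0 in _tile_starts(H, patch, overlap):
        for c0 in _tile_starts(W, patch, overlap):
            tile = image[r0 : r0 + patch, c0 : c0 + patch]
            pred = gen.forward(tile[None].astype(np.float32))[0]
            acc[r0 : r0 + patch, c0 : c0 + patch] += pred * wt
            wsum[r0 : r0 + patch, c0 : c0 + patch] += wt
    return np.clip(acc / wsum, 0.0, 1.0)


def _patch_size_for(gen: UNetGenerator, H: int, W: int) -> int:
    # largest power-of-two-friendly tile that keeps memory modest
    mult = 2**gen.depth
    target = 128
    patch = min(target, H, W)
    return max(patch - patch % mult, mult)


def denoise(projections, checkpoint_or_gen, overlap: int = 16):
    """Denoise every view of an attenuation_norm ProjectionSet."""
    if projections.domain != "attenuation_norm":
        raise ValueError("denoise expects attenuation_norm projections")
    if isinstance(checkpoint_or_gen, Checkpoint):
        gen = checkpoint_or_gen.build_generator()
    else:
        gen = checkpoint_or_gen
    images = np.stack(
        [apply_generator(gen, np.asarray(im, dtype=np.float32), overlap)
         for im in projections.images]
    ).astype(np.float32)
    return projections.copy_with(images=images, arm="pix2pix")
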