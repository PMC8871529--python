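"""Adversarial + L1 objectives of the conditional GAN.

The discriminator minimizes
``-E[log D(pld, pref)] - E[log(1 - D(pld, G(pld, z)))]``
and the generator minimizes the non-saturating adversarial term
``-E[log D(pld, G(pld, z))]`` plus ``alpha * E||pref - G(pld, z)||_1``
(the L1 weight alpha defaults to 50 in the training configuration).
Score maps are patch probabilities in (0, 1); the mean over the map is
the per-sample expectation.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _check_prob(d: np.ndarray) -> None:
    if np.any(d <= 0.0) or np.any(d >= 1.0):
        raise ValueError("discriminator outputs must lie strictly inside (0, 1)")


def d_loss(d_real: np.ndarray, d_fake: np.ndarray) -> float:
    """Discriminator loss in nats (mean over the patch score maps)."""
    _check_prob(d_real)
    _check_prob(d_fake)
    return float(
        -np.mean(np.log(d_real + _EPS)) - np.mean(np.log(1.0 - d_fake + _EPS))
    )


def g_adv_loss(d_fake: np.ndarray) -> float:
    """Non-saturating generator adversarial term ``-E[log D(pld, G)]``."""
    _check_prob(d_fake)
    return float(-np.mean(np.log(d_fake + _EPS)))


def l1_loss(pref: np.ndarray, fake: np.ndarray) -> float:
    return float(np.mean(np.abs(pref - fake)))


def gan_losses(disc, gen, pld: np.ndarray, pref: np.ndarray, alpha_l1: float = 50.0):
    """Evaluate (loss_D, loss_G) for one conditioned pair.

    ``pld``/``pref`` are (1, H, W) arrays in [0, 1].  The generator's noise
    source (dropout) is sampled internally.  This is the evaluation form of
    the objectives; the training loop computes the same quantities from
    logits for numerical stability.
    """
    if pld.shape != pref.shape:
        raise ValueError("paired images must share a shape")
    fake = gen.forward(pld)
    d_real = disc.forward(pld, pref)
    d_fake = disc.forward(pld, fake)
    loss_d = d_loss(d_real, d_fake)
    loss_g = g_adv_loss(d_fake) + alpha_l1 * l1_loss(pref, fake)
    return loss_d, loss_g


# --- logit-space gradients used by the training loop ---------------------


def d_real_term_from_logits(logit_real: np.ndarray):
    """``-E[log D(real)]`` and its gradient w.r.t. the logits."""
    pr = 1.0 / (1.0 + np.exp(-logit_real))
    loss = -np.log(pr + _EPS).mean()
    grad = (pr - 1.0) / pr.size
    return float(loss), grad


def d_fake_term_from_logits(logit_fake: np.ndarray):
    """``-E[log(1 - D(fake))]`` and its gradient w.r.t. the logits."""
    pf = 1.0 / (1.0 + np.exp(-logit_fake))
    loss = -np.log(1.0 - pf + _EPS).mean()
    grad = pf / pf.size
    return float(loss), grad


def g_adv_loss_and_grad_from_logits(logit_fake: np.ndarray):
    """Non-saturating adversarial loss and d(loss)/d(logit_fake)."""
    pf = 1.0 / (1.0 + np.exp(-logit_fake))
    loss = -np.log(pf + _EPS).mean()
    grad = (pf - 1.0) / pf.size
    return float(loss), grad


def l1_loss_and_grad(pref: np.ndarray, fake: np.ndarray):
    diff = fake - pref
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad
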