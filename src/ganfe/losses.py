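"""Binary cross entropy and the GAN-feature-enhanced (GFE) loss.

The GFE loss extends BCE for training on a mixture of observed and
GAN-generated records:

    GFE = BCE(X) + W * (1 - Acc(D(P))) * Acc(D(N)) * BCE(X')

where X is the full batch, X' the observed positive records in the batch,
Acc(D(P)) the frozen discriminator's accuracy on the observed-positive
reference set, Acc(D(N)) its accuracy on the (never-trained-on) negative
reference set, and W the weight of the observed portion (observed records in
the batch over the total training count). The correction term re-emphasizes
ground-truth positives in proportion to how much misleading information the
generated data carries (1 - Acc(D(P))), discounted by how trustworthy the
discriminator itself is (Acc(D(N))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nnet import bce_loss_and_grad

__all__ = ["GfeContext", "bce", "gfe", "gfe_loss_and_grad"]


@dataclass
class GfeContext:
    """Frozen-discriminator quantities entering the GFE correction term.

    accP/accN are refreshed once per epoch from the reference sets; W is
    recomputed per batch.
    """

    accP: float  # Acc(D(P)): discriminator accuracy on observed positives
    accN: float  # Acc(D(N)): discriminator accuracy on reference negatives
    W: float     # weight of the observed portion

    def __post_init__(self):
        for name in ("accP", "accN", "W"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def bce(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross entropy -mean[y log p + (1-y) log(1-p)]."""
    loss, _ = bce_loss_and_grad(np.asarray(predictions, dtype=float),
                                np.asarray(labels, dtype=float))
    return loss


def gfe(predictions: np.ndarray, labels: np.ndarray,
        observed_mask: np.ndarray, ctx: GfeContext) -> float:
    """GFE loss of a batch; X' = records with observed_mask=1 and label=1.

    Reduces exactly to BCE(X) when accP=1, accN=0, W=0 or X' is empty, and
    is never smaller than BCE(X) since every correction factor is >= 0.
    """
    loss, _ = gfe_loss_and_grad(np.asarray(predictions, dtype=float),
                                np.asarray(labels, dtype=float),
                                np.asarray(observed_mask, dtype=bool), ctx)
    return loss


def gfe_loss_and_grad(p: np.ndarray, y: np.ndarray, observed_mask: np.ndarray,
                      ctx: GfeContext) -> tuple[float, np.ndarray]:
    """GFE loss and its gradient w.r.t. the predicted probabilities."""
    p = p.ravel()
    y = y.ravel()
    observed_mask = observed_mask.ravel()
    loss_x, grad = bce_loss_and_grad(p, y)
    grad = grad.copy()
    prime = observed_mask & (y == 1)
    factor = ctx.W * (1.0 - ctx.accP) * ctx.accN
    if factor > 0.0 and prime.any():
        loss_xp, grad_xp = bce_loss_and_grad(p[prime], y[prime])
        grad[prime] += factor * grad_xp
        return loss_x + factor * loss_xp, grad
    return loss_x, grad
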