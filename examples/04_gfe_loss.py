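"""The GFE loss by hand: BCE plus a discriminator-weighted correction.

Evaluates GFE = BCE(X) + W * (1 - Acc(D(P))) * Acc(D(N)) * BCE(X') on a
four-record batch where the first two records are observed positives (X')
and the rest are generated. The printed decomposition shows how the
correction term re-emphasizes ground-truth positives, and that GFE falls
back to plain BCE when the discriminator finds the generated data
indistinguishable from real (Acc(D(P)) = 1)."""

import numpy as np

from ganfe.losses import GfeContext, bce, gfe

p = np.array([0.9, 0.8, 0.2, 0.6])     # predicted probabilities
y = np.ones(4)                          # all labelled positive
observed = np.array([1, 1, 0, 0])       # X' = first two records

base = bce(p, y)
prime = bce(p[:2], y[:2])
ctx = GfeContext(accP=0.8, accN=0.9, W=0.5)
total = gfe(p, y, observed, ctx)

print(f"BCE(X)  = {base:.4f}")
print(f"BCE(X') = {prime:.4f}")
print(f"correction = W(1-accP)accN * BCE(X') = "
      f"{ctx.W * (1 - ctx.accP) * ctx.accN * prime:.4f}")
print(f"GFE     = {total:.4f}")
print(f"GFE with accP=1 (perfect generation): "
      f"{gfe(p, y, observed, GfeContext(1.0, 0.9, 0.5)):.4f} == BCE(X)")
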