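"""Generative-quality diagnostics for the feature-enhanced data.

A deep autoencoder (382 -> 400 -> 300 -> 200 -> 100 -> 3, LeakyReLU
activations, mirrored decoder) is trained jointly on the observed positives
and the generated records; its 3-wide bottleneck embeds both clouds in a
common low-dimensional space. Agreement between the clouds is quantified by
the energy distance between the embedded point sets (0 iff the
distributions coincide), complementing per-feature mean/sd concordance and
a two-component PCA projection in the original feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from . import nnet

__all__ = [
    "QcAutoencoder",
    "EmbeddingReport",
    "train_qc_autoencoder",
    "embedding_distance",
    "energy_distance",
    "moment_comparison",
]


@dataclass
class QcAutoencoder:
    encoder: nnet.Sequential
    decoder: nnet.Sequential
    loss_curve: list[float]

    def embed(self, X: np.ndarray) -> np.ndarray:
        """3-coordinate embedding of each record."""
        return self.encoder.forward(np.asarray(X, dtype=float),
                                    training=False)

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.decoder.forward(self.embed(X), training=False)


@dataclass
class EmbeddingReport:
    embedding: np.ndarray        # (n, 3)
    source: np.ndarray           # 'observed-positive' | 'generated'
    loss_curve: list[float]
    energy_distance: float
    moments: dict                # per-feature mean/sd pairs + concordance
    pca_projection: np.ndarray   # (n, 2) in the original feature space


def _build_autoencoder(p: int, rng: np.random.Generator,
                       widths: tuple[int, ...] = (400, 300, 200, 100, 3),
                       alpha: float = 0.01):
    enc: list[nnet.Layer] = []
    w_in = p
    for w in widths:
        enc += [nnet.Linear(w_in, w, rng), nnet.LeakyReLU(alpha)]
        w_in = w
    dec: list[nnet.Layer] = []
    for w in reversed(widths[:-1]):
        dec += [nnet.Linear(w_in, w, rng), nnet.LeakyReLU(alpha)]
        w_in = w
    dec += [nnet.Linear(w_in, p, rng)]
    return nnet.Sequential(enc), nnet.Sequential(dec)


def train_qc_autoencoder(data: np.ndarray, epochs: int = 2000,
                         lr: float = 1e-4, batch_size: int = 128,
                         seed: int = 0) -> QcAutoencoder:
    """Train the 3-bottleneck autoencoder by mean-squared reconstruction.

    `data` should be the min-max-scaled union of observed positives and
    generated records. The final-epoch loss is asserted to be below the
    first-epoch loss — a non-decreasing curve signals a broken run.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 10:
        raise ValueError("need at least 10 records to train the QC autoencoder")
    rng = np.random.default_rng(seed)
    encoder, decoder = _build_autoencoder(data.shape[1], rng)
    opt = nnet.Adam(encoder.params() + decoder.params(), lr)

    n = data.shape[0]
    curve: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            x = data[order[start:start + batch_size]]
            z = encoder.forward(x, training=True)
            xhat = decoder.forward(z, training=True)
            diff = xhat - x
            loss = float(np.mean(diff * diff))
            grad = 2.0 * diff / diff.size
            encoder.backward(decoder.backward(grad))
            opt.step()
            epoch_loss += loss
            n_batches += 1
        curve.append(epoch_loss / n_batches)
    if curve[-1] >= curve[0]:
        raise RuntimeError("QC autoencoder loss did not decrease; "
                           "check scaling and learning rate")
    return QcAutoencoder(encoder, decoder, curve)


def energy_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Energy distance between two point clouds.

    E = 2 E|a-b| - E|a-a'| - E|b-b'| with Euclidean norms; nonnegative,
    symmetric, and 0 iff the two distributions coincide.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    ab = cdist(A, B).mean()
    aa = cdist(A, A).mean()
    bb = cdist(B, B).mean()
    return float(max(2.0 * ab - aa - bb, 0.0))


def embedding_distance(model: QcAutoencoder, observed: np.ndarray,
                       generated: np.ndarray) -> float:
    """Energy distance between the embedded observed and generated clouds."""
    if len(observed) == 0 or len(generated) == 0:
        raise ValueError("both clouds must be nonempty")
    return energy_distance(model.embed(observed), model.embed(generated))


def moment_comparison(observed: np.ndarray, generated: np.ndarray,
                      feature_names: list[str] | None = None) -> dict:
    """Per-feature mean/sd of both sets, their concordance, and a shared
    two-component PCA projection.

    Concordance is the Pearson correlation of the paired per-feature values
    (observed vs generated) together with the mean absolute deviation from
    the y = x line; a faithful generator puts all pairs on the diagonal.
    """
    observed = np.asarray(observed, dtype=float)
    generated = np.asarray(generated, dtype=float)
    if observed.shape[1] != generated.shape[1]:
        raise ValueError("observed/generated feature schema mismatch")
    mo, mg = observed.mean(axis=0), generated.mean(axis=0)
    so, sg = observed.std(axis=0), generated.std(axis=0)

    def _concord(a, b):
        corr = 1.0 if np.allclose(a, b) else float(np.corrcoef(a, b)[0, 1])
        return {"correlation": corr,
                "mad_from_diagonal": float(np.mean(np.abs(a - b)))}

    pca = PCA(n_components=2)
    stacked = np.vstack([observed, generated])
    proj = pca.fit_transform(stacked)
    out = {
        "mean": {"observed": mo, "generated": mg,
                 "concordance": _concord(mo, mg)},
        "sd": {"observed": so, "generated": sg,
               "concordance": _concord(so, sg)},
        "pca_projection": proj,
        "pca_source": np.array(["observed"] * observed.shape[0]
                               + ["generated"] * generated.shape[0]),
    }
    if feature_names is not None:
        out["feature_names"] = list(feature_names)
    return out
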