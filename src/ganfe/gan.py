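"""Adversarial feature enhancement of the minority class.

An autoencoder-shaped generator is trained against a discriminator on the
observed positive (incident-case) records only; non-cases never enter GAN
training and are reserved as an unseen reference set for judging the frozen
discriminator. After training, the generator maps resampled observed
positives — perturbed by Gaussian noise at its 75-wide bottleneck — to
"feature-enhanced" synthetic positives on the min-max-scaled feature scale.

Architectures (input width configurable, default 382):

* discriminator: 382 -> 200 -> 200 -> 200 -> 100 -> 1, ReLU + batch norm on
  the hidden layers, sigmoid output score in (0, 1);
* generator: encoder 382 -> 300 -> 75 and decoder 75 -> 150 -> 382, ReLU +
  batch norm on hidden layers.

Both are trained with Adam (lr 0.005, weight decay 1e-4) for a configurable
number of alternating steps (default 3000).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnet

__all__ = [
    "DiscriminatorSpec",
    "GeneratorSpec",
    "ReferenceSets",
    "GanBundle",
    "train_gan",
    "generate",
    "discriminator_accuracy",
]


@dataclass
class DiscriminatorSpec:
    input_dim: int = 382
    hidden: tuple[int, ...] = (200, 200, 200, 100)

    def build(self, rng: np.random.Generator) -> nnet.Sequential:
        layers: list[nnet.Layer] = []
        w_in = self.input_dim
        for w in self.hidden:
            layers += [nnet.Linear(w_in, w, rng), nnet.ReLU(), nnet.BatchNorm(w)]
            w_in = w
        layers += [nnet.Linear(w_in, 1, rng), nnet.Sigmoid()]
        return nnet.Sequential(layers)


@dataclass
class GeneratorSpec:
    input_dim: int = 382
    encoder_hidden: tuple[int, ...] = (300, 75)
    decoder_hidden: tuple[int, ...] = (150,)
    sigma_z: float = 0.1  # bottleneck noise scale

    def build(self, rng: np.random.Generator) -> tuple[nnet.Sequential, nnet.Sequential]:
        enc: list[nnet.Layer] = []
        w_in = self.input_dim
        for w in self.encoder_hidden:
            enc += [nnet.Linear(w_in, w, rng), nnet.ReLU(), nnet.BatchNorm(w)]
            w_in = w
        dec: list[nnet.Layer] = []
        for w in self.decoder_hidden:
            dec += [nnet.Linear(w_in, w, rng), nnet.ReLU(), nnet.BatchNorm(w)]
            w_in = w
        dec += [nnet.Linear(w_in, self.input_dim, rng)]
        return nnet.Sequential(enc), nnet.Sequential(dec)

    @property
    def bottleneck(self) -> int:
        return self.encoder_hidden[-1]


@dataclass
class ReferenceSets:
    """Observed positives P and negatives N for frozen-discriminator QC.

    N is never used in GAN training; it exists only to score the trained
    discriminator on data it has not seen.
    """

    P: np.ndarray
    N: np.ndarray

    def __post_init__(self):
        if self.N.shape[0] == 0:
            raise ValueError("reference negatives must be nonempty")


@dataclass
class GanBundle:
    """Trained generator/discriminator pair with frozen-weights evaluation."""

    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    encoder: nnet.Sequential
    decoder: nnet.Sequential
    discriminator: nnet.Sequential
    history: dict[str, list[float]] = field(default_factory=dict)
    steps: int = 0
    seed: int = 0

    def discriminator_scores(self, records: np.ndarray) -> np.ndarray:
        """Score records with the frozen discriminator (eval mode; running
        batch-norm statistics, no weight updates)."""
        return self.discriminator.forward(records, training=False).ravel()

    def transform(self, records: np.ndarray,
                  rng: np.random.Generator | None = None) -> np.ndarray:
        """Encode -> (noise at bottleneck) -> decode, clipped to [0, 1]."""
        z = self.encoder.forward(records, training=False)
        if rng is not None and self.gen_spec.sigma_z > 0:
            z = z + rng.normal(0.0, self.gen_spec.sigma_z, size=z.shape)
        out = self.decoder.forward(z, training=False)
        return np.clip(out, 0.0, 1.0)

    # --- checkpointing ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        arrays = (self.encoder.state_arrays() + self.decoder.state_arrays()
                  + self.discriminator.state_arrays())
        np.savez(path, *arrays)
        meta = {
            "gen_spec": {"input_dim": self.gen_spec.input_dim,
                         "encoder_hidden": list(self.gen_spec.encoder_hidden),
                         "decoder_hidden": list(self.gen_spec.decoder_hidden),
                         "sigma_z": self.gen_spec.sigma_z},
            "disc_spec": {"input_dim": self.disc_spec.input_dim,
                          "hidden": list(self.disc_spec.hidden)},
            "steps": self.steps,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "GanBundle":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        meta = json.loads(
            path.with_suffix(path.suffix + ".meta.json").read_text())
        g = meta["gen_spec"]
        d = meta["disc_spec"]
        gen_spec = GeneratorSpec(g["input_dim"], tuple(g["encoder_hidden"]),
                                 tuple(g["decoder_hidden"]), g["sigma_z"])
        disc_spec = DiscriminatorSpec(d["input_dim"], tuple(d["hidden"]))
        rng = np.random.default_rng(0)
        encoder, decoder = gen_spec.build(rng)
        discriminator = disc_spec.build(rng)
        with np.load(path) as data:
            arrays = [data[k] for k in data.files]
        n_enc = len(encoder.state_arrays())
        n_dec = len(decoder.state_arrays())
        encoder.load_state(arrays[:n_enc])
        decoder.load_state(arrays[n_enc:n_enc + n_dec])
        discriminator.load_state(arrays[n_enc + n_dec:])
        return cls(gen_spec, disc_spec, encoder, decoder, discriminator,
                   steps=meta["steps"], seed=meta["seed"])


def train_gan(positives: np.ndarray, steps: int = 3000, lr: float = 0.005,
              weight_decay: float = 1e-4, sigma_z: float = 0.1,
              batch_size: int = 64, seed: int = 0,
              gen_spec: GeneratorSpec | None = None,
              disc_spec: DiscriminatorSpec | None = None) -> GanBundle:
    """Train the adversarial pair on observed positive records.

    Alternating 1:1 updates: the discriminator minimizes BCE labelling
    observed positives 1 and generator outputs 0; the generator minimizes
    the non-saturating BCE of the discriminator scoring its outputs as 1
    (gradients flow through the frozen-for-this-step discriminator). Inputs
    must be min-max scaled to [0, 1].
    """
    positives = np.asarray(positives, dtype=float)
    if positives.shape[0] < 2:
        raise ValueError("need at least 2 positive records to train")
    p = positives.shape[1]
    gen_spec = gen_spec or GeneratorSpec(input_dim=p, sigma_z=sigma_z)
    disc_spec = disc_spec or DiscriminatorSpec(input_dim=p)
    if gen_spec.input_dim != p or disc_spec.input_dim != p:
        raise ValueError("spec input_dim does not match data width")

    rng = np.random.default_rng(seed)
    encoder, decoder = gen_spec.build(rng)
    discriminator = disc_spec.build(rng)
    opt_d = nnet.Adam(discriminator.params(), lr, weight_decay)
    opt_g = nnet.Adam(encoder.params() + decoder.params(), lr, weight_decay)

    n = positives.shape[0]
    bsz = min(batch_size, n)
    history: dict[str, list[float]] = {"d_loss": [], "g_loss": []}

    for _ in range(steps):
        # --- discriminator update ------------------------------------------
        idx = rng.choice(n, size=bsz, replace=False)
        real = positives[idx]
        z = encoder.forward(real, training=True)
        if gen_spec.sigma_z > 0:
            z = z + rng.normal(0.0, gen_spec.sigma_z, size=z.shape)
        fake = decoder.forward(z, training=True)
        batch = np.vstack([real, fake])
        targets = np.concatenate([np.ones(bsz), np.zeros(bsz)])[:, None]
        scores = discriminator.forward(batch, training=True)
        d_loss, grad = nnet.bce_loss_and_grad(scores, targets)
        discriminator.backward(grad)
        opt_d.step()

        # --- generator update (non-saturating) -----------------------------
        idx = rng.choice(n, size=bsz, replace=False)
        real = positives[idx]
        z = encoder.forward(real, training=True)
        if gen_spec.sigma_z > 0:
            z = z + rng.normal(0.0, gen_spec.sigma_z, size=z.shape)
        fake = decoder.forward(z, training=True)
        # score fakes alongside a real batch so the discriminator's batch
        # normalization sees representative statistics; only the fake half
        # contributes to the generator loss
        scores = discriminator.forward(np.vstack([real, fake]), training=True)
        g_loss, grad_fake_scores = nnet.bce_loss_and_grad(
            scores[bsz:], np.ones((bsz, 1)))
        grad_scores = np.vstack([np.zeros((bsz, 1)), grad_fake_scores])
        grad_in = discriminator.backward(grad_scores)  # D not stepped: frozen here
        grad_z = decoder.backward(grad_in[bsz:])
        encoder.backward(grad_z)
        opt_g.step()

        history["d_loss"].append(d_loss)
        history["g_loss"].append(g_loss)

    return GanBundle(gen_spec, disc_spec, encoder, decoder, discriminator,
                     history, steps, seed)


def generate(bundle: GanBundle, positives: np.ndarray, n: int = 2600,
             seed: int = 0) -> np.ndarray:
    """Emit n feature-enhanced records from resampled observed positives.

    Each output row is a resampled observed positive passed through the
    trained generator with Gaussian bottleneck noise, clipped to [0, 1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    positives = np.asarray(positives, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, positives.shape[0], size=n)
    return bundle.transform(positives[idx], rng=rng)


def discriminator_accuracy(bundle: GanBundle, records: np.ndarray,
                           expected: str) -> float:
    """Fraction of records the frozen discriminator scores on the expected
    side of 0.5 ('real': score >= 0.5; 'fake': score < 0.5).

    Acc(D(P)) is this with the observed-positive reference set and
    expected='real'; Acc(D(N)) with the negative reference set and
    expected='fake' (negatives are not positive cases, so a reliable
    discriminator should not score them as real positives).
    """
    records = np.asarray(records, dtype=float)
    if records.shape[0] == 0:
        raise ValueError("records must be nonempty")
    if expected not in ("real", "fake"):
        raise ValueError("expected must be 'real' or 'fake'")
    scores = bundle.discriminator_scores(records)
    hits = scores >= 0.5 if expected == "real" else scores < 0.5
    return float(hits.mean())
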