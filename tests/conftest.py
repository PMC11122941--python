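import numpy as np
import pytest

import ganfe
from ganfe.gan import DiscriminatorSpec, GeneratorSpec


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with the default schema proportions and planted signal."""
    spec = ganfe.CohortSpec(
        n_negative=200, n_positive=40, n_clinical_continuous=4,
        n_clinical_categorical=2, categorical_level_counts=[2, 3],
        n_metabolites=24, signal_features=[(4, 1.0), (8, 0.6)], seed=5)
    return ganfe.simulate_cohort(spec)


@pytest.fixture(scope="session")
def toy_positives():
    """Tight 2-feature positive cloud inside [0,1]^2 — an easy GAN target."""
    rng = np.random.default_rng(0)
    return np.clip(rng.normal([0.7, 0.3], 0.05, size=(60, 2)), 0, 1)


@pytest.fixture(scope="session")
def toy_gan_specs():
    gen = GeneratorSpec(input_dim=2, encoder_hidden=(16, 4),
                        decoder_hidden=(8,), sigma_z=0.05)
    disc = DiscriminatorSpec(input_dim=2, hidden=(16, 8))
    return gen, disc


@pytest.fixture(scope="session")
def toy_trained_gan(toy_positives, toy_gan_specs):
    gen_spec, disc_spec = toy_gan_specs
    return ganfe.train_gan(toy_positives, steps=4000, lr=5e-4, seed=1,
                           gen_spec=gen_spec, disc_spec=disc_spec)


class ScoreStub:
    """Stand-in bundle returning fixed discriminator scores (synthetic)."""

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=float)

    def discriminator_scores(self, records):
        return self._scores[: len(records)]


@pytest.fixture
def score_stub():
    return ScoreStub
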