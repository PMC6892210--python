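import pytest

from latentgan import (
    FixtureSpec,
    Heteroencoder,
    HeteroencoderConfig,
    generate_library,
    plant_actives,
    vocabulary_for_records,
)


@pytest.fixture(scope="session")
def library50():
    """Small synthetic library: 5 series, 50 molecules."""
    return generate_library(FixtureSpec(n_molecules=50, n_series=5, seed=3))


@pytest.fixture(scope="session")
def labeled200():
    """Labeled library: 8 series, 200 molecules, ~40% active."""
    spec = FixtureSpec(n_molecules=200, n_series=8, actives_fraction=0.4, seed=11)
    return plant_actives(generate_library(spec), spec)


@pytest.fixture(scope="session")
def overfit_ae(library50):
    """A heteroencoder memorizing the 50-molecule library.

    Shared by the convergence, determinism, round-trip and checkpoint tests
    so the training cost is paid once.
    """
    vocab = vocabulary_for_records(library50, seed=1)
    config = HeteroencoderConfig.small(
        rnn_units=64, latent_dim=48, epochs=90, batch_size=8,
        lr_constant_epochs=60, pairs_per_molecule=8,
        bn_freeze_epochs=30, lr_final=1e-4,
    )
    model = Heteroencoder(config, vocab, seed=0)
    losses = model.train(library50, seed=0)
    return model, losses
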