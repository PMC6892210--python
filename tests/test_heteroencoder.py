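"""Heteroencoder: architecture contracts, schedules, determinism, decoding."""

import numpy as np
import pytest
from rdkit import Chem

from latentgan.data import standardize
from latentgan.heteroencoder import (
    Heteroencoder,
    HeteroencoderConfig,
    learning_rate_at_epoch,
    reconstruction_report_from_decodes,
    vocabulary_for_records,
    _one_hot,
)
from latentgan.nn import softmax
from latentgan.vocab import build_vocabulary, encode_batch

TINY = HeteroencoderConfig(
    rnn_units=16, latent_dim=8, epochs=2, batch_size=4,
    lr_constant_epochs=1, pairs_per_molecule=1, noise_sd=0.0,
)


@pytest.fixture()
def tiny_model():
    vocab = build_vocabulary(["CCO", "CCN", "CCC"], length_margin=2)
    return Heteroencoder(TINY, vocab, seed=0)


class TestConfig:
    def test_defaults_match_reference_architecture(self):
        cfg = HeteroencoderConfig()
        assert (cfg.encoder_layers, cfg.rnn_units, cfg.latent_dim,
                cfg.decoder_layers) == (2, 512, 512, 4)
        assert (cfg.noise_sd, cfg.batchnorm_momentum) == (0.1, 0.9)
        assert (cfg.epochs, cfg.batch_size) == (100, 128)
        assert (cfg.lr_initial, cfg.lr_final, cfg.lr_constant_epochs) == (
            1e-3, 1e-6, 50)

    def test_validation(self):
        with pytest.raises(ValueError):
            HeteroencoderConfig(latent_dim=0)
        with pytest.raises(ValueError):
            HeteroencoderConfig(rnn_units=15)  # odd: cannot split directions
        with pytest.raises(ValueError):
            HeteroencoderConfig(noise_sd=-0.1)
        with pytest.raises(ValueError):
            HeteroencoderConfig(batchnorm_momentum=1.5)
        with pytest.raises(ValueError):
            HeteroencoderConfig(lr_final=1.0, lr_initial=1e-3)
        with pytest.raises(ValueError):
            HeteroencoderConfig(lr_constant_epochs=200, epochs=100)


class TestLearningRateSchedule:
    def test_constant_then_exponential_decay_closed_form(self):
        cfg = HeteroencoderConfig()
        for epoch in range(1, 51):
            assert learning_rate_at_epoch(epoch, cfg) == 1e-3
        r = (1e-6 / 1e-3) ** (1 / 50)
        for epoch in range(51, 101):
            expected = 1e-3 * r ** (epoch - 50)
            assert learning_rate_at_epoch(epoch, cfg) == pytest.approx(expected, rel=1e-12)
        assert learning_rate_at_epoch(100, cfg) == pytest.approx(1e-6, rel=1e-12)


class TestArchitecture:
    def test_parameter_count_is_pure_function_of_config(self, tiny_model):
        vocab = build_vocabulary(["CCO", "CCN", "CCC"], length_margin=2)
        other = Heteroencoder(TINY, vocab, seed=123)
        assert tiny_model.parameter_count() == other.parameter_count()

    def test_decoder_state_expansion_size(self, tiny_model):
        # one dense layer fans the latent out to decoder_layers x 2 x units
        assert tiny_model.state_dense.W.shape == (
            TINY.latent_dim, TINY.decoder_layers * 2 * TINY.rnn_units)

    def test_forward_pass_yields_probability_simplices(self, tiny_model):
        idx, lengths = encode_batch(["CCO"], tiny_model.vocab)
        latent = tiny_model._encode_forward(idx, lengths)
        assert latent.shape == (1, TINY.latent_dim)
        states = tiny_model._decoder_states(latent)
        h = _one_hot(idx[:, :-1], len(tiny_model.vocab))
        for i, lstm in enumerate(tiny_model.dec):
            h = lstm.forward(h, h0=states[i][0], c0=states[i][1])
        B, T, _ = h.shape
        logits = tiny_model.out_dense.forward(h.reshape(B * T, -1))
        probs = softmax(logits)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


class TestTrainingContracts:
    def test_identical_seeds_give_identical_loss_curves(self):
        records = [standardize(s) for s in ["CCO", "CCN", "CCC", "CCS"]]
        vocab = vocabulary_for_records(records, seed=0)
        runs = []
        for _ in range(2):
            model = Heteroencoder(TINY, vocab, seed=7)
            runs.append(model.train(records, seed=7))
        assert runs[0] == runs[1]
        assert len(runs[0]) == TINY.epochs

    def test_empty_training_set_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.train([])

    def test_noise_deactivated_after_training(self):
        records = [standardize("CCO"), standardize("CCN")]
        vocab = vocabulary_for_records(records, seed=0)
        model = Heteroencoder(TINY, vocab, seed=0)
        assert model.noise_active
        model.train(records, seed=0)
        assert not model.noise_active


class TestEncodeDecode:
    def test_encode_is_bitwise_deterministic(self, overfit_ae, library50):
        model, _ = overfit_ae
        smiles = [r.canonical_smiles for r in library50[:8]]
        a = model.encode(smiles)
        b = model.encode(smiles)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (8, model.config.latent_dim)

    def test_randomized_renderings_encode_nearby(self, overfit_ae, library50):
        """Different renderings of one molecule map to similar latents on a
        converged model (trend metric, loose bound)."""
        from latentgan.data import randomize_smiles

        model, _ = overfit_ae
        sims = []
        for rec in library50[:10]:
            variants = randomize_smiles(rec.canonical_smiles, 2, seed=1)
            z = model.encode(variants)
            cos = float(z[0] @ z[1] / (np.linalg.norm(z[0]) * np.linalg.norm(z[1])))
            sims.append(cos)
        assert np.mean(sims) > 0.5

    def test_empty_batch(self, overfit_ae):
        model, _ = overfit_ae
        assert model.encode([]).shape == (0, model.config.latent_dim)

    def test_decode_is_deterministic_and_total(self, overfit_ae):
        model, _ = overfit_ae
        rng = np.random.default_rng(0)
        z = rng.normal(size=(4, model.config.latent_dim))
        assert model.decode(z) == model.decode(z)
        out = model.decode(np.zeros((1, model.config.latent_dim)))
        assert isinstance(out[0], str)  # possibly empty, but no crash

    def test_dimension_mismatch_rejected(self, overfit_ae):
        model, _ = overfit_ae
        with pytest.raises(ValueError):
            model.decode(np.zeros((2, model.config.latent_dim + 1)))

    def test_overfit_library_is_memorized(self, overfit_ae, library50):
        """Convergence contract: loss decreases and most training molecules
        round-trip to themselves."""
        model, losses = overfit_ae
        assert losses[-1] < losses[0]
        smiles = [r.canonical_smiles for r in library50]
        decoded = model.decode(model.encode(smiles))
        identical = sum(
            1 for s, d in zip(smiles, decoded)
            if (mol := Chem.MolFromSmiles(d)) is not None
            and Chem.MolToSmiles(mol) == s
        )
        assert identical / len(smiles) >= 0.9


class TestReconstructionReport:
    def test_identity_decode_stub(self):
        smiles = ["CCO", "CCN", "c1ccccc1"]
        report = reconstruction_report_from_decodes(smiles, list(smiles))
        assert report.validity_pct == 100.0
        assert report.reconstruction_error_pct == 0.0

    def test_different_rendering_is_not_an_error(self):
        report = reconstruction_report_from_decodes(["CCO"], ["OCC"])
        assert report.validity_pct == 100.0
        assert report.reconstruction_error_pct == 0.0

    def test_different_molecule_is_an_error(self):
        report = reconstruction_report_from_decodes(["CCO"], ["CCC"])
        assert report.reconstruction_error_pct == 100.0

    def test_invalid_decode_excluded_from_error_denominator(self):
        report = reconstruction_report_from_decodes(
            ["CCO", "CCN", "CCS"], ["C((", "CCN", "CCC"]
        )
        assert report.validity_pct == pytest.approx(100 * 2 / 3)
        assert report.reconstruction_error_pct == pytest.approx(50.0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_report_from_decodes([], [])


class TestCheckpoint:
    def test_save_load_gives_identical_encodings(self, overfit_ae, library50, tmp_path):
        model, _ = overfit_ae
        smiles = [r.canonical_smiles for r in library50[:5]]
        model.save(tmp_path / "ae")
        again = Heteroencoder.load(tmp_path / "ae")
        np.testing.assert_array_equal(model.encode(smiles), again.encode(smiles))
        assert again.noise_active == model.noise_active
        assert again.vocab.tokens == model.vocab.tokens
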