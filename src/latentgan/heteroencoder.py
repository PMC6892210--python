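"""SMILES heteroencoder: sequence model mapping molecules to latent vectors.

An encoder–decoder trained on pairs of *different* randomized SMILES of the
same molecule. The encoder is a stacked bidirectional LSTM whose two final
direction outputs are concatenated and compressed by a dense layer into a
fixed-length latent vector; during training the latent is perturbed with
additive zero-centered gaussian noise (sd 0.1 by default) as a regularizer.
The decoder expands the latent through a dense layer into initial hidden and
cell states for every layer of a stacked unidirectional LSTM, which is
trained with teacher forcing under a token-level categorical cross-entropy
loss. After training the noise layer is deactivated, so encoding and decoding
are deterministic.

Reference defaults follow the published configuration: 2 encoder layers of
512 LSTM units (half per direction), 512-d latent, 4 decoder layers of 512
units, batch normalization with momentum 0.9 on the dense bottleneck layers,
100 epochs at batch size 128 with learning rate 1e-3 held for 50 epochs then
decayed exponentially to 1e-6. Desk-scale work uses the ``small()`` config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from latentgan.arrayio import load_arrays, save_arrays
from latentgan.data import MoleculeRecord, SmilesPair, make_pairs
from latentgan.nn import (
    Adam,
    BatchNorm,
    Dense,
    GaussianNoise,
    LSTM,
    global_norm_clip,
    masked_softmax_cross_entropy,
    softmax,
)
from latentgan.vocab import Vocabulary, decode_indices, encode_batch

from rdkit import Chem


@dataclass(frozen=True)
class HeteroencoderConfig:
    encoder_layers: int = 2
    rnn_units: int = 512          # total per encoder layer; half per direction
    latent_dim: int = 512
    decoder_layers: int = 4
    noise_sd: float = 0.1
    batchnorm_momentum: float = 0.9
    epochs: int = 100
    batch_size: int = 128
    lr_initial: float = 1e-3
    lr_final: float = 1e-6
    lr_constant_epochs: int = 50
    pair_scheme: str = "random_random"
    pairs_per_molecule: int = 1
    grad_clip: float = 1.0
    # freeze batch-norm statistics for the last K epochs: the network then
    # fine-tunes against fixed normalization instead of per-batch estimates,
    # whose sampling noise otherwise caps decoder sharpness at small batch
    bn_freeze_epochs: int = 0

    def __post_init__(self) -> None:
        if min(self.encoder_layers, self.rnn_units, self.latent_dim,
               self.decoder_layers, self.epochs, self.batch_size,
               self.pairs_per_molecule) <= 0:
            raise ValueError("counts must be positive")
        if self.rnn_units % 2:
            raise ValueError("rnn_units must be even (split across directions)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.batchnorm_momentum < 1:
            raise ValueError("batchnorm_momentum must be in (0, 1)")
        if self.lr_final > self.lr_initial:
            raise ValueError("lr_final must be <= lr_initial")
        if self.lr_constant_epochs > self.epochs:
            raise ValueError("lr_constant_epochs must be <= epochs")
        if not 0 <= self.bn_freeze_epochs <= self.epochs:
            raise ValueError("bn_freeze_epochs must be in [0, epochs]")

    @classmethod
    def small(cls, **overrides) -> "HeteroencoderConfig":
        """Desk-scale configuration used by the synthetic-library studies."""
        base = dict(
            rnn_units=64, latent_dim=64, epochs=40, batch_size=16,
            lr_constant_epochs=30, lr_final=1e-4, pairs_per_molecule=8,
            pair_scheme="random_canonical", noise_sd=0.02,
            bn_freeze_epochs=12,
        )
        base.update(overrides)
        if "bn_freeze_epochs" not in overrides:
            base["bn_freeze_epochs"] = min(12, max(1, base["epochs"] // 3))
        return cls(**base)


def learning_rate_at_epoch(epoch: int, config: HeteroencoderConfig) -> float:
    """Learning rate for a 1-indexed epoch: constant for the first
    ``lr_constant_epochs``, then exponential decay reaching ``lr_final``
    exactly at the last epoch."""
    if epoch <= config.lr_constant_epochs or config.epochs == config.lr_constant_epochs:
        return config.lr_initial
    n_decay = config.epochs - config.lr_constant_epochs
    r = (config.lr_final / config.lr_initial) ** (1.0 / n_decay)
    return config.lr_initial * r ** (epoch - config.lr_constant_epochs)


@dataclass
class ReconstructionReport:
    """Decoder quality on a molecule set.

    ``validity_pct``: share of decoded strings that parse as molecules.
    ``reconstruction_error_pct``: among *valid* decodes, share whose canonical
    form differs from the input molecule — decoding to a different SMILES of
    the same molecule is not an error.
    """

    n_inputs: int
    validity_pct: float
    reconstruction_error_pct: float


def reconstruction_report_from_decodes(
    input_smiles: Sequence[str], decoded_smiles: Sequence[str]
) -> ReconstructionReport:
    """Score decoded strings against their inputs (molecule identity, not
    string identity)."""
    if len(input_smiles) == 0:
        raise ValueError("empty input set")
    if len(input_smiles) != len(decoded_smiles):
        raise ValueError("length mismatch")
    n_valid = 0
    n_wrong = 0
    for inp, dec in zip(input_smiles, decoded_smiles):
        mol = Chem.MolFromSmiles(dec) if dec else None
        if mol is None:
            continue
        n_valid += 1
        inp_mol = Chem.MolFromSmiles(inp)
        if Chem.MolToSmiles(mol) != Chem.MolToSmiles(inp_mol):
            n_wrong += 1
    validity = 100.0 * n_valid / len(input_smiles)
    error = 100.0 * n_wrong / n_valid if n_valid else 0.0
    return ReconstructionReport(len(input_smiles), validity, error)


def vocabulary_for_records(
    records: Sequence[MoleculeRecord],
    n_random: int = 10,
    seed: int = 0,
    length_margin: int = 6,
) -> Vocabulary:
    """Vocabulary covering the canonical corpus plus a sweep of randomized
    renderings, with length headroom for renderings outside the sweep."""
    from latentgan.data import randomize_smiles
    from latentgan.vocab import build_vocabulary

    rng = np.random.default_rng(seed)
    corpus = [r.canonical_smiles for r in records]
    for r in records:
        corpus.extend(randomize_smiles(r.canonical_smiles, n_random, rng))
    return build_vocabulary(corpus, length_margin=length_margin)


def _one_hot(idx: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros(idx.shape + (n_classes,), dtype=np.float64)
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


def _reverse_within_length(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence over its first ``length`` positions, leaving the
    trailing padding in place."""
    out = x.copy()
    for b, L in enumerate(lengths):
        out[b, :L] = x[b, :L][::-1]
    return out


class Heteroencoder:
    """Trained-parameter bundle plus the forward/backward machinery."""

    def __init__(self, config: HeteroencoderConfig, vocab: Vocabulary, seed: int = 0):
        self.config = config
        self.vocab = vocab
        self.noise_active = True
        rng = np.random.default_rng(seed)
        V = len(vocab)
        H = config.rnn_units
        Hd = H // 2
        # encoder: per layer a forward and a backward LSTM of H/2 units each
        self.enc_fwd: list[LSTM] = []
        self.enc_bwd: list[LSTM] = []
        d_in = V
        for _ in range(config.encoder_layers):
            self.enc_fwd.append(LSTM(d_in, Hd, rng))
            self.enc_bwd.append(LSTM(d_in, Hd, rng))
            d_in = H
        self.latent_dense = Dense(H, config.latent_dim, rng)
        self.latent_bn = BatchNorm(config.latent_dim, config.batchnorm_momentum)
        self.noise = GaussianNoise(config.noise_sd, rng)
        self.state_dense = Dense(config.latent_dim, config.decoder_layers * 2 * H, rng)
        self.state_bn = BatchNorm(config.decoder_layers * 2 * H, config.batchnorm_momentum)
        self.dec: list[LSTM] = [
            LSTM(V if i == 0 else H, H, rng) for i in range(config.decoder_layers)
        ]
        self.out_dense = Dense(H, V, rng)
        self._rng = rng

    # -- bookkeeping --------------------------------------------------------
    @property
    def layers(self):
        return (
            self.enc_fwd + self.enc_bwd
            + [self.latent_dense, self.latent_bn, self.state_dense, self.state_bn]
            + self.dec + [self.out_dense]
        )

    def _set_training(self, training: bool) -> None:
        self.latent_bn.training = training
        self.state_bn.training = training
        self.noise.active = training and self.noise_active

    def parameter_count(self) -> int:
        return sum(v.size for layer in self.layers for _, v, _ in layer.parameters())

    # -- encoder ------------------------------------------------------------
    def _encode_forward(self, idx: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """One-hot indices -> latent vectors. Caches for backward."""
        V = len(self.vocab)
        x = _one_hot(idx, V)
        self._enc_lengths = lengths
        h = x
        self._bwd_rev_outputs = []
        for li in range(self.config.encoder_layers):
            fwd_out = self.enc_fwd[li].forward(h)
            h_rev = _reverse_within_length(h, lengths)
            bwd_out_rev = self.enc_bwd[li].forward(h_rev)
            self._bwd_rev_outputs.append(bwd_out_rev)
            if li < self.config.encoder_layers - 1:
                h = np.concatenate(
                    [fwd_out, _reverse_within_length(bwd_out_rev, lengths)], axis=2
                )
            else:
                gather = (np.arange(len(lengths)), lengths - 1)
                final = np.concatenate([fwd_out[gather], bwd_out_rev[gather]], axis=1)
        z = self.latent_dense.forward(final)
        z = self.latent_bn.forward(z)
        return self.noise.forward(z)

    def _encode_backward(self, dlatent: np.ndarray) -> None:
        lengths = self._enc_lengths
        dz = self.noise.backward(dlatent)
        dz = self.latent_bn.backward(dz)
        dfinal = self.latent_dense.backward(dz)
        Hd = self.config.rnn_units // 2
        B = dfinal.shape[0]
        n_layers = self.config.encoder_layers
        T = self._bwd_rev_outputs[-1].shape[1]
        dfwd_seq = np.zeros((B, T, Hd))
        dbwd_rev_seq = np.zeros((B, T, Hd))
        gather = (np.arange(B), lengths - 1)
        dfwd_seq[gather] = dfinal[:, :Hd]
        dbwd_rev_seq[gather] = dfinal[:, Hd:]
        for li in range(n_layers - 1, -1, -1):
            dx_f, _, _ = self.enc_fwd[li].backward(dfwd_seq)
            dx_b_rev, _, _ = self.enc_bwd[li].backward(dbwd_rev_seq)
            dx = dx_f + _reverse_within_length(dx_b_rev, lengths)
            if li > 0:
                dfwd_seq = dx[:, :, :Hd]
                dbwd_rev_seq = _reverse_within_length(dx[:, :, Hd:], lengths)

    # -- decoder ------------------------------------------------------------
    def _decoder_states(self, latent: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        s = self.state_dense.forward(latent)
        s = self.state_bn.forward(s)
        H = self.config.rnn_units
        states = []
        for i in range(self.config.decoder_layers):
            h0 = s[:, (2 * i) * H : (2 * i + 1) * H]
            c0 = s[:, (2 * i + 1) * H : (2 * i + 2) * H]
            states.append((h0, c0))
        return states

    def _decoder_states_backward(self, dstates) -> np.ndarray:
        ds = np.concatenate([np.concatenate([dh, dc], axis=1) for dh, dc in dstates], axis=1)
        ds = self.state_bn.backward(ds)
        return self.state_dense.backward(ds)

    def _teacher_forced_loss(
        self, latent: np.ndarray, tgt_idx: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Teacher forcing: the true previous token is the decoder input at
        every step. Returns (loss, dlatent)."""
        V = len(self.vocab)
        states = self._decoder_states(latent)
        dec_in = _one_hot(tgt_idx[:, :-1], V)
        h = dec_in
        for i, lstm in enumerate(self.dec):
            h0, c0 = states[i]
            h = lstm.forward(h, h0=h0, c0=c0)
        B, T, _ = h.shape
        logits = self.out_dense.forward(h.reshape(B * T, -1)).reshape(B, T, V)
        targets = tgt_idx[:, 1:]
        mask = (targets != self.vocab.pad_index).astype(np.float64)
        loss, dlogits = masked_softmax_cross_entropy(logits, targets, mask)
        dh = self.out_dense.backward(dlogits.reshape(B * T, -1)).reshape(B, T, -1)
        dstates = [None] * len(self.dec)
        for i in range(len(self.dec) - 1, -1, -1):
            dh, dh0, dc0 = self.dec[i].backward(dh)
            dstates[i] = (dh0, dc0)
        dlatent = self._decoder_states_backward(dstates)
        return loss, dlatent

    def _refresh_bn_stats(self, records: Sequence[MoleculeRecord],
                          batch_size: int = 256) -> None:
        """Replace EMA batch-norm statistics with exact population statistics
        over the corpus, so frozen-BN fine-tuning (and evaluation) normalize
        against the true activation distribution."""
        smiles = [r.canonical_smiles for r in records]
        captured: list[np.ndarray] = []

        def capture(bn):
            orig = bn.__class__.forward

            def fwd(x, _bn=bn, _orig=orig):
                captured.append(x.copy())
                return _orig(_bn, x)

            return fwd

        noise_was = self.noise.active
        try:
            self.noise.active = False
            self.latent_bn.forward = capture(self.latent_bn)
            self.encode(smiles, batch_size)
            X = np.vstack(captured)
            del self.latent_bn.forward  # restore the class method
            self.latent_bn.running_mean = X.mean(axis=0)
            self.latent_bn.running_var = X.var(axis=0)
            captured.clear()
            self.state_bn.forward = capture(self.state_bn)
            self._decoder_states(self.encode(smiles, batch_size))
            S = np.vstack(captured)
            del self.state_bn.forward
            self.state_bn.running_mean = S.mean(axis=0)
            self.state_bn.running_var = S.var(axis=0)
        finally:
            self.noise.active = noise_was
            for bn in (self.latent_bn, self.state_bn):
                if "forward" in bn.__dict__:
                    del bn.forward

    def _fits(self, smiles: str) -> bool:
        from latentgan.vocab import encode_indices, TokenizationError

        try:
            encode_indices(smiles, self.vocab)
            return True
        except TokenizationError:
            return False

    # -- public API ---------------------------------------------------------
    def train(
        self,
        records: Sequence[MoleculeRecord],
        seed: int = 0,
        progress: Callable[[int, float, float], None] | None = None,
    ) -> list[float]:
        """Train on randomized-SMILES pairs re-enumerated every epoch.

        Returns the per-epoch mean training loss. Deactivates the noise layer
        on completion so subsequent encode/decode calls are deterministic.
        """
        if len(records) == 0:
            raise ValueError("empty training set")
        cfg = self.config
        rng = np.random.default_rng(seed)
        opt = Adam(self.layers, lr=cfg.lr_initial)
        losses: list[float] = []
        self.noise_active = True
        bn_frozen = False
        for epoch in range(1, cfg.epochs + 1):
            opt.lr = learning_rate_at_epoch(epoch, cfg)
            if (not bn_frozen
                    and epoch > cfg.epochs - cfg.bn_freeze_epochs):
                self._refresh_bn_stats(records)
                bn_frozen = True
            pairs: list[SmilesPair] = []
            for k in range(cfg.pairs_per_molecule):
                # "mixed" alternates randomized-input and canonical pairs so
                # the encoder sees both augmented and canonical renderings
                scheme = cfg.pair_scheme
                if scheme == "mixed":
                    scheme = "random_canonical" if k % 2 == 0 else "canonical_canonical"
                for p in make_pairs(records, rng, scheme):
                    # randomized renderings can exceed the vocabulary's length
                    # cap or token set; fall back to the canonical form
                    canon = records[p.molecule_id].canonical_smiles
                    inp = p.input_smiles if self._fits(p.input_smiles) else canon
                    tgt = p.target_smiles if self._fits(p.target_smiles) else canon
                    pairs.append(SmilesPair(inp, tgt, p.molecule_id))
            # length-bucketed batches: sort by sequence length (random
            # tie-break), chunk, then shuffle batch order — each batch is
            # trimmed to its own longest sequence, which roughly halves the
            # wasted padding compute
            keys = np.array([
                max(len(p.input_smiles), len(p.target_smiles)) for p in pairs
            ])
            order = rng.permutation(len(pairs))
            order = order[np.argsort(keys[order], kind="stable")]
            starts = rng.permutation(np.arange(0, len(pairs), cfg.batch_size))
            epoch_loss = 0.0
            n_batches = 0
            self._set_training(True)
            if bn_frozen:
                self.latent_bn.training = False
                self.state_bn.training = False
            for start in starts:
                batch = [pairs[i] for i in order[start : start + cfg.batch_size]]
                in_idx, in_len = encode_batch([p.input_smiles for p in batch], self.vocab)
                tgt_idx, tgt_len = encode_batch([p.target_smiles for p in batch], self.vocab)
                in_idx = in_idx[:, : in_len.max()]
                tgt_idx = tgt_idx[:, : tgt_len.max()]
                opt.zero_grad()
                latent = self._encode_forward(in_idx, in_len)
                loss, dlatent = self._teacher_forced_loss(latent, tgt_idx)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch {n_batches}"
                    )
                self._encode_backward(dlatent)
                global_norm_clip(self.layers, cfg.grad_clip)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / n_batches)
            if progress is not None:
                progress(epoch, losses[-1], opt.lr)
        self.noise_active = False
        self._set_training(False)
        return losses

    def encode(self, smiles_batch: Sequence[str], batch_size: int = 256) -> np.ndarray:
        """Encode SMILES to latent vectors (deterministic once trained)."""
        if len(smiles_batch) == 0:
            return np.zeros((0, self.config.latent_dim))
        self._set_training(False)
        out = []
        for start in range(0, len(smiles_batch), batch_size):
            chunk = smiles_batch[start : start + batch_size]
            idx, lengths = encode_batch(chunk, self.vocab)
            out.append(self._encode_forward(idx[:, : lengths.max()], lengths))
        return np.vstack(out)

    def decode(
        self, latents: np.ndarray, batch_size: int = 256, greedy: bool = True,
        seed: int = 0,
    ) -> list[str]:
        """Greedy argmax decoding from the start token until the end token or
        the length cap. Multinomial sampling is available with
        ``greedy=False``."""
        latents = np.atleast_2d(np.asarray(latents, dtype=np.float64))
        if latents.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent dim {latents.shape[1]} != model {self.config.latent_dim}"
            )
        self._set_training(False)
        rng = np.random.default_rng(seed)
        V = len(self.vocab)
        H = self.config.rnn_units
        results: list[str] = []
        for start in range(0, len(latents), batch_size):
            z = latents[start : start + batch_size]
            B = z.shape[0]
            states = self._decoder_states(z)
            hs = [h0.copy() for h0, _ in states]
            cs = [c0.copy() for _, c0 in states]
            tok = np.full(B, self.vocab.start_index, dtype=np.int64)
            seqs = np.full((B, self.vocab.max_length), self.vocab.pad_index, dtype=np.int64)
            done = np.zeros(B, dtype=bool)
            for t in range(self.vocab.max_length - 1):
                x = _one_hot(tok[:, None], V)
                for i, lstm in enumerate(self.dec):
                    seq = lstm.forward(x, h0=hs[i], c0=cs[i])
                    cache = lstm._cache[1][0]
                    hs[i] = seq[:, 0]
                    # final cell state: c = f*c_prev + i*g, recover from cache
                    gi, gf, gg, go, c_prev, tanh_c, _ = cache
                    cs[i] = gf * c_prev + gi * gg
                    x = seq
                probs = softmax(self.out_dense.forward(hs[-1]))
                if greedy:
                    tok = probs.argmax(axis=1)
                else:
                    cum = probs.cumsum(axis=1)
                    u = rng.random(B)[:, None]
                    tok = (u > cum).sum(axis=1)
                tok = np.where(done, self.vocab.pad_index, tok)
                seqs[:, t] = tok
                done |= tok == self.vocab.end_index
                if done.all():
                    break
            results.extend(decode_indices(seq, self.vocab) for seq in seqs)
        return results

    def reconstruction_report(
        self, smiles_set: Sequence[str], batch_size: int = 256
    ) -> ReconstructionReport:
        if len(smiles_set) == 0:
            raise ValueError("empty input set")
        decoded = self.decode(self.encode(smiles_set, batch_size), batch_size)
        return reconstruction_report_from_decodes(smiles_set, decoded)

    # -- checkpointing ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Checkpoint: JSON config + vocabulary + npz weight arrays."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "config.json").write_text(json.dumps(asdict(self.config)))
        self.vocab.save(d / "vocabulary.json")
        arrays = {}
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "state_dict"):
                for name, arr in layer.state_dict().items():
                    arrays[f"layer{i}.{name}"] = arr
        save_arrays(d / "weights.npz", arrays)
        (d / "meta.json").write_text(json.dumps({"noise_active": self.noise_active}))

    @classmethod
    def load(cls, directory: str | Path) -> "Heteroencoder":
        d = Path(directory)
        config = HeteroencoderConfig(**json.loads((d / "config.json").read_text()))
        vocab = Vocabulary.load(d / "vocabulary.json")
        model = cls(config, vocab)
        data = load_arrays(d / "weights.npz")
        for i, layer in enumerate(model.layers):
            if hasattr(layer, "state_dict"):
                layer.load_state_dict(
                    {name: data[f"layer{i}.{name}"] for name in layer.state_dict()}
                )
        meta = json.loads((d / "meta.json").read_text())
        model.noise_active = meta["noise_active"]
        model._set_training(False)
        return model
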