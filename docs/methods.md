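# Methods

## Overview

`latentgan` implements a two-stage generative model for de novo molecular
design. A *SMILES heteroencoder* — an encoder–decoder network trained on
pairs of different SMILES renderings of the same molecule — maps molecules
to fixed-length latent vectors *h*. A *Wasserstein GAN with gradient penalty*
(WGAN-GP) is then trained on the encoded latent vectors of a training
corpus: its generator learns to map uniform noise to realistic latent
vectors, which the frozen decoder converts back into SMILES strings. The
two stages are trained separately; the GAN never sees a SMILES string, so it
can concentrate on the distribution of latent codes rather than on syntax.

The package also contains the complete evaluation battery used to judge
generated sets: validity / uniqueness / novelty, predicted target activity
under an FCFP6 SVM, recovered held-out actives (exact and at Tanimoto 0.7),
compound- and Murcko-scaffold-level nearest-neighbor similarity profiles,
compound/scaffold set overlap, QED and synthetic-accessibility
distributions, and a 2-component PCA chemical-space map on MQN fingerprints.

## Heteroencoder

Architecture (reference configuration):

- **Encoder**: one-hot token sequences pass through a 2-layer bidirectional
  LSTM with 512 units per layer (256 per direction). The final outputs of
  the two directions are concatenated and compressed by a 512-d dense layer.
- **Noise**: during training the latent vector is perturbed with additive
  zero-centered gaussian noise, sd 0.1. After training the noise layer is
  deactivated, making encoding and decoding deterministic.
- **Decoder**: a dense layer expands the latent vector into initial hidden
  and cell states for all 4 layers of a unidirectional LSTM decoder
  (`decoder_layers x 2 x units` values from a single dense map — the most
  literal reading of "copied and inserted as hidden and cell states"); a
  dense softmax head yields per-position token probabilities.
- **Batch normalization** (momentum 0.9) is applied to the two dense
  bottleneck layers: the encoder's latent projection (before the noise
  layer) and the decoder's state expansion. We deliberately do *not*
  batch-normalize the recurrent output sequences: per-timestep
  normalization over padded variable-length batches couples the statistics
  to the padding structure and to the length-bucketed batch composition,
  and at desk scale it measurably adds noise without improving convergence.
  This placement is held constant everywhere.
- **Training**: teacher forcing under token-level categorical cross entropy,
  Adam, learning rate 1e-3 held for the first 50 of 100 epochs then decayed
  exponentially to 1e-6 at the last epoch (the schedule is exposed as
  `learning_rate_at_epoch` and tested against its closed form). Gradients
  are clipped to a global norm (default 1.0) as a safety net against rare
  loss spikes; clipping is configurable and not part of the reference
  description.

Tokenization is token-level rather than character-level: `Cl`, `Br`,
bracket atoms (`[nH]`, …) and `%nn` ring closures are single tokens, so the
decoder can never emit half a halogen and tokenize/join is exactly invertible.
The vocabulary's length cap is the longest tokenized corpus entry + 2
(start/end) plus a small margin for randomized renderings that tokenize
longer than anything in the construction sweep; training pairs whose
rendering still does not fit fall back to the canonical form of the same
molecule.

**Pair construction.** The reference scheme draws two fresh randomized
renderings of each molecule per epoch (`random_random`). Randomized-SMILES
targets carry irreducible rendering entropy — the model cannot know *which*
rendering it is being asked to produce — which is harmless at corpus scale
but dominates the loss floor when a small model must memorize a small
library. The desk-scale configuration (`HeteroencoderConfig.small()`)
therefore uses `random_canonical` pairs: randomized inputs (keeping the
heteroencoder property that all renderings of a molecule encode to one
point) with the canonical rendering as the deterministic decode target.
Schemes are configurable (`random_random`, `random_canonical`,
`canonical_random`, `canonical_canonical`, `mixed`).

**Reconstruction metrics.** `validity` is the share of decoded strings that
parse; `reconstruction error` is the share of *valid* decodes whose
canonical form differs from the input molecule. Decoding to a different
SMILES of the same molecule is not an error; invalid decodes are excluded
from the error denominator.

**Decoding** is greedy argmax from the start token until the end token or
the length cap (multinomial sampling is available behind a flag). Greedy
decoding keeps the post-training pipeline fully deterministic.

## Latent GAN

- **Critic**: three dense layers — two of width 256 with leaky ReLU
  (slope 0.2) between, and an unactivated scalar output. No batch
  normalization (a gradient-penalized critic and batch norm conflict).
- **Generator**: five dense layers of width 256, each followed by batch
  normalization and leaky ReLU, then a linear map to the latent dimension.
  Noise prior: uniform on [-1, 1] per component, noise dimension equal to
  the latent dimension by default.
- **Loss**: critic minimizes `E[c(fake)] - E[c(real)] + λ·E[(‖∇ c(x̂)‖₂ - 1)²]`
  with λ = 10 and per-sample uniform interpolates x̂ between real and fake;
  generator maximizes `E[c(fake)]`. Five critic updates run per generator
  update; the counter carries across epochs, so the 5:1 ratio is exact.
- **Optimizer**: Adam, lr 2e-4, betas (0.5, 0.9) — the standard WGAN-GP
  settings; all configurable.
- **"Epoch"** means one full pass of the critic over the shuffled real
  latent set with generator updates interleaved at the 5:1 ratio. The
  reference counts (30,000 general / 10,000 targeted) are plausibly
  generator-round counts; both readings are runnable since epochs, batch
  size and ratio are independent knobs.

The whole network stack is written in NumPy (float64) with hand-written
backward passes. For the gradient penalty this requires the derivative of
the critic's input gradient with respect to its weights (double backprop);
because the critic is piecewise linear (dense + leaky ReLU), that derivative
is computed analytically with the activation masks held constant, which is
exact almost everywhere. Every backward pass — including this one — is
validated against central finite differences in the test suite, and
training is bit-reproducible under a fixed seed.

## Synthetic study libraries

Real corpus-scale training data (millions of drug-like molecules, ExCAPE
target sets) cannot ship with the package, so `latentgan.fixtures` generates
desk-scale libraries with the statistical structure the method relies on:

- a fixed, versioned pool of 31 mono-/bi-cyclic cores over {C, N, O, S, Cl,
  Br} (benzene through benzimidazole, piperazine, biphenyl, …);
- each library draws `n_series` cores and decorates them with 1–3 short
  acyclic substituents (alkyl, alkoxy, amino, halogen, nitrile, acyl, …) at
  random attachment points, so every molecule in a series shares its Murcko
  scaffold and series scaffolds differ;
- all molecules are standardized, deduplicated, and filter-closed (allowed
  elements, ≤ 50 heavy atoms); generation is deterministic under the spec
  seed and fails loudly if the diversity budget is exhausted;
- `plant_actives` labels whole series active until a target fraction of
  molecules is reached, making activity scaffold-correlated: an FCFP6 SVM
  can learn it (held-out-series AUC ≈ 1 on well-separated cores) and label
  shuffling collapses it to chance — the planted-signal/negative-control
  pair used throughout the tests.

What the fixtures do **not** emulate: real structure–activity cliffs,
property distributions of vendor catalogs, tautomer-rich chemistry, very
long SMILES (> ~40 tokens), or inter-series similarity gradients. Passing
tests on these libraries therefore demonstrates that the machinery is
correct and converges in the intended direction, not that the package
reproduces corpus-scale published figures.

## Scaled-down study conditions

The reference configuration (512-unit layers, 100 epochs on 1.35 M
molecules; 10,000–30,000 GAN epochs) is far outside a single-CPU budget.
The bundled studies and tests therefore run a small configuration chosen
once and used everywhere:

- library: 500 molecules, 10 series (the SVM negative control uses its own
  500-molecule library);
- heteroencoder: 2×64-unit encoder, 64-d latent, 4×64-unit decoder,
  40 epochs, batch 16, 8 pairs/molecule/epoch (`random_canonical`), lr 1e-3
  constant for 30 epochs then decayed to 1e-4, noise sd scaled to 0.02 —
  the 0.1 reference value is calibrated against corpus-scale overfitting
  and, on unit-variance latent features of a 500-molecule library, puts a
  hard floor under the achievable reconstruction precision;
- **batch-norm freeze** (`bn_freeze_epochs`, 12 of 40 in the small config):
  at small batch sizes the per-batch normalization statistics carry
  sampling noise of roughly σ/√B per feature — larger than the noise layer
  itself — which caps how sharp the decoder can become. For the final K
  epochs the batch-norm statistics are replaced by exact population
  statistics over the corpus and frozen while fine-tuning continues against
  the fixed normalization. This moves the small config from ~50% to ~13%
  reconstruction error; at corpus scale (batch 128) the effect is minor and
  the feature defaults to off;
- GAN on latents: widths 128, 150–300 epochs, batch 32 (ratio and λ
  unchanged); the 2-D ring study uses the reference widths (256) and 2000
  epochs;
- batches are length-bucketed (sorted by sequence length, batch order
  shuffled) to avoid padding compute; this is a throughput optimization
  only.

At this scale the heteroencoder reaches ≥ 90% decode validity with ≤ 30%
reconstruction error on its training library (measured: 99.8% / 12.6% at
the study seed) — the direction-of-effect analogue of the corpus-scale
99%/18% — and the GAN at least halves the exact-assignment 1-Wasserstein
distance to a 2-D ring of 8 gaussians relative to its untrained
initialization.

## Evaluation definitions

For a sampled set: `valid%` = parseable / sampled; `unique%` = distinct
canonical molecules / valid; `novel%` = unique not in the training set /
unique; `active%` = unique predicted active / unique (the alternative
novel-based denominator is reported alongside); `recovered actives%` =
held-out actives regenerated exactly / all held-out actives;
`recovered neighbors` = held-out actives with ≥ 1 sampled compound at FCFP6
Tanimoto ≥ 0.7. Similarity profiles use nearest-neighbor (maximum) Tanimoto
— the field convention — with narrative bins [1.0], [0.7, 1.0), [0.4, 0.7),
[0, 0.4); scaffold-level profiles compute FCFP6 on Murcko scaffolds and
exclude acyclic molecules (counted and reported). Chemical-series splits
are single-linkage connected components at FCFP6 Tanimoto ≥ 0.4, which
guarantees no pair at or above the threshold straddles the split; whole
clusters are assigned to the test side in seeded order until the test
fraction is met. MQN vectors are z-scored per feature before PCA (MQN
components span wildly different scales); PCA signs are fixed by making
each component's largest-magnitude loading positive.

## Numerical and design notes

- All randomness flows from explicit seeds through `numpy.random.Generator`;
  repeated runs produce byte-identical artifacts, and checkpoints are
  written with pinned zip timestamps so manifest hashes are reproducible.
- SMILES standardization: parse → largest fragment → neutralize → strip
  isotopes → canonical tautomer → strip stereo → canonicalize (stereo
  stripping keeps the generative alphabet small and is configurable).
- The SVM uses an RBF kernel with default regularization and probability
  calibration, evaluated on the held-out series side (ROC-AUC and Cohen's
  kappa at the 0.5 probability threshold).
- Degenerate inputs: empty Tanimoto union → similarity 0; all-identical
  split input → one side plus a warning; zero-vector decode input →
  decodes to some (possibly empty) string without error; non-finite
  training loss aborts with the step index.

## Known limitations

- Desk-scale models memorize their small libraries; sampled sets are
  correspondingly less novel than corpus-scale results.
- Greedy decoding returns one rendering per latent point; sampling-based
  decoding is available but untested at scale.
- The analytic double-backprop for the penalty assumes a piecewise-linear
  critic; switching the critic activation would require revisiting it.
- Per-timestep recurrent batch normalization is intentionally omitted (see
  above); at corpus scale this is a deviation from the reference
  architecture whose effect we have not measured.
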