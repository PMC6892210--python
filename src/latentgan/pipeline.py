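"""End-to-end orchestration: preprocess -> pretrain -> encode -> GAN ->
sample -> decode -> evaluate, with per-stage checkpoints and a manifest.

Two workflows are provided. ``run_general`` trains the generator on a
(subset of the) whole corpus and reports validity/uniqueness/novelty.
``run_targeted`` reuses a pretrained heteroencoder, splits a labeled target
set by chemical series, fits the SVM activity model on the training side,
trains the GAN on the encoded *active training* molecules only, and scores
the sample against the held-out actives (recovered actives and neighbors).

Every stage writes its artifact into the run directory and is skipped on
rerun if the artifact already exists, so deleting a single checkpoint
retrains only that stage. The manifest records configs, seeds, stage hashes
and metrics — no timestamps, so repeated runs with one seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from latentgan.data import (
    MoleculeRecord,
    SplitResult,
    series_split,
    write_smi,
)
from latentgan.gan import GanConfig, GanModel, train_gan
from latentgan.heteroencoder import (
    Heteroencoder,
    HeteroencoderConfig,
    vocabulary_for_records,
)
from latentgan.scoring import sample_report, train_target_model


@dataclass
class EvaluationConfig:
    nn_threshold: float = 0.7
    low_similarity_bin: float = 0.4
    series_similarity_threshold: float = 0.4
    test_fraction: float = 0.3


@dataclass
class RunConfig:
    output_dir: str
    heteroencoder: HeteroencoderConfig = field(default_factory=HeteroencoderConfig)
    gan: GanConfig = field(default_factory=GanConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    gan_subset: int | None = None   # train the GAN on a seeded subset this size
    sample_n: int = 1000            # molecules to sample after training

    def __post_init__(self) -> None:
        if self.gan.latent_dim != self.heteroencoder.latent_dim:
            raise ValueError("gan.latent_dim must equal heteroencoder.latent_dim")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _save_latents(path: Path, latents: np.ndarray) -> None:
    np.savetxt(path, latents, fmt="%.17g", delimiter=",")


def load_latents(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def _stage_hashes(out: Path, names: Sequence[str]) -> dict[str, str]:
    hashes = {}
    for name in names:
        p = out / name
        if p.is_file():
            hashes[name] = _sha256(p)
        elif p.is_dir():
            hashes[name] = hashlib.sha256(
                b"".join(_sha256(f).encode() for f in sorted(p.rglob("*")) if f.is_file())
            ).hexdigest()
    return hashes


def _pretrain_stage(
    out: Path, records: Sequence[MoleculeRecord], config: RunConfig
) -> Heteroencoder:
    ae_dir = out / "heteroencoder"
    if (ae_dir / "weights.npz").exists():
        return Heteroencoder.load(ae_dir)
    vocab = vocabulary_for_records(records, seed=config.seed)
    model = Heteroencoder(config.heteroencoder, vocab, seed=config.seed)
    losses = model.train(records, seed=config.seed)
    model.save(ae_dir)
    (ae_dir / "losses.json").write_text(json.dumps(losses))
    return model

def _encode_stage(
    out: Path, name: str, ae: Heteroencoder, smiles: Sequence[str]
) -> np.ndarray:
    path = out / name
    if path.exists():
        return load_latents(path)
    latents = ae.encode(smiles)
    _save_latents(path, latents)
    return latents


def _gan_stage(out: Path, latents: np.ndarray, gan_config: GanConfig) -> GanModel:
    gan_dir = out / "gan"
    if (gan_dir / "weights.npz").exists():
        return GanModel.load(gan_dir)
    model = train_gan(latents, gan_config)
    model.save(gan_dir)
    return model


def _sample_stage(
    out: Path, gan: GanModel, ae: Heteroencoder, n: int, seed: int
) -> list[str]:
    smi = out / "sampled.smi"
    if smi.exists():
        return [line.split()[0] if line.split() else "" for line in smi.read_text().splitlines()]
    latents = gan.generate_latents(n, seed=seed)
    _save_latents(out / "sampled_latents.csv", latents)
    decoded = ae.decode(latents)
    smi.write_text("\n".join(decoded) + "\n")
    return decoded


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> dict:
    manifest = {
        "seed": config.seed,
        "config": {
            "heteroencoder": asdict(config.heteroencoder),
            "gan": asdict(config.gan),
            "evaluation": asdict(config.evaluation),
            "gan_subset": config.gan_subset,
            "sample_n": config.sample_n,
        },
        "stage_hashes": _stage_hashes(
            out,
            ["train.smi", "heteroencoder", "latents.csv", "gan",
             "sampled_latents.csv", "sampled.smi", "split.json"],
        ),
    }
    manifest.update(extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_general(records: Sequence[MoleculeRecord], config: RunConfig) -> dict:
    """Full chain on an unlabeled corpus; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_smi = out / "train.smi"
    if not train_smi.exists():
        write_smi(train_smi, records)
    ae = _pretrain_stage(out, records, config)

    all_smiles = [r.canonical_smiles for r in records]
    if config.gan_subset is not None and config.gan_subset < len(records):
        rng = np.random.default_rng(config.seed)
        subset_idx = rng.choice(len(records), size=config.gan_subset, replace=False)
        gan_smiles = [all_smiles[i] for i in sorted(subset_idx)]
    else:
        gan_smiles = all_smiles
    latents = _encode_stage(out, "latents.csv", ae, gan_smiles)
    gan = _gan_stage(out, latents, config.gan)
    sampled = _sample_stage(out, gan, ae, config.sample_n, config.seed)

    report = sample_report(sampled, all_smiles, test_actives=[], model=None,
                           nn_threshold=config.evaluation.nn_threshold)
    (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
    return _write_manifest(out, config, {
        "report": report.as_dict(),
        "n_train": len(records),
        "n_gan_train": int(latents.shape[0]),
    })


def run_targeted(
    records: Sequence[MoleculeRecord],
    config: RunConfig,
    pretrained_ae: Heteroencoder | str | Path,
) -> dict:
    """Targeted chain on a labeled set, reusing a pretrained heteroencoder.

    Splits by chemical series, fits the activity SVM on the training side,
    trains the GAN on the encoded active training molecules, then scores the
    decoded sample against the held-out actives.
    """
    labels = {r.activity_label for r in records}
    if labels != {"active", "inactive"}:
        raise ValueError("target set must contain both active and inactive molecules")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ae = (
        pretrained_ae
        if isinstance(pretrained_ae, Heteroencoder)
        else Heteroencoder.load(pretrained_ae)
    )

    split_path = out / "split.json"
    if split_path.exists():
        split = SplitResult.from_json(split_path.read_text())
    else:
        split = series_split(
            records,
            similarity_threshold=config.evaluation.series_similarity_threshold,
            test_fraction=config.evaluation.test_fraction,
            seed=config.seed,
        )
        split_path.write_text(split.to_json())

    target_model = train_target_model(records, split, seed=config.seed)

    train_records = [records[i] for i in split.train_ids]
    train_actives = [r.canonical_smiles for r in train_records if r.activity_label == "active"]
    test_actives = [
        records[i].canonical_smiles
        for i in split.test_ids
        if records[i].activity_label == "active"
    ]
    if not train_actives or not test_actives:
        raise ValueError("split left no actives on one side; adjust test_fraction")
    train_smi = out / "train.smi"
    if not train_smi.exists():
        write_smi(train_smi, train_records)

    latents = _encode_stage(out, "latents.csv", ae, train_actives)
    gan = _gan_stage(out, latents, config.gan)
    sampled = _sample_stage(out, gan, ae, config.sample_n, config.seed)

    report = sample_report(
        sampled,
        training_set=train_actives,
        test_actives=test_actives,
        model=target_model,
        nn_threshold=config.evaluation.nn_threshold,
    )
    (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
    return _write_manifest(out, config, {
        "report": report.as_dict(),
        "svm": {"roc_auc": target_model.roc_auc, "kappa": target_model.kappa,
                "n_train": target_model.n_train, "n_test": target_model.n_test},
        "n_gan_train": int(latents.shape[0]),
        "n_train_actives": len(train_actives),
        "n_test_actives": len(test_actives),
    })
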