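"""Evaluation battery for generated molecule sets.

Covers the standard generative-chemistry report: validity / uniqueness /
novelty of a sampled set, predicted activity under an FCFP6 SVM target model,
recovered held-out actives (exact and Tanimoto-0.7 neighbors), compound- and
Murcko-scaffold-level nearest-neighbor similarity profiles, compound/scaffold
set overlap, QED and synthetic-accessibility distributions, and a 2-component
PCA chemical-space map on MQN fingerprints.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, DataStructs, RDConfig
from rdkit.Chem import QED, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.decomposition import PCA
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.svm import SVC

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib module)

from latentgan.data import MoleculeRecord, SplitResult  # noqa: E402

FCFP6_BITS = 2048
_FCFP6_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=3,
    fpSize=FCFP6_BITS,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)


def _as_mol(mol_or_smiles) -> Chem.Mol:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    mol = Chem.MolFromSmiles(mol_or_smiles)
    if mol is None:
        raise ValueError(f"invalid molecule: {mol_or_smiles!r}")
    return mol


def fcfp6(mol_or_smiles) -> np.ndarray:
    """2048-bit FCFP6 (feature-class Morgan, radius 3) as a 0/1 vector."""
    fp = _FCFP6_GEN.GetFingerprint(_as_mol(mol_or_smiles))
    arr = np.zeros(FCFP6_BITS, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr


def fcfp6_rdkit_fps(smiles_list: Sequence[str]):
    """Native RDKit bit vectors, for fast BulkTanimotoSimilarity scans."""
    return [_FCFP6_GEN.GetFingerprint(_as_mol(s)) for s in smiles_list]


def mqn(mol_or_smiles) -> np.ndarray:
    """The 42 molecular-quantum-number integer descriptors."""
    return np.asarray(rdMolDescriptors.MQNs_(_as_mol(mol_or_smiles)), dtype=np.int64)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a∧b| / |a∨b| on equal-length bit vectors; 0 when both are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def murcko_scaffold(mol_or_smiles) -> str:
    """Canonical SMILES of the Murcko scaffold; empty for acyclic molecules."""
    mol = _as_mol(mol_or_smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold) if scaffold is not None else ""


def qed_score(mol_or_smiles) -> float:
    """Quantitative estimate of drug-likeness, in [0, 1]."""
    return float(QED.qed(_as_mol(mol_or_smiles)))


def sa_score(mol_or_smiles) -> float:
    """Ertl–Schuffenhauer synthetic accessibility (≈1 easy … 10 hard)."""
    return float(sascorer.calculateScore(_as_mol(mol_or_smiles)))


# ---------------------------------------------------------------------------
# Target activity model

@dataclass
class TargetModel:
    """FCFP6 SVM activity classifier with held-out-series performance."""

    svm: SVC
    roc_auc: float
    kappa: float
    n_train: int
    n_test: int
    active_threshold: float = 0.5

    def probability_active(self, smiles_list: Sequence[str]) -> np.ndarray:
        X = np.stack([fcfp6(s) for s in smiles_list]).astype(np.float64)
        idx = list(self.svm.classes_).index(1)
        return self.svm.predict_proba(X)[:, idx]

    def predict_active(self, smiles_list: Sequence[str]) -> np.ndarray:
        return self.probability_active(smiles_list) >= self.active_threshold


def train_target_model(
    records: Sequence[MoleculeRecord],
    split: SplitResult,
    c: float = 1.0,
    gamma: str | float = "scale",
    seed: int = 0,
) -> TargetModel:
    """RBF-kernel SVM on FCFP6 bits, evaluated on the held-out series side.

    Probability calibration is enabled so downstream maps can color sampled
    compounds by their probability of activity.
    """
    labels = np.array(
        [1 if r.activity_label == "active" else 0 for r in records], dtype=np.int64
    )
    X = np.stack([fcfp6(r.canonical_smiles) for r in records]).astype(np.float64)
    tr, te = split.train_ids, split.test_ids
    y_tr, y_te = labels[tr], labels[te]
    if len(set(y_tr.tolist())) < 2 or len(set(y_te.tolist())) < 2:
        raise ValueError("both classes must be present on both split sides")
    svm = SVC(C=c, gamma=gamma, kernel="rbf", probability=True, random_state=seed)
    svm.fit(X[tr], y_tr)
    idx = list(svm.classes_).index(1)
    prob_te = svm.predict_proba(X[te])[:, idx]
    auc = float(roc_auc_score(y_te, prob_te))
    kappa = float(cohen_kappa_score(y_te, (prob_te >= 0.5).astype(int)))
    return TargetModel(svm=svm, roc_auc=auc, kappa=kappa, n_train=len(tr), n_test=len(te))


# ---------------------------------------------------------------------------
# Sampled-set report

@dataclass
class SampleReport:
    """Validity / uniqueness / novelty / activity metrics for a sampled set.

    Percentages chain: unique is counted among valid, novel and active among
    unique. ``active_pct_of_novel`` restates predicted activity over the
    novel subset (the alternative denominator), alongside the primary
    unique-based figure.
    """

    n_sampled: int
    valid_pct: float
    unique_pct: float
    novel_pct: float
    active_pct: float
    active_pct_of_novel: float
    recovered_actives_pct: float
    recovered_neighbors: int
    n_valid: int
    n_unique: int
    n_novel: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def canonicalize_valid(smiles_list: Iterable[str]) -> list[str | None]:
    """Canonical SMILES per entry, None where the string does not parse."""
    out = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s) if s else None
        out.append(Chem.MolToSmiles(mol) if mol is not None else None)
    return out


def sample_report(
    sampled_smiles: Sequence[str],
    training_set: Sequence[str],
    test_actives: Sequence[str],
    model: TargetModel | None = None,
    nn_threshold: float = 0.7,
) -> SampleReport:
    """Score a generated sample against the training set and held-out actives.

    valid%   = parseable strings / sample size
    unique%  = distinct canonical molecules / valid
    novel%   = unique molecules absent from the training set / unique
    active%  = unique molecules the target model predicts active / unique
    recovered actives% = held-out actives regenerated exactly / all held-out
    recovered neighbors = held-out actives with a sampled compound at
                          FCFP6 Tanimoto >= ``nn_threshold``
    """
    if len(sampled_smiles) == 0:
        raise ValueError("empty sample")
    canon = canonicalize_valid(sampled_smiles)
    valid = [c for c in canon if c is not None]
    unique = list(dict.fromkeys(valid))
    train_canon = {c for c in canonicalize_valid(training_set) if c is not None}
    novel = [u for u in unique if u not in train_canon]
    n, nv, nu, nn_ = len(sampled_smiles), len(valid), len(unique), len(novel)

    active_pct = active_pct_novel = 0.0
    if model is not None and nu:
        is_active = model.predict_active(unique)
        active_pct = 100.0 * float(is_active.sum()) / nu
        novel_mask = np.array([u not in train_canon for u in unique])
        if nn_:
            active_pct_novel = 100.0 * float(is_active[novel_mask].sum()) / nn_

    recovered_pct = 0.0
    neighbors = 0
    test_canon = [c for c in canonicalize_valid(test_actives) if c is not None]
    if test_canon:
        unique_set = set(unique)
        recovered = sum(1 for t in test_canon if t in unique_set)
        recovered_pct = 100.0 * recovered / len(test_canon)
        if unique:
            test_fps = fcfp6_rdkit_fps(test_canon)
            sample_fps = fcfp6_rdkit_fps(unique)
            for tfp in test_fps:
                sims = DataStructs.BulkTanimotoSimilarity(tfp, sample_fps)
                if max(sims) >= nn_threshold:
                    neighbors += 1

    return SampleReport(
        n_sampled=n,
        valid_pct=100.0 * nv / n,
        unique_pct=100.0 * nu / nv if nv else 0.0,
        novel_pct=100.0 * nn_ / nu if nu else 0.0,
        active_pct=active_pct,
        active_pct_of_novel=active_pct_novel,
        recovered_actives_pct=recovered_pct,
        recovered_neighbors=neighbors,
        n_valid=nv,
        n_unique=nu,
        n_novel=nn_,
    )


# ---------------------------------------------------------------------------
# Similarity profiles and set overlap

@dataclass
class SimilarityProfile:
    """Nearest-neighbor Tanimoto of each query to a reference set.

    ``bins`` reports the narrative fractions: identical (= 1.0), high
    [0.7, 1.0), medium [0.4, 0.7), and low [0, 0.4). ``n_excluded`` counts
    queries without a scaffold (acyclic) skipped at scaffold level.
    """

    values: list[float]
    level: str
    bins: dict[str, float] = field(default_factory=dict)
    n_excluded: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        n = max(len(v), 1)
        self.bins = {
            "identical": float((v == 1.0).sum()) / n,
            "high": float(((v >= 0.7) & (v < 1.0)).sum()) / n,
            "medium": float(((v >= 0.4) & (v < 0.7)).sum()) / n,
            "low": float((v < 0.4).sum()) / n,
        }


def similarity_profile(
    query_set: Sequence[str],
    reference_set: Sequence[str],
    level: str = "compound",
) -> SimilarityProfile:
    """Maximum FCFP6 Tanimoto of each query against the reference set,
    computed on whole compounds or on their Murcko scaffolds."""
    if not query_set or not reference_set:
        raise ValueError("query and reference sets must be non-empty")
    if level not in ("compound", "scaffold"):
        raise ValueError("level must be 'compound' or 'scaffold'")
    n_excluded = 0
    if level == "scaffold":
        queries, refs = [], []
        for s in query_set:
            scaf = murcko_scaffold(s)
            if scaf:
                queries.append(scaf)
            else:
                n_excluded += 1
        refs = [sc for sc in (murcko_scaffold(s) for s in reference_set) if sc]
        if not refs:
            raise ValueError("reference set has no scaffolds")
    else:
        queries, refs = list(query_set), list(reference_set)
    ref_fps = fcfp6_rdkit_fps(refs)
    values = []
    for q in queries:
        qfp = _FCFP6_GEN.GetFingerprint(_as_mol(q))
        values.append(float(max(DataStructs.BulkTanimotoSimilarity(qfp, ref_fps))))
    return SimilarityProfile(values=values, level=level, n_excluded=n_excluded)


@dataclass
class OverlapCounts:
    """Venn counts for two molecule sets at compound and scaffold level."""

    compounds_only_a: int
    compounds_only_b: int
    compounds_shared: int
    scaffolds_only_a: int
    scaffolds_only_b: int
    scaffolds_shared: int


def overlap_analysis(set_a: Sequence[str], set_b: Sequence[str]) -> OverlapCounts:
    ca = {c for c in canonicalize_valid(set_a) if c is not None}
    cb = {c for c in canonicalize_valid(set_b) if c is not None}
    sa = {murcko_scaffold(c) for c in ca} - {""}
    sb = {murcko_scaffold(c) for c in cb} - {""}
    return OverlapCounts(
        compounds_only_a=len(ca - cb),
        compounds_only_b=len(cb - ca),
        compounds_shared=len(ca & cb),
        scaffolds_only_a=len(sa - sb),
        scaffolds_only_b=len(sb - sa),
        scaffolds_shared=len(sa & sb),
    )


# ---------------------------------------------------------------------------
# Chemical-space PCA on MQN fingerprints

def pca_projection(
    fingerprints: Sequence[np.ndarray] | np.ndarray,
    k: int = 2,
    standardize_features: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k principal-component scores, per-component explained-variance
    percentages, and the (k, n_features) component loadings.

    MQN components have wildly different scales, so features are z-scored by
    default before the PCA (disable with ``standardize_features=False``).
    The sign convention fixes each component's largest-magnitude loading
    positive, so projections are fully deterministic.
    """
    X = np.asarray(fingerprints, dtype=np.float64)
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[0] < k + 1:
        raise ValueError("need at least k+1 samples")
    if standardize_features:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_
    for i in range(k):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    return scores, 100.0 * pca.explained_variance_ratio_, components
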