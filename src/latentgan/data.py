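"""Molecule-set preparation: standardization, filtering, augmentation, splitting.

The corpus conventions follow common practice for SMILES generative models:
molecules are standardized (largest fragment, neutralized, isotope-free,
canonical tautomer, stereo stripped), restricted to the drug-like element set
{H, C, N, O, S, Cl, Br} with at most 50 heavy atoms, and de-duplicated on
canonical SMILES. Chemical series are kept intact across train/test splits so
that evaluation measures generalization to unseen series rather than to
near-duplicates.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

RDLogger.DisableLog("rdApp.*")

DEFAULT_ALLOWED_ELEMENTS = frozenset({"H", "C", "N", "O", "S", "Cl", "Br"})
DEFAULT_MAX_HEAVY = 50


class StandardizationError(ValueError):
    """Raised when a SMILES cannot be standardized.

    ``reason`` is one of ``"parse_error"`` or ``"empty"``.
    """

    def __init__(self, reason: str, smiles: str):
        self.reason = reason
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


@dataclass(frozen=True)
class StandardizationConfig:
    """Knobs for :func:`standardize`.

    ``strip_stereo`` removes stereo descriptors (wedge/CIP and E/Z); the
    default keeps the generative alphabet small. ``canonical_tautomer``
    normalizes to the toolkit's canonical tautomer.
    """

    strip_stereo: bool = True
    canonical_tautomer: bool = True
    neutralize: bool = True
    strip_isotopes: bool = True


@dataclass
class MoleculeRecord:
    """A standardized molecule plus bookkeeping used throughout the package."""

    raw_smiles: str
    canonical_smiles: str
    heavy_atom_count: int
    element_set: frozenset[str]
    activity_label: str | None = None  # "active" | "inactive" | None
    source_id: str | None = None
    series_id: int | None = None

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.canonical_smiles)
        if m is None:  # pragma: no cover - canonical SMILES always parse
            raise StandardizationError("parse_error", self.canonical_smiles)
        return m


# Standardizer objects are stateless; build once.
_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMER = rdMolStandardize.TautomerEnumerator()


def standardize(
    raw_smiles: str,
    config: StandardizationConfig = StandardizationConfig(),
) -> MoleculeRecord:
    """Standardize a raw SMILES into a :class:`MoleculeRecord`.

    Step order: parse -> largest fragment -> charge neutralization ->
    isotope removal -> canonical tautomer -> stereo strip -> canonicalize.

    Raises :class:`StandardizationError` on unparsable input or when nothing
    remains after fragment selection.
    """
    if not raw_smiles or not raw_smiles.strip():
        raise StandardizationError("parse_error", raw_smiles)
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        raise StandardizationError("parse_error", raw_smiles)
    mol = _LARGEST_FRAGMENT.choose(mol)
    if mol is None or mol.GetNumAtoms() == 0:
        raise StandardizationError("empty", raw_smiles)
    if config.neutralize:
        mol = _UNCHARGER.uncharge(mol)
    if config.strip_isotopes:
        for atom in mol.GetAtoms():
            atom.SetIsotope(0)
    if config.canonical_tautomer:
        try:
            mol = _TAUTOMER.Canonicalize(mol)
        except Exception:  # tautomer canonicalization can fail on exotica
            pass
    if config.strip_stereo:
        Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        raise StandardizationError("parse_error", raw_smiles)
    elements = frozenset(a.GetSymbol() for a in mol.GetAtoms()) | {"H"}
    return MoleculeRecord(
        raw_smiles=raw_smiles,
        canonical_smiles=canonical,
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        element_set=elements,
    )


def passes_filters(
    record: MoleculeRecord,
    allowed_elements: Iterable[str] = DEFAULT_ALLOWED_ELEMENTS,
    max_heavy: int = DEFAULT_MAX_HEAVY,
) -> bool:
    """True iff the record's elements are all allowed and it has at most
    ``max_heavy`` heavy atoms."""
    allowed = frozenset(allowed_elements) | {"H"}
    return record.element_set <= allowed and record.heavy_atom_count <= max_heavy


def deduplicate(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Keep the first record per distinct canonical SMILES, preserving order."""
    seen: set[str] = set()
    out: list[MoleculeRecord] = []
    for rec in records:
        if rec.canonical_smiles not in seen:
            seen.add(rec.canonical_smiles)
            out.append(rec)
    return out


def prepare_corpus(
    raw_smiles: Iterable[str],
    config: StandardizationConfig = StandardizationConfig(),
    allowed_elements: Iterable[str] = DEFAULT_ALLOWED_ELEMENTS,
    max_heavy: int = DEFAULT_MAX_HEAVY,
) -> tuple[list[MoleculeRecord], list[tuple[str, str]]]:
    """Standardize + filter + deduplicate a raw corpus.

    Returns (kept records, rejections as (smiles, reason) pairs).
    """
    kept: list[MoleculeRecord] = []
    rejected: list[tuple[str, str]] = []
    for s in raw_smiles:
        try:
            rec = standardize(s, config)
        except StandardizationError as e:
            rejected.append((s, e.reason))
            continue
        if passes_filters(rec, allowed_elements, max_heavy):
            kept.append(rec)
        else:
            rejected.append((s, "filtered"))
    return deduplicate(kept), rejected


def randomize_smiles(
    canonical_smiles: str, n: int, seed: int | np.random.Generator
) -> list[str]:
    """Produce ``n`` randomized (non-canonical) renderings of one molecule.

    Atom output order is permuted before writing, the standard augmentation
    for SMILES sequence models. Entries need not be distinct for small
    molecules. Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise StandardizationError("parse_error", canonical_smiles)
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    n_atoms = mol.GetNumAtoms()
    out = []
    for _ in range(n):
        order = rng.permutation(n_atoms).tolist()
        shuffled = Chem.RenumberAtoms(mol, order)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


@dataclass(frozen=True)
class SmilesPair:
    """Two renderings of the same molecule, the heteroencoder training unit."""

    input_smiles: str
    target_smiles: str
    molecule_id: int  # index into the corpus record list


def make_pairs(
    records: Sequence[MoleculeRecord],
    rng: np.random.Generator,
    scheme: str = "random_random",
) -> list[SmilesPair]:
    """One input/target pair per record.

    ``scheme``: ``random_random`` (default), ``random_canonical`` (randomized
    input, canonical target — the cheapest-to-learn heteroencoder variant),
    ``canonical_random``, or ``canonical_canonical`` (plain autoencoder
    pairs).
    """
    pairs = []
    for i, rec in enumerate(records):
        if scheme == "canonical_canonical":
            inp = tgt = rec.canonical_smiles
        elif scheme == "canonical_random":
            inp = rec.canonical_smiles
            tgt = randomize_smiles(rec.canonical_smiles, 1, rng)[0]
        elif scheme == "random_canonical":
            inp = randomize_smiles(rec.canonical_smiles, 1, rng)[0]
            tgt = rec.canonical_smiles
        elif scheme == "random_random":
            inp, tgt = randomize_smiles(rec.canonical_smiles, 2, rng)
        else:
            raise ValueError(f"unknown pair scheme {scheme!r}")
        pairs.append(SmilesPair(inp, tgt, i))
    return pairs


@dataclass
class SplitResult:
    """Series-aware train/test split: whole clusters on one side."""

    train_ids: list[int]
    test_ids: list[int]
    cluster_assignments: dict[int, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_ids": self.train_ids,
                "test_ids": self.test_ids,
                "cluster_assignments": {
                    str(k): v for k, v in self.cluster_assignments.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitResult":
        d = json.loads(text)
        return cls(
            train_ids=list(d["train_ids"]),
            test_ids=list(d["test_ids"]),
            cluster_assignments={int(k): v for k, v in d["cluster_assignments"].items()},
        )


def series_split(
    records: Sequence[MoleculeRecord],
    similarity_threshold: float = 0.4,
    test_fraction: float = 0.3,
    seed: int = 0,
) -> SplitResult:
    """Cluster molecules into chemical series and split by whole series.

    Series are single-linkage connected components of the graph whose edges
    join molecules with FCFP6 Tanimoto >= ``similarity_threshold``; this
    guarantees no pair at or above the threshold straddles the split. Whole
    clusters are assigned to the test side, in seeded random order, until the
    test fraction is reached.
    """
    from latentgan.scoring import fcfp6_rdkit_fps  # local import, avoids cycle

    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    fps = fcfp6_rdkit_fps([r.canonical_smiles for r in records])
    from rdkit import DataStructs

    rows, cols = [], []
    for i in range(1, n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[:i])
        for j, s in enumerate(sims):
            if s >= similarity_threshold:
                rows.append(i)
                cols.append(j)
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.int8
    )
    n_clusters, labels = connected_components(graph, directed=False)
    assignments = {i: int(labels[i]) for i in range(n)}
    if n_clusters == 1:
        warnings.warn("all molecules fall in one series; entire set on train side")
        return SplitResult(train_ids=list(range(n)), test_ids=[], cluster_assignments=assignments)

    rng = np.random.default_rng(seed)
    cluster_members: dict[int, list[int]] = {}
    for i, lab in assignments.items():
        cluster_members.setdefault(lab, []).append(i)
    order = rng.permutation(sorted(cluster_members)).tolist()
    target = test_fraction * n
    test_ids: list[int] = []
    for lab in order:
        if len(test_ids) >= target:
            break
        test_ids.extend(cluster_members[lab])
    test_set = set(test_ids)
    train_ids = [i for i in range(n) if i not in test_set]
    return SplitResult(train_ids, sorted(test_set), assignments)


# ---------------------------------------------------------------------------
# I/O helpers: .smi (SMILES [id] per line) and CSV (smiles, activity, id)

def read_smi(path: str | Path) -> list[tuple[str, str | None]]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        out.append((parts[0], parts[1].strip() if len(parts) > 1 else None))
    return out


def write_smi(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    lines = []
    for rec in records:
        if rec.source_id:
            lines.append(f"{rec.canonical_smiles} {rec.source_id}")
        else:
            lines.append(rec.canonical_smiles)
    Path(path).write_text("\n".join(lines) + "\n")


def read_labeled_csv(path: str | Path) -> list[tuple[str, str | None, str | None]]:
    """Read CSV with columns smiles, activity (active/inactive), id."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append((row["smiles"], row.get("activity") or None, row.get("id") or None))
    return out


def write_labeled_csv(path: str | Path, records: Sequence[MoleculeRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["smiles", "activity", "id", "series"])
        for rec in records:
            w.writerow(
                [rec.canonical_smiles, rec.activity_label or "", rec.source_id or "",
                 rec.series_id if rec.series_id is not None else ""]
            )
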