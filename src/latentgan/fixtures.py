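"""Synthetic drug-like molecule libraries with planted chemical series.

Generates desk-scale corpora with the statistical structure the generative
workflow assumes: valid drug-like SMILES over the {C, N, O, S, Cl, Br}
element set, at most 50 heavy atoms, organized into chemical series that
share a Murcko scaffold, with activity labels planted on whole series so an
FCFP6 classifier can learn them and a series-aware split is meaningful.

Molecules are built by decorating a fixed pool of mono-/bi-cyclic cores with
short acyclic substituents, so every series keeps its scaffold and decode
sequences stay short.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from latentgan.data import (
    DEFAULT_ALLOWED_ELEMENTS,
    MoleculeRecord,
    passes_filters,
    standardize,
)
from latentgan.scoring import murcko_scaffold

# Versioned scaffold pool: valid mono- and bi-cyclic cores over the allowed
# element set, each with a distinct Murcko scaffold.
SCAFFOLD_POOL: tuple[str, ...] = (
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1cnccn1",            # pyrazine
    "c1ccnnc1",            # pyridazine
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "c1cc[nH]c1",          # pyrrole
    "c1c[nH]cn1",          # imidazole
    "c1cc[nH]n1",          # pyrazole
    "c1ocnc1",             # oxazole
    "c1scnc1",             # thiazole
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2cnccc2c1",      # isoquinoline
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc2occc2c1",       # benzofuran
    "c1ccc2sccc2c1",       # benzothiophene
    "c1ccc2[nH]cnc2c1",    # benzimidazole
    "c1ccc2nccnc2c1",      # quinoxaline
    "C1CCCCC1",            # cyclohexane
    "C1CCCC1",             # cyclopentane
    "C1CCNCC1",            # piperidine
    "C1CNCCN1",            # piperazine
    "C1COCCN1",            # morpholine
    "C1CCOC1",             # tetrahydrofuran
    "C1CCOCC1",            # tetrahydropyran
    "C1CCNC1",             # pyrrolidine
    "C1CSCCN1",            # thiomorpholine
    "c1ccc(-c2ccccc2)cc1", # biphenyl
    "c1ccc(N2CCNCC2)cc1",  # phenylpiperazine
)

# Short acyclic substituents; none adds a ring, so the series scaffold is
# preserved under decoration.
SUBSTITUENT_POOL: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CO", "CCO", "OC", "OCC", "N", "NC",
    "N(C)C", "Cl", "Br", "C#N", "C(=O)C", "C(=O)OC", "C(=O)N", "SC", "CS",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic library."""

    n_molecules: int = 500
    allowed_elements: frozenset[str] = DEFAULT_ALLOWED_ELEMENTS
    max_heavy: int = 50
    n_series: int = 10
    actives_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.actives_fraction < 1:
            raise ValueError("actives_fraction must be in (0, 1)")
        if self.n_series < 2:
            raise ValueError("n_series must be >= 2")
        if self.n_series > len(SCAFFOLD_POOL):
            raise ValueError(f"at most {len(SCAFFOLD_POOL)} series supported")
        if self.n_molecules < self.n_series:
            raise ValueError("need at least one molecule per series")


def _attach(mol: Chem.Mol, atom_idx: int, frag_smiles: str) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(frag_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(atom_idx, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _decorate(core: Chem.Mol, rng: np.random.Generator, n_subs: int) -> Chem.Mol | None:
    mol = Chem.Mol(core)
    for _ in range(n_subs):
        candidates = [
            a.GetIdx() for a in mol.GetAtoms()
            if a.GetTotalNumHs() >= 1 and a.GetSymbol() in ("C", "N")
        ]
        if not candidates:
            return None
        idx = int(rng.choice(candidates))
        frag = str(rng.choice(SUBSTITUENT_POOL))
        nxt = _attach(mol, idx, frag)
        if nxt is None:
            return None
        mol = nxt
    return mol


def generate_library(spec: FixtureSpec) -> list[MoleculeRecord]:
    """Build a deduplicated, standardized, filter-closed library.

    Deterministic under ``spec.seed``. Each record carries its series id and
    a source id. Raises if the diversity budget cannot produce
    ``n_molecules`` distinct molecules within a bounded number of attempts.
    """
    rng = np.random.default_rng(spec.seed)
    core_idx = rng.choice(len(SCAFFOLD_POOL), size=spec.n_series, replace=False)
    cores = []
    for ci in core_idx:
        core = Chem.MolFromSmiles(SCAFFOLD_POOL[ci])
        cores.append((core, murcko_scaffold(core)))

    per_series = [spec.n_molecules // spec.n_series] * spec.n_series
    for i in range(spec.n_molecules % spec.n_series):
        per_series[i] += 1

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    max_attempts = 200 * spec.n_molecules
    attempts = 0
    for sid, ((core, core_scaffold), target) in enumerate(zip(cores, per_series)):
        made = 0
        while made < target:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"could not generate {spec.n_molecules} distinct molecules "
                    f"(series {sid} stuck after {attempts} attempts)"
                )
            n_subs = int(rng.integers(1, 4))
            mol = _decorate(core, rng, n_subs)
            if mol is None:
                continue
            try:
                rec = standardize(Chem.MolToSmiles(mol))
            except Exception:
                continue
            if not passes_filters(rec, spec.allowed_elements, spec.max_heavy):
                continue
            if rec.canonical_smiles in seen:
                continue
            # tautomer standardization may rearrange the core; keep the
            # series scaffold-pure
            if murcko_scaffold(rec.canonical_smiles) != core_scaffold:
                continue
            seen.add(rec.canonical_smiles)
            rec.series_id = sid
            rec.source_id = f"S{sid:02d}_M{made:04d}"
            records.append(rec)
            made += 1
    return records


def plant_actives(
    records: Sequence[MoleculeRecord], spec: FixtureSpec
) -> list[MoleculeRecord]:
    """Label whole series active until ~``actives_fraction`` of molecules is
    reached; the rest are inactive. Activity is therefore scaffold-correlated."""
    rng = np.random.default_rng(spec.seed + 1)
    series_ids = sorted({r.series_id for r in records})
    order = rng.permutation(series_ids).tolist()
    counts = {sid: sum(1 for r in records if r.series_id == sid) for sid in series_ids}
    target = spec.actives_fraction * len(records)
    active_series: set[int] = set()
    n_active = 0
    for sid in order:
        if n_active >= target:
            break
        active_series.add(sid)
        n_active += counts[sid]
    if not active_series or len(active_series) == len(series_ids):
        warnings.warn("actives_fraction incompatible with series granularity; "
                      "using nearest achievable labeling")
        active_series = {order[0]}
    out = []
    for r in records:
        label = "active" if r.series_id in active_series else "inactive"
        out.append(
            MoleculeRecord(
                raw_smiles=r.raw_smiles,
                canonical_smiles=r.canonical_smiles,
                heavy_atom_count=r.heavy_atom_count,
                element_set=r.element_set,
                activity_label=label,
                source_id=r.source_id,
                series_id=r.series_id,
            )
        )
    return out
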