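"""Deterministic generator of valid small molecules and derived toy tasks.

Molecules are grown as random trees of heavy atoms with valence bookkeeping
(elements C, N, O, S, F, Cl, Br), optionally closed into rings, sprinkled
with double bonds, and six-membered carbon cycles are aromatized when RDKit
accepts the aromatic form. Every draw is standardized and filtered by
``chem_prep``; invalid or duplicate draws are resampled, so the resulting
corpus consists of unique canonical structures that all pass the corpus
filters. Everything is reproducible from the spec seed.

Also builds toy QSAR tasks (labels computed from structure, never stored
approximations) and virtual-screening fixtures with a controllable
scaffold signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from . import chem_prep
from .chem_prep import FilterPolicy, MoleculeRecord

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}

_DEFAULT_WEIGHTS = {
    "C": 0.70, "N": 0.12, "O": 0.12, "S": 0.03, "F": 0.01, "Cl": 0.01,
    "Br": 0.01,
}


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a synthetic corpus.

    Heavy-atom range (4, 11) keeps every draw inside the corpus filter window
    while spanning fragment- to small-drug-fragment-sized molecules; element
    weights approximate the element abundance of organic screening compounds.
    """

    n_molecules: int = 1000
    heavy_atom_range: tuple[int, int] = (4, 11)
    element_weights: Optional[dict] = None
    ring_prob: float = 0.35
    branch_prob: float = 0.3
    double_bond_prob: float = 0.25
    aromatize_prob: float = 0.5
    aromatic_seed_prob: float = 0.2
    seed: int = 0

    def weights(self) -> dict:
        w = dict(self.element_weights or _DEFAULT_WEIGHTS)
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}


def _grow_tree(rng: np.random.Generator, n_heavy: int, weights: dict,
               branch_prob: float, seed_mol: Chem.RWMol | None = None):
    """Grow a random heavy-atom tree; returns (RWMol, free-valence list)."""
    elements = list(weights)
    probs = np.array([weights[e] for e in elements])
    if seed_mol is None:
        mol = Chem.RWMol()
        first = str(rng.choice(elements, p=probs))
        mol.AddAtom(Chem.Atom(first))
        free = [_VALENCE[first]]
        start = 1
    else:
        mol = Chem.RWMol(seed_mol)
        free = [a.GetTotalNumHs() for a in mol.GetAtoms()]
        start = 0
    for _ in range(start, n_heavy):
        open_atoms = [i for i, f in enumerate(free) if f >= 1]
        if not open_atoms:
            break
        # prefer recent atoms (chains) unless branching
        if rng.random() < branch_prob:
            parent = int(open_atoms[rng.integers(len(open_atoms))])
        else:
            parent = int(open_atoms[-1])
        sym = str(rng.choice(elements, p=probs))
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        free.append(_VALENCE[sym] - 1)
        free[parent] -= 1
    return mol, free


def _close_ring(rng, mol: Chem.RWMol, free: list[int]) -> None:
    """Try to close one ring of size 4-7 between atoms with free valence."""
    n = mol.GetNumAtoms()
    if n < 4:
        return
    dmat = Chem.GetDistanceMatrix(mol, force=True)
    candidates = [
        (i, j)
        for i in range(n) for j in range(i + 1, n)
        if free[i] >= 1 and free[j] >= 1 and 3 <= dmat[i, j] <= 6
        and mol.GetBondBetweenAtoms(i, j) is None
    ]
    if not candidates:
        return
    i, j = candidates[rng.integers(len(candidates))]
    mol.AddBond(int(i), int(j), Chem.BondType.SINGLE)
    free[i] -= 1
    free[j] -= 1


def _add_double_bonds(rng, mol: Chem.RWMol, free: list[int]) -> None:
    bonds = [b for b in mol.GetBonds()
             if free[b.GetBeginAtomIdx()] >= 1 and free[b.GetEndAtomIdx()] >= 1
             and b.GetBondType() == Chem.BondType.SINGLE]
    if not bonds:
        return
    b = bonds[rng.integers(len(bonds))]
    b.SetBondType(Chem.BondType.DOUBLE)
    free[b.GetBeginAtomIdx()] -= 1
    free[b.GetEndAtomIdx()] -= 1


def _try_aromatize(mol: Chem.Mol, rng) -> Chem.Mol:
    """Aromatize one all-carbon six-ring if RDKit accepts the aromatic form."""
    ri = mol.GetRingInfo()
    six_c = [r for r in ri.AtomRings() if len(r) == 6 and all(
        mol.GetAtomWithIdx(a).GetSymbol() == "C"
        and mol.GetAtomWithIdx(a).GetTotalNumHs() >= 1
        for a in r)]
    if not six_c:
        return mol
    ring = six_c[rng.integers(len(six_c))]
    trial = Chem.RWMol(mol)
    for a in ring:
        trial.GetAtomWithIdx(a).SetIsAromatic(True)
        trial.GetAtomWithIdx(a).SetNumExplicitHs(0)
        trial.GetAtomWithIdx(a).SetNoImplicit(False)
    ring_set = set(ring)
    for b in trial.GetBonds():
        if b.GetBeginAtomIdx() in ring_set and b.GetEndAtomIdx() in ring_set:
            b.SetBondType(Chem.BondType.AROMATIC)
            b.SetIsAromatic(True)
    try:
        out = trial.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return mol


def _sample_smiles(rng: np.random.Generator, spec: CorpusSpec,
                   seed_mol: Chem.Mol | None = None,
                   n_extra: tuple[int, int] | None = None) -> Optional[str]:
    """One raw molecule draw; None when the draw fails sanitization."""
    weights = spec.weights()
    lo, hi = spec.heavy_atom_range
    if seed_mol is not None and n_extra is not None:
        n_heavy = int(rng.integers(n_extra[0], n_extra[1] + 1))
    else:
        n_heavy = int(rng.integers(lo, hi + 1))
        # a fraction of draws decorate a benzene core: organic screening
        # collections are aryl-rich and this exercises aromatic tokens
        if n_heavy >= 7 and rng.random() < spec.aromatic_seed_prob:
            seed_mol = Chem.MolFromSmiles("c1ccccc1")
            n_heavy -= 6
            n_extra = None
    mol, free = _grow_tree(rng, n_heavy, weights, spec.branch_prob, seed_mol)
    try:
        mol.UpdatePropertyCache()
    except Exception:
        return None
    if seed_mol is None:
        if rng.random() < spec.ring_prob:
            _close_ring(rng, mol, free)
        if rng.random() < spec.double_bond_prob:
            _add_double_bonds(rng, mol, free)
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if seed_mol is None and rng.random() < spec.aromatize_prob:
        out = _try_aromatize(out, rng)
    return Chem.MolToSmiles(out)


def generate(spec: CorpusSpec,
             policy: FilterPolicy = FilterPolicy()) -> list[MoleculeRecord]:
    """Generate exactly ``spec.n_molecules`` unique, filter-passing records."""
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    budget = 60 * spec.n_molecules + 1000
    attempts = 0
    while len(records) < spec.n_molecules:
        attempts += 1
        if attempts > budget:
            raise RuntimeError(
                f"retry budget exhausted: {len(records)}/{spec.n_molecules} "
                "unique molecules generated")
        raw = _sample_smiles(rng, spec)
        if raw is None:
            continue
        rec = chem_prep.standardize(raw, id=f"syn{len(records)}")
        if isinstance(rec, chem_prep.Rejection):
            continue
        lo, hi = spec.heavy_atom_range
        n_heavy = rec.mol().GetNumHeavyAtoms()
        if not lo <= n_heavy <= hi:
            continue
        ok, _ = chem_prep.passes_filters(rec, policy)
        if not ok or rec.canonical_smiles in seen:
            continue
        seen.add(rec.canonical_smiles)
        records.append(rec)
    return records


@dataclass
class QsarTask:
    """A toy QSAR dataset: molecules, labels and the requested split kind."""

    name: str
    kind: str                      # "classification" | "regression"
    molecules: list[MoleculeRecord]
    labels: np.ndarray = field(repr=False)
    split_kind: str = "random_cv"

    def __post_init__(self):
        if len(self.molecules) != len(self.labels):
            raise ValueError("labels must align 1:1 with molecules")
        if self.kind == "classification":
            if not set(np.unique(self.labels)) <= {0.0, 1.0}:
                raise ValueError("classification labels must be 0/1")


def _target_value(rec: MoleculeRecord, target: str) -> float:
    if target == "tpsa":
        return float(rec.properties[8])
    if target == "logp_threshold":
        return float(rec.properties[0])
    if target == "ring_count":
        return float(rdMolDescriptors.CalcNumRings(rec.mol()))
    raise ValueError(f"unknown target {target!r}")


def make_toy_task(corpus: Sequence[MoleculeRecord], kind: str, target: str,
                  seed: int = 0, split_kind: str = "random_cv") -> QsarTask:
    """Build a QSAR task whose labels are computed from structure."""
    if len(corpus) < 50:
        raise ValueError("corpus too small for a toy task")
    values = np.array([_target_value(r, target) for r in corpus])
    if values.std() < 1e-12:
        raise ValueError("degenerate label variance")
    if kind == "regression":
        labels = values
    elif kind == "classification":
        labels = (values > np.median(values)).astype(float)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return QsarTask(name=f"{target}_{kind}", kind=kind,
                    molecules=list(corpus), labels=labels,
                    split_kind=split_kind)


@dataclass
class VsTarget:
    """One virtual-screening target: active and decoy molecule records."""

    name: str
    actives: list[MoleculeRecord]
    decoys: list[MoleculeRecord]
    n_queries: int = 5
    n_reps: int = 50


def make_vs_fixture(corpus: Sequence[MoleculeRecord], n_targets: int,
                    n_actives: int, n_decoys: int, signal: float,
                    seed: int = 0) -> list[VsTarget]:
    """Virtual-screening fixtures with a tunable scaffold signal.

    With probability ``signal`` an active is grown from the target's shared
    scaffold (a 6-8 heavy-atom random molecule) by decorating it with 1-4
    extra atoms; otherwise it is an exchangeable random corpus draw, so
    signal=0 yields a null fixture and signal=1 scaffold-pure actives.
    """
    if not 0.0 <= signal <= 1.0:
        raise ValueError("signal must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pool = list(corpus)
    if len(pool) < n_actives + n_decoys:
        raise ValueError("corpus too small for the requested fixture")
    scaffold_spec = CorpusSpec(heavy_atom_range=(6, 8), ring_prob=0.6,
                               seed=seed)
    targets: list[VsTarget] = []
    for t in range(n_targets):
        scaffold = None
        for _ in range(200):
            raw = _sample_smiles(rng, scaffold_spec)
            if raw is None:
                continue
            m = Chem.MolFromSmiles(raw)
            if m is not None and m.GetNumHeavyAtoms() >= 6:
                scaffold = m
                break
        if scaffold is None:
            raise RuntimeError("scaffold yield too low")
        draw_idx = rng.permutation(len(pool))
        cursor = 0
        actives: list[MoleculeRecord] = []
        seen: set[str] = set()
        guard = 0
        while len(actives) < n_actives:
            guard += 1
            if guard > 200 * n_actives:
                raise RuntimeError("scaffold yield too low")
            if rng.random() < signal:
                raw = _sample_smiles(rng, scaffold_spec, seed_mol=scaffold,
                                     n_extra=(1, 4))
                if raw is None:
                    continue
                rec = chem_prep.standardize(raw, id=f"t{t}_a{len(actives)}")
                if isinstance(rec, chem_prep.Rejection):
                    continue
            else:
                rec = pool[draw_idx[cursor]]
                cursor += 1
            if rec.canonical_smiles in seen:
                continue
            seen.add(rec.canonical_smiles)
            actives.append(rec)
        decoys = []
        while len(decoys) < n_decoys and cursor < len(pool):
            rec = pool[draw_idx[cursor]]
            cursor += 1
            if rec.canonical_smiles in seen:
                continue
            seen.add(rec.canonical_smiles)
            decoys.append(rec)
        if len(decoys) < n_decoys:
            raise ValueError("corpus too small for the requested decoy count")
        targets.append(VsTarget(name=f"target{t}", actives=actives,
                                decoys=decoys))
    return targets
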