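"""Molecule standardization, filtering and auxiliary property computation.

All elementary chemistry (SMILES parsing, canonical atom ordering, InChI
generation, property primitives) is delegated to RDKit; this module owns the
standardization pipeline (stereo removal, salt stripping, largest fragment),
the acceptance filters and the fixed nine-property vector used as the
auxiliary prediction target of the translation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

#: Order of the auxiliary property vector. Charges are in elementary-charge
#: units, TPSA in Angstrom^2, counts dimensionless.
PROPERTY_NAMES = (
    "logp",
    "max_partial_charge",
    "min_partial_charge",
    "valence_electrons",
    "hbd",
    "hba",
    "balaban_j",
    "molar_refractivity",
    "tpsa",
)

#: Default element whitelist defining "organic" molecules (a carbon atom is
#: additionally required; hydrogens are always allowed).
ORGANIC_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

# Common counter-ions removed before the largest-fragment rule.
_SALT_SMARTS = (
    "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Zn+2]", "[NH4+]",
    "[Cl-]", "[Br-]", "[I-]", "[F-]", "[OH-]",
)


@dataclass(frozen=True)
class FilterPolicy:
    """Acceptance window for the pretraining corpus.

    Molecular-weight and logP bounds are inclusive; the heavy-atom bound is
    strict (a molecule must have *more than* ``min_heavy_atoms_exclusive``
    heavy atoms).
    """

    mw_min: float = 12.0
    mw_max: float = 600.0
    min_heavy_atoms_exclusive: int = 3
    logp_min: float = -7.0
    logp_max: float = 5.0
    allowed_elements: frozenset = ORGANIC_ELEMENTS

    def __post_init__(self):
        if not self.mw_min < self.mw_max:
            raise ValueError("mw_min must be < mw_max")
        if not self.logp_min < self.logp_max:
            raise ValueError("logp_min must be < logp_max")


@dataclass(frozen=True)
class MoleculeRecord:
    """A standardized molecule: canonical SMILES, InChI and 9 properties."""

    id: str
    canonical_smiles: str
    inchi: str
    properties: np.ndarray = field(repr=False)

    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass(frozen=True)
class Rejection:
    """Why a raw input was dropped from the corpus."""

    id: str
    raw: str
    reason: str


def canonicalize(smiles: str) -> Optional[str]:
    """Canonical SMILES of ``smiles``, or None if it does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def _strip_salts_largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    salt_smiles = {Chem.CanonSmiles(s) for s in _SALT_SMARTS}
    keep = [f for f in frags if Chem.MolToSmiles(f) not in salt_smiles]
    if not keep:
        keep = list(frags)
    # largest fragment by heavy atoms; ties by MW then canonical SMILES
    def key(f: Chem.Mol):
        return (
            f.GetNumHeavyAtoms(),
            Descriptors.MolWt(f),
            # lexicographically smallest wins on exact ties -> negate by sort
        )
    keep.sort(key=lambda f: (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f),
                             Chem.MolToSmiles(f)))
    return keep[0]


def compute_properties(mol: Chem.Mol) -> Optional[np.ndarray]:
    """The fixed 9-vector of auxiliary molecular properties.

    Order: logP, max partial charge, min partial charge, valence-electron
    count, H-bond donors, H-bond acceptors, Balaban J, molar refractivity,
    TPSA. Returns None when Gasteiger charges cannot be computed or any value
    is non-finite.
    """
    try:
        max_q = Descriptors.MaxPartialCharge(mol)
        min_q = Descriptors.MinPartialCharge(mol)
    except Exception:
        return None
    props = np.array(
        [
            Crippen.MolLogP(mol),
            max_q,
            min_q,
            Descriptors.NumValenceElectrons(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            rdMolDescriptors.CalcNumHBA(mol),
            GraphDescriptors.BalabanJ(mol),
            Crippen.MolMR(mol),
            rdMolDescriptors.CalcTPSA(mol),
        ],
        dtype=np.float64,
    )
    if not np.all(np.isfinite(props)):
        return None
    return props


def standardize(raw_smiles: str, id: str = "") -> MoleculeRecord | Rejection:
    """Standardize a raw SMILES into a :class:`MoleculeRecord`.

    Stereochemistry is removed, salts stripped, only the largest fragment
    (by heavy-atom count) kept; canonical SMILES, InChI and the nine
    properties are computed. Unparseable or unprocessable input yields a
    :class:`Rejection` with a reason code, never an exception.
    """
    if not raw_smiles:
        raise ValueError("raw_smiles must be non-empty")
    mol = Chem.MolFromSmiles(raw_smiles)
    if mol is None:
        return Rejection(id, raw_smiles, "parse_error")
    Chem.RemoveStereochemistry(mol)
    mol = _strip_salts_largest_fragment(mol)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return Rejection(id, raw_smiles, "sanitize_error")
    canonical = Chem.MolToSmiles(mol)
    # re-parse so properties are computed on the canonical form
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:
        return Rejection(id, raw_smiles, "parse_error")
    inchi = Chem.MolToInchi(mol)
    if not inchi:
        return Rejection(id, raw_smiles, "inchi_error")
    props = compute_properties(mol)
    if props is None:
        return Rejection(id, raw_smiles, "property_error")
    return MoleculeRecord(id=id, canonical_smiles=canonical, inchi=inchi,
                          properties=props)


def passes_filters(
    record: MoleculeRecord, policy: FilterPolicy = FilterPolicy()
) -> tuple[bool, Optional[str]]:
    """Check the corpus acceptance criteria; reports the first failure.

    Criteria, in order: organic (>=1 C, whitelist elements), molecular weight
    in [mw_min, mw_max], heavy atoms strictly greater than the bound, logP in
    [logp_min, logp_max].
    """
    mol = record.mol()
    symbols = {a.GetSymbol() for a in mol.GetAtoms()}
    if "C" not in symbols or not symbols <= policy.allowed_elements:
        return False, "not_organic"
    mw = Descriptors.MolWt(mol)
    if not policy.mw_min <= mw <= policy.mw_max:
        return False, "molecular_weight"
    if not mol.GetNumHeavyAtoms() > policy.min_heavy_atoms_exclusive:
        return False, "heavy_atoms"
    logp = record.properties[PROPERTY_NAMES.index("logp")]
    if not policy.logp_min <= logp <= policy.logp_max:
        return False, "logp"
    return True, None


def enumerate_smiles(mol_or_record, rng: np.random.Generator) -> str:
    """A random SMILES variant of the molecule (enumeration augmentation).

    The atom order is permuted uniformly at random and a non-canonical SMILES
    is written from the permuted graph, so the returned string is a valid
    alternative spelling of the same molecule.
    """
    if isinstance(mol_or_record, MoleculeRecord):
        mol = mol_or_record.mol()
    else:
        mol = mol_or_record
    n = mol.GetNumAtoms()
    if n == 0:
        raise ValueError("molecule has no atoms")
    perm = rng.permutation(n).tolist()
    shuffled = Chem.RenumberAtoms(mol, perm)
    return Chem.MolToSmiles(shuffled, canonical=False)


def preprocess(
    raw_smiles: Iterable[str],
    policy: FilterPolicy = FilterPolicy(),
    ids: Optional[Iterable[str]] = None,
) -> tuple[list[MoleculeRecord], list[Rejection]]:
    """Standardize and filter a list of raw SMILES.

    Returns (accepted records, rejections); every input lands in exactly one
    of the two lists, filter failures carrying their first failing criterion
    as the rejection reason.
    """
    accepted: list[MoleculeRecord] = []
    rejected: list[Rejection] = []
    raws = list(raw_smiles)
    id_list = list(ids) if ids is not None else [str(i) for i in range(len(raws))]
    for mid, raw in zip(id_list, raws):
        rec = standardize(raw, id=mid)
        if isinstance(rec, Rejection):
            rejected.append(rec)
            continue
        ok, reason = passes_filters(rec, policy)
        if ok:
            accepted.append(rec)
        else:
            rejected.append(Rejection(mid, raw, reason))
    return accepted, rejected
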