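"""Structure-derived featurization of ionic liquids.

An ionic liquid is represented by a (possibly multi-component,
dot-separated) SMILES string covering both the cation and the anion.  Each
record is mapped to a 310-dimensional feature vector: ten whole-molecule
descriptors followed by a 300-dimensional circular-substructure embedding.
The descriptor block, in fixed order, is

    1. number of atoms (hydrogens included)
    2. number of heavy atoms
    3. number of carbon atoms
    4. number of oxygen atoms
    5. number of nitrogen atoms
    6. number of chlorine atoms
    7. topological polar surface area (TPSA, Angstrom^2)
    8. molecular weight (g/mol, average atomic masses)
    9. number of valence electrons
    10. number of heteroatoms (heavy atoms that are not carbon)

The embedding block is the sum over the molecule's substructure "sentence"
(Morgan atom-environment identifiers at radii 0 and 1, atom-major order) of
per-identifier vectors from an :class:`~iltox.embedding.EmbeddingModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

__all__ = [
    "SmilesParseError",
    "MoleculeRecord",
    "DescriptorVector",
    "DESCRIPTOR_NAMES",
    "N_DESCRIPTORS",
    "EMBEDDING_DIM",
    "N_FEATURES",
    "parse_molecule",
    "compute_descriptors",
    "mol_to_sentence",
    "featurize",
]

RDLogger.DisableLog("rdApp.error")

#: Names of the ten whole-molecule descriptors, in feature-vector order.
DESCRIPTOR_NAMES = (
    "n_atoms_total",
    "n_heavy",
    "n_carbon",
    "n_oxygen",
    "n_nitrogen",
    "n_chlorine",
    "tpsa",
    "mol_weight",
    "n_valence_electrons",
    "n_heteroatoms",
)

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)
EMBEDDING_DIM = 300
N_FEATURES = N_DESCRIPTORS + EMBEDDING_DIM


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str, detail: str = ""):
        self.smiles = smiles
        msg = f"could not parse SMILES {smiles!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


@dataclass(frozen=True)
class MoleculeRecord:
    """A parsed, canonicalized molecule with optional measured logEC50.

    Multi-component (dot-separated cation.anion) inputs stay one record:
    descriptors and substructure sentences are computed over all components
    together, matching one feature vector per ionic liquid.
    """

    source_smiles: str
    canonical_smiles: str
    label: Optional[float] = None

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_smiles)

    def with_label(self, label: Optional[float]) -> "MoleculeRecord":
        return MoleculeRecord(self.source_smiles, self.canonical_smiles, label)


@dataclass(frozen=True)
class DescriptorVector:
    """The ten whole-molecule descriptors, in fixed feature order."""

    n_atoms_total: int
    n_heavy: int
    n_carbon: int
    n_oxygen: int
    n_nitrogen: int
    n_chlorine: int
    tpsa: float
    mol_weight: float
    n_valence_electrons: int
    n_heteroatoms: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in DESCRIPTOR_NAMES],
                        dtype=float)


def parse_molecule(smiles: str, label: Optional[float] = None) -> MoleculeRecord:
    """Parse a SMILES string into a canonical :class:`MoleculeRecord`.

    Raises :class:`SmilesParseError` naming the offending string if RDKit
    cannot sanitize it.  Dot-separated multi-component strings are accepted
    as a single record.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise SmilesParseError(str(smiles), "empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return MoleculeRecord(source_smiles=smiles,
                          canonical_smiles=Chem.MolToSmiles(mol),
                          label=label)


def compute_descriptors(mol: MoleculeRecord | Chem.Mol) -> DescriptorVector:
    """Compute the ten-descriptor block for one molecule.

    The atom count includes implicit hydrogens; heteroatoms are heavy atoms
    other than carbon.
    """
    m = mol.mol if isinstance(mol, MoleculeRecord) else mol
    if m is None or m.GetNumAtoms() == 0:
        raise ValueError("cannot compute descriptors for an empty molecule")
    counts = {"C": 0, "O": 0, "N": 0, "Cl": 0}
    n_h = 0
    for atom in m.GetAtoms():
        sym = atom.GetSymbol()
        if sym in counts:
            counts[sym] += 1
        n_h += atom.GetTotalNumHs()
    n_heavy = m.GetNumAtoms()
    return DescriptorVector(
        n_atoms_total=n_heavy + n_h,
        n_heavy=n_heavy,
        n_carbon=counts["C"],
        n_oxygen=counts["O"],
        n_nitrogen=counts["N"],
        n_chlorine=counts["Cl"],
        tpsa=float(rdMolDescriptors.CalcTPSA(m)),
        mol_weight=float(Descriptors.MolWt(m)),
        n_valence_electrons=int(Descriptors.NumValenceElectrons(m)),
        n_heteroatoms=int(rdMolDescriptors.CalcNumHeteroatoms(m)),
    )


def mol_to_sentence(mol: MoleculeRecord | Chem.Mol,
                    radii: Sequence[int] = (0, 1)) -> list[int]:
    """List the Morgan atom-environment identifiers of a molecule.

    One identifier per heavy atom per radius, atom-major order (all radii
    of atom 0, then atom 1, ...), so the sentence length is
    ``len(radii) * n_heavy``.  Atoms with no neighbours have no radius-1
    environment in RDKit; their radius-0 identifier is reused so the length
    invariant holds for single-atom ions such as ``[Cl-]``.
    """
    m = mol.mol if isinstance(mol, MoleculeRecord) else mol
    if m is None or m.GetNumAtoms() == 0:
        raise ValueError("cannot build a sentence for an empty molecule")
    radii = sorted(radii)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=max(radii))
    out = rdFingerprintGenerator.AdditionalOutput()
    out.AllocateBitInfoMap()
    gen.GetSparseCountFingerprint(m, additionalOutput=out)
    ident: dict[tuple[int, int], int] = {}
    for bit_id, hits in out.GetBitInfoMap().items():
        for atom_idx, radius in hits:
            ident[(atom_idx, radius)] = bit_id
    sentence: list[int] = []
    for atom_idx in range(m.GetNumAtoms()):
        for r in radii:
            key = (atom_idx, r)
            if key not in ident:
                key = (atom_idx, 0)  # isolated atom: no larger environment
            sentence.append(ident[key])
    return sentence


def featurize(mol: MoleculeRecord, model) -> np.ndarray:
    """Concatenate descriptors and substructure embedding into one vector.

    Parameters
    ----------
    mol : MoleculeRecord
    model : iltox.embedding.EmbeddingModel
        Provides 300-dimensional vectors for substructure identifiers.

    Returns
    -------
    numpy.ndarray of shape (310,)
    """
    desc = compute_descriptors(mol).as_array()
    emb = model.embed_sentence(mol_to_sentence(mol))
    vec = np.concatenate([desc, emb])
    if vec.shape != (N_FEATURES,):
        raise ValueError(
            f"feature vector has length {vec.shape[0]}, expected {N_FEATURES}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite values")
    return vec


def featurize_records(records: Sequence[MoleculeRecord], model) -> np.ndarray:
    """Stack :func:`featurize` over records into an (n, 310) matrix."""
    return np.vstack([featurize(r, model) for r in records])
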