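"""Drug structure parsing and molecular-graph featurization.

Small molecules enter as SMILES strings or SDF (V2000) records and leave as
attributed graphs: heavy atoms are nodes, chemical bonds are edges, and every
node carries a 9-slot integer feature vector (atom-count context, chirality,
degree, formal charge, attached hydrogens, radical electrons, hybridization,
aromaticity, ring membership). All categorical slots index the frozen
dictionaries in :mod:`dtafusion.constants`, with a reserved "unknown" code for
out-of-dictionary values, so featurization is stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from . import constants as C

RDLogger.DisableLog("rdApp.*")


class MoleculeParseError(ValueError):
    """Raised when a drug record cannot be parsed into a valid molecule."""

    def __init__(self, source_id, message):
        self.source_id = source_id
        super().__init__(f"{source_id}: {message}")


@dataclass(frozen=True)
class AtomRecord:
    element: str
    formal_charge: int
    hybridization: str
    aromatic: bool
    in_ring: bool
    num_h: int
    radical_electrons: int
    chirality: str  # one of constants.CHIRALITY


@dataclass(frozen=True)
class BondRecord:
    bond_type: str
    stereo: str
    conjugated: bool


@dataclass
class Molecule:
    """Heavy-atom molecular graph in the parser's canonical input order."""

    atoms: list
    bonds: list  # (i, j, BondRecord), i < j, undirected, no duplicates
    source_id: str = ""

    @property
    def n_atoms(self):
        return len(self.atoms)


@dataclass
class DrugGraph:
    node_features: np.ndarray  # (N, 9) int
    adjacency: np.ndarray      # (N, N) 0/1 symmetric, zero diagonal
    edges: list                # (i, j, bond feature vector (3,) int)
    degrees: np.ndarray        # (N,) int

    @property
    def n_nodes(self):
        return self.node_features.shape[0]


def _chirality_label(atom):
    try:
        return atom.GetPropsAsDict().get("_CIPCode", "none")  # "R" or "S"
    except Exception:
        return "none"


def _from_rdkit(mol, source_id):
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(AtomRecord(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            hybridization=str(a.GetHybridization()),
            aromatic=a.GetIsAromatic(),
            in_ring=a.IsInRing(),
            num_h=a.GetTotalNumHs(),
            radical_electrons=a.GetNumRadicalElectrons(),
            chirality=_chirality_label(a),
        ))
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i > j:
            i, j = j, i
        bonds.append((i, j, BondRecord(
            bond_type=str(b.GetBondType()),
            stereo=str(b.GetStereo()),
            conjugated=b.GetIsConjugated(),
        )))
    return Molecule(atoms=atoms, bonds=bonds, source_id=source_id)


def parse_molecule(source, source_id=""):
    """Parse a SMILES string or an SDF V2000 record into a :class:`Molecule`.

    Hydrogens stay implicit: graph nodes are heavy atoms only, and the
    attached-hydrogen count is recorded per atom. Node order is RDKit's
    canonical input order and is the node order of every downstream graph.
    """
    if not isinstance(source, str) or not source.strip():
        raise MoleculeParseError(source_id or "<empty>", "empty drug record")
    sid = source_id or source.splitlines()[0][:40]
    if "V2000" in source or "\n" in source.strip():
        mol = Chem.MolFromMolBlock(source, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(source, sanitize=True)
    if mol is None:
        raise MoleculeParseError(sid, f"unparsable structure: {source[:60]!r}")
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    if mol.GetNumAtoms() == 0:
        raise MoleculeParseError(sid, "molecule has no heavy atoms")
    return _from_rdkit(mol, sid)


def featurize_atom(mol, idx):
    """Return the 9-slot integer feature vector for atom ``idx``."""
    if not 0 <= idx < mol.n_atoms:
        raise IndexError(f"atom index {idx} out of range for {mol.n_atoms} atoms")
    a = mol.atoms[idx]
    degree = sum(1 for i, j, _ in mol.bonds if idx in (i, j))
    return np.array([
        min(mol.n_atoms, C.MAX_ATOM_COUNT),
        C.code(C.CHIRALITY, a.chirality),
        min(degree, C.MAX_DEGREE),
        C.code(C.FORMAL_CHARGES, a.formal_charge),
        min(a.num_h, C.MAX_NUM_H),
        min(a.radical_electrons, C.MAX_RADICALS),
        C.code(C.HYBRIDIZATIONS, a.hybridization),
        int(a.aromatic),
        int(a.in_ring),
    ], dtype=np.int64)


def featurize_bond(mol, bond):
    """Return the 3-slot integer feature vector (type, stereo, conjugation).

    ``bond`` may be a (i, j) pair in either order or an index into
    ``mol.bonds``.
    """
    if isinstance(bond, (int, np.integer)):
        if not 0 <= bond < len(mol.bonds):
            raise IndexError(f"bond index {bond} out of range")
        _, _, rec = mol.bonds[bond]
    else:
        i, j = sorted(bond)
        for bi, bj, r in mol.bonds:
            if (bi, bj) == (i, j):
                rec = r
                break
        else:
            raise IndexError(f"no bond between atoms {i} and {j}")
    return np.array([
        C.code(C.BOND_TYPES, rec.bond_type),
        C.code(C.BOND_STEREO, rec.stereo),
        int(rec.conjugated),
    ], dtype=np.int64)


def build_drug_graph(mol):
    """Assemble the attributed molecular graph for one molecule."""
    n = mol.n_atoms
    if n < 1:
        raise ValueError("molecule has no atoms")
    feats = np.stack([featurize_atom(mol, i) for i in range(n)])
    adj = np.zeros((n, n), dtype=np.int64)
    edges = []
    for k, (i, j, _) in enumerate(mol.bonds):
        adj[i, j] = adj[j, i] = 1
        edges.append((i, j, featurize_bond(mol, k)))
    return DrugGraph(node_features=feats, adjacency=adj, edges=edges,
                     degrees=adj.sum(axis=1))


def mol_encoder_features(mol):
    """Integer feature codes for the GCN drug encoder path.

    This path uses a different slot set from the 9-vector: element, degree,
    position index in the molecule, implicit valence (approximated by the
    attached-hydrogen count), formal charge, and hybridization.
    """
    rows = []
    for idx, a in enumerate(mol.atoms):
        degree = sum(1 for i, j, _ in mol.bonds if idx in (i, j))
        rows.append([
            C.code(C.ELEMENTS, a.element),
            min(degree, C.MAX_DEGREE),
            min(idx, C.MAX_ATOM_COUNT - 1),
            min(a.num_h, C.MAX_NUM_H),
            C.code(C.FORMAL_CHARGES, a.formal_charge),
            C.code(C.HYBRIDIZATIONS, a.hybridization),
        ])
    return np.asarray(rows, dtype=np.int64)
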