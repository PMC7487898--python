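"""Molecular graph representations.

Two views of a molecule are used in this package:

* :class:`DirectedMolGraph` — the featurized directed-bond graph consumed by
  the message-passing property encoder. Atoms carry 133-dimensional feature
  vectors and bonds 14-dimensional ones; each chemical bond contributes two
  directed bonds, and each directed bond an input vector of length
  133 + 14 = 147 (source-atom features concatenated with bond features).

* :class:`DenseState` — the dense (A, E, F) state used by the reinforcement
  learning environment and policy network: adjacency A in {0,1}^{n x n}, an
  edge-conditioned tensor E in {0,1}^{3 x n x n} whose slices are the
  single/double/triple bond types, and node features F. Because E has only
  three bond-order slices, molecules are kekulized when converted to a
  DenseState; the property featurization keeps aromaticity flags.

Hydrogens are implicit throughout; atom counts refer to heavy atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

ATOM_FDIM = 133
BOND_FDIM = 14
BOND_INPUT_DIM = ATOM_FDIM + BOND_FDIM

#: Default menu of atom types the generator may add. The order defines the
#: meaning of "second atom" indices >= n in the action space.
DEFAULT_ATOM_TYPES: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")

# Feature block layout. Each categorical block reserves its last slot for
# out-of-range ("uncommon") values; block sizes sum to 133 with the aromatic
# flag and the scaled atomic mass as the two trailing scalar entries.
_ATOMIC_NUM_RANGE = list(range(1, 101))          # slots 0..99, uncommon -> 100
_DEGREE_RANGE = list(range(0, 6))                # slots 101..106, uncommon -> 107
_FORMAL_CHARGE_RANGE = [-2, -1, 0, 1, 2]         # slots 108..112, uncommon -> 113
_CHIRAL_TAG_RANGE = list(range(0, 4))            # slots 114..117, uncommon -> 118
_NUM_H_RANGE = list(range(0, 5))                 # slots 119..123, uncommon -> 124
_HYBRIDIZATION_RANGE = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]                                                # slots 125..129, uncommon -> 130

_BLOCKS = (
    len(_ATOMIC_NUM_RANGE) + 1,
    len(_DEGREE_RANGE) + 1,
    len(_FORMAL_CHARGE_RANGE) + 1,
    len(_CHIRAL_TAG_RANGE) + 1,
    len(_NUM_H_RANGE) + 1,
    len(_HYBRIDIZATION_RANGE) + 1,
)
assert sum(_BLOCKS) + 2 == ATOM_FDIM

AROMATIC_INDEX = sum(_BLOCKS)          # 131
MASS_INDEX = AROMATIC_INDEX + 1        # 132

_BOND_STEREO_SLOTS = 7                 # RDKit stereo codes 0..5 + uncommon


@dataclass(frozen=True)
class AtomDescriptor:
    """Plain record of the atom attributes that enter the feature vector."""

    atomic_num: int
    degree: int
    formal_charge: int
    chiral_tag: int
    num_h: int
    hybridization: object
    is_aromatic: bool
    mass: float

    @classmethod
    def from_rdkit(cls, atom: Chem.Atom) -> "AtomDescriptor":
        return cls(
            atomic_num=atom.GetAtomicNum(),
            degree=atom.GetTotalDegree(),
            formal_charge=atom.GetFormalCharge(),
            chiral_tag=int(atom.GetChiralTag()),
            num_h=atom.GetTotalNumHs(),
            hybridization=atom.GetHybridization(),
            is_aromatic=atom.GetIsAromatic(),
            mass=atom.GetMass(),
        )


def _one_hot(value, choices: list) -> np.ndarray:
    """One-hot over ``choices`` with a trailing uncommon slot."""
    v = np.zeros(len(choices) + 1)
    try:
        v[choices.index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


def featurize_atom(atom: Chem.Atom | AtomDescriptor) -> np.ndarray:
    """133-dimensional atom feature vector.

    Blocks: atomic number (1..100), total degree (0..5), formal charge
    (-2..+2), chiral tag (0..3), total H count (0..4), hybridization
    (SP..SP3D2) — each with one extra uncommon slot — followed by the
    aromaticity flag and the atomic mass scaled by 0.01.
    """
    if isinstance(atom, Chem.Atom):
        atom = AtomDescriptor.from_rdkit(atom)
    parts = [
        _one_hot(atom.atomic_num, _ATOMIC_NUM_RANGE),
        _one_hot(atom.degree, _DEGREE_RANGE),
        _one_hot(atom.formal_charge, _FORMAL_CHARGE_RANGE),
        _one_hot(atom.chiral_tag, _CHIRAL_TAG_RANGE),
        _one_hot(atom.num_h, _NUM_H_RANGE),
        _one_hot(atom.hybridization, _HYBRIDIZATION_RANGE),
        np.array([1.0 if atom.is_aromatic else 0.0]),
        np.array([atom.mass * 0.01]),
    ]
    return np.concatenate(parts)


def featurize_bond(bond: Chem.Bond | None) -> np.ndarray:
    """14-dimensional bond feature vector; ``None`` encodes "no bond" (zeros).

    Layout: bond present; single/double/triple one-hot; aromatic; conjugated;
    in-ring; 7-slot stereo code. Aromatic bonds carry a zero bond-type block
    (order is expressed by the aromatic flag); any other nonstandard type also
    zeroes the block and is logged.
    """
    v = np.zeros(BOND_FDIM)
    if bond is None:
        return v
    v[0] = 1.0
    bt = bond.GetBondType()
    if bt == Chem.BondType.SINGLE:
        v[1] = 1.0
    elif bt == Chem.BondType.DOUBLE:
        v[2] = 1.0
    elif bt == Chem.BondType.TRIPLE:
        v[3] = 1.0
    elif bt == Chem.BondType.AROMATIC:
        pass  # expressed by the aromatic flag below
    else:
        logger.warning("unknown bond type %s; bond-type block left zero", bt)
    if bond.GetIsAromatic():
        v[4] = 1.0
    if bond.GetIsConjugated():
        v[5] = 1.0
    if bond.IsInRing():
        v[6] = 1.0
    stereo = int(bond.GetStereo())
    v[7 + (stereo if 0 <= stereo < _BOND_STEREO_SLOTS - 1 else _BOND_STEREO_SLOTS - 1)] = 1.0
    return v


@dataclass
class DirectedMolGraph:
    """Directed-bond message-passing structure for one molecule."""

    atom_features: np.ndarray            # (n_atoms, 133)
    bond_src: np.ndarray                 # (n_bonds,) source atom per directed bond
    bond_dst: np.ndarray                 # (n_bonds,) target atom per directed bond
    bond_features: np.ndarray            # (n_bonds, 14)
    bond_inputs: np.ndarray              # (n_bonds, 147) [source atom || bond]
    incoming: list[list[int]]            # atom -> incoming directed-bond indices
    reverse: np.ndarray                  # directed bond -> its opposite twin
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_src.shape[0]


def mol_to_graph(mol: Chem.Mol, smiles: str = "") -> DirectedMolGraph:
    n = mol.GetNumAtoms()
    atom_features = np.array([featurize_atom(a) for a in mol.GetAtoms()]).reshape(n, ATOM_FDIM)
    src, dst, bfeat = [], [], []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = featurize_bond(bond)
        src += [u, v]
        dst += [v, u]
        bfeat += [f, f]
    nb = len(src)
    bond_src = np.array(src, dtype=np.int64)
    bond_dst = np.array(dst, dtype=np.int64)
    bond_features = np.array(bfeat).reshape(nb, BOND_FDIM)
    bond_inputs = (
        np.concatenate([atom_features[bond_src], bond_features], axis=1)
        if nb else np.zeros((0, BOND_INPUT_DIM))
    )
    incoming: list[list[int]] = [[] for _ in range(n)]
    for k, a in enumerate(bond_dst):
        incoming[a].append(k)
    reverse = np.array([k ^ 1 for k in range(nb)], dtype=np.int64)
    return DirectedMolGraph(atom_features, bond_src, bond_dst, bond_features,
                            bond_inputs, incoming, reverse, smiles=smiles)


def smiles_to_mol(smiles: str, kekulize: bool = False) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES: {smiles!r}")
    if kekulize:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def smiles_to_graph(smiles: str) -> DirectedMolGraph:
    """Featurized directed graph from a SMILES string.

    Raises ``ValueError`` naming the input when the SMILES does not parse.
    """
    return mol_to_graph(smiles_to_mol(smiles), smiles=smiles)


def canonical(smiles: str) -> str:
    return Chem.MolToSmiles(smiles_to_mol(smiles))


# ---------------------------------------------------------------------------
# Dense (A, E, F) state
# ---------------------------------------------------------------------------

_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)


@dataclass
class DenseState:
    """Dense molecular state (A, E, F) over n heavy atoms.

    ``E`` has three symmetric slices for single/double/triple bonds; ``A`` is
    the slice-wise OR. ``F`` holds per-atom feature vectors and ``elements``
    the atom symbols (needed to rebuild a molecule).
    """

    A: np.ndarray                        # (n, n)
    E: np.ndarray                        # (3, n, n)
    F: np.ndarray                        # (n, ATOM_FDIM)
    elements: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def validate(self) -> None:
        A, E = self.A, self.E
        if not np.array_equal(A, A.T) or np.any(np.diag(A) != 0):
            raise ValueError("A must be symmetric with zero diagonal")
        if np.any(E.sum(axis=0) > 1):
            raise ValueError("at most one bond-type slice per atom pair")
        if not np.array_equal((E.sum(axis=0) > 0).astype(A.dtype), A):
            raise ValueError("A must equal the OR of E slices")
        for i in range(3):
            if not np.array_equal(E[i], E[i].T):
                raise ValueError("E slices must be symmetric")


def mol_to_dense(mol: Chem.Mol) -> DenseState:
    """Kekulized dense state of a molecule (aromatic bonds become alternating
    single/double so they fit the three bond-order slices)."""
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    n = mol.GetNumAtoms()
    A = np.zeros((n, n), dtype=np.int8)
    E = np.zeros((3, n, n), dtype=np.int8)
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        try:
            i = _BOND_ORDERS.index(bond.GetBondType())
        except ValueError as err:
            raise ValueError(f"bond type {bond.GetBondType()} has no edge slice") from err
        E[i, u, v] = E[i, v, u] = 1
        A[u, v] = A[v, u] = 1
    F = np.array([featurize_atom(a) for a in mol.GetAtoms()]).reshape(n, ATOM_FDIM)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    return DenseState(A=A, E=E, F=F, elements=elements)


def smiles_to_dense(smiles: str) -> DenseState:
    return mol_to_dense(smiles_to_mol(smiles))


def state_to_molecule(state: DenseState, atom_types: list[str] | None = None
                      ) -> tuple[Chem.Mol, str]:
    """Rebuild a sanitized molecule (and canonical SMILES) from a dense state.

    ``atom_types`` overrides the element symbols stored on the state (one per
    node). A valence-violating state raises ``ValueError``.
    """
    elements = list(atom_types) if atom_types is not None else state.elements
    if len(elements) != state.n:
        raise ValueError("element list length must equal atom count")
    rw = Chem.RWMol()
    for sym in elements:
        rw.AddAtom(Chem.Atom(sym))
    n = state.n
    for i, order in enumerate(_BOND_ORDERS):
        rows, cols = np.nonzero(np.triu(state.E[i], k=1))
        for u, v in zip(rows.tolist(), cols.tolist()):
            rw.AddBond(u, v, order)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as err:
        raise ValueError(f"dense state is not a valid molecule: {err}") from err
    return mol, Chem.MolToSmiles(mol)
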