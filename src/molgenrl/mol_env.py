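"""Molecule-construction Markov decision process.

A molecule is grown one bond at a time. The state is the current partial
molecule (always a chemically valid, kekulized heavy-atom graph); an action
is a 4-vector (first atom, second atom, bond type, stop). The second-atom
index may point past the current atoms into an ordered menu of addable atom
types, in which case a new atom is attached; pointing at an existing atom
closes a ring. Actions whose result fails chemistry (valence) checks leave
the state unchanged and earn nothing; valid growth steps earn a small
constant bonus. On termination the final reward combines weighted predicted
properties, drug-likeness (QED), normalized synthetic accessibility, a
steric-strain bonus, a functional-group-filter bonus and an optional
adversarial term, itemised in a :class:`RewardBreakdown`.
"""

from __future__ import annotations

import logging
import math
import os
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, QED, RDConfig

from .molgraph import DEFAULT_ATOM_TYPES, DenseState, mol_to_dense, smiles_to_mol

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, resolved via RDConfig)

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

__all__ = [
    "ActionVector", "EnvState", "RewardConfig", "RewardBreakdown",
    "MoleculeEnv", "valence_ok", "strain_ok", "zinc_filter_ok",
    "load_filter_catalog", "sa_norm",
]

_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)
_PT = Chem.GetPeriodicTable()


@dataclass(frozen=True)
class ActionVector:
    """(first atom, second atom, bond type, stop).

    ``first`` indexes the current atoms [0, n); ``second`` indexes [0, n+c):
    below n it closes a cycle, at n+k it adds a new atom of the k-th menu
    type. ``edge`` is 0/1/2 for single/double/triple; ``stop`` in {0, 1}.
    """

    first: int
    second: int
    edge: int
    stop: int


@dataclass
class EnvState:
    mol: Chem.Mol
    steps: int = 0
    done: bool = False
    seed_smiles: str = "C"

    @property
    def n(self) -> int:
        return self.mol.GetNumAtoms()

    def to_dense(self) -> DenseState:
        return mol_to_dense(self.mol)

    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass
class RewardConfig:
    """Weights and limits of the reward function.

    ``property_weights`` maps property-model names to reward weights (the
    dual-target setting uses e.g. {target: +2, antitarget: -1}); ``sa_weight``
    defaults to 2 because the final reward adds twice the normalized
    synthetic-accessibility score.
    """

    property_weights: dict[str, float] = field(default_factory=dict)
    step_valid_bonus: float = 0.05
    invalid_penalty: float = 0.0
    strain_bonus: float = 1.0
    filter_bonus: float = 1.0
    qed_weight: float = 1.0
    sa_weight: float = 2.0
    adversarial_weight: float = 0.0
    max_heavy_atoms: int = 25
    strain_threshold: float = 0.82   # kcal/mol of angle-bend energy per heavy atom

    def __post_init__(self):
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")
        vals = list(self.property_weights.values()) + [
            self.step_valid_bonus, self.strain_bonus, self.filter_bonus,
            self.qed_weight, self.sa_weight, self.adversarial_weight]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("reward weights must be finite")

    @classmethod
    def from_yaml(cls, path: str) -> "RewardConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class RewardBreakdown:
    """Itemised final reward; ``total`` is exactly the sum of ``parts``."""

    parts: dict[str, float]
    total: float

    @classmethod
    def from_parts(cls, parts: dict[str, float]) -> "RewardBreakdown":
        return cls(parts=parts, total=float(sum(parts.values())))


# ---------------------------------------------------------------------------
# Chemistry checks
# ---------------------------------------------------------------------------

def max_valence(symbol: str) -> int:
    vals = list(_PT.GetValenceList(symbol))
    return max(vals) if vals and vals[0] != -1 else 8


def valence_ok(graph: DenseState) -> bool:
    """True iff every atom's total bond order fits its element's maximum
    valence (implicit hydrogens fill the remainder)."""
    orders = np.tensordot([1, 2, 3], graph.E, axes=1).sum(axis=1)
    return all(o <= max_valence(sym) for o, sym in zip(orders, graph.elements))


def strain_ok(mol: Chem.Mol, threshold: float = 0.82,
              on_embed_failure: str = "pass") -> bool:
    """Steric-strain check on a relaxed 3-D conformer.

    Embeds the molecule, minimizes with MMFF94, then evaluates the angle-bend
    term alone; passes iff that energy per heavy atom is below ``threshold``
    (kcal/mol). Molecules that cannot be embedded or parameterized follow the
    ``on_embed_failure`` policy ("pass" or "fail").
    """
    if not math.isfinite(threshold):
        return threshold > 0
    fallback = on_embed_failure == "pass"
    try:
        m3 = Chem.AddHs(Chem.Mol(mol))
        if AllChem.EmbedMolecule(m3, randomSeed=0xC0FFEE, maxAttempts=50) != 0:
            logger.warning("conformer embedding failed; strain check %s",
                           "passed" if fallback else "failed")
            return fallback
        props = AllChem.MMFFGetMoleculeProperties(m3)
        if props is None:
            return fallback
        AllChem.MMFFGetMoleculeForceField(m3, props).Minimize(maxIts=500)
        for term in ("Bond", "StretchBend", "Oop", "Torsion", "VdW", "Ele"):
            getattr(props, f"SetMMFF{term}Term")(False)
        angle_energy = AllChem.MMFFGetMoleculeForceField(m3, props).CalcEnergy()
        return angle_energy / max(mol.GetNumHeavyAtoms(), 1) < threshold
    except Exception:
        logger.warning("strain check errored; applying %s policy", on_embed_failure)
        return fallback


def load_filter_catalog(path: str | None = None) -> list[tuple[str, Chem.Mol]]:
    """Load the substructure exclusion catalog (name<TAB>SMARTS per line)."""
    if path is None:
        path = os.path.join(os.path.dirname(__file__), "data", "zinc_filters.smarts")
    catalog = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, smarts = line.split("\t")
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"malformed SMARTS pattern {name!r}: {smarts}")
            catalog.append((name, patt))
    return catalog


_DEFAULT_CATALOG: list[tuple[str, Chem.Mol]] | None = None


def zinc_filter_ok(mol: Chem.Mol,
                   catalog: list[tuple[str, Chem.Mol]] | None = None) -> bool:
    """True iff no exclusion pattern matches the molecule."""
    global _DEFAULT_CATALOG
    if catalog is None:
        if _DEFAULT_CATALOG is None:
            _DEFAULT_CATALOG = load_filter_catalog()
        catalog = _DEFAULT_CATALOG
    return not any(mol.HasSubstructMatch(p) for _, p in catalog)


def sa_norm(mol: Chem.Mol) -> float:
    """Synthetic accessibility mapped to [0, 1], higher = easier: (10 - SA)/9."""
    return (10.0 - sascorer.calculateScore(mol)) / 9.0


# ---------------------------------------------------------------------------
# Environment
# ---------------------------------------------------------------------------

def _kekulized(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


class MoleculeEnv:
    """Valence-checked molecule-building environment.

    ``property_models`` maps names (the keys of
    ``RewardConfig.property_weights``) to callables scoring an RDKit Mol.
    ``discriminator`` (optional) is a callable Mol -> probability-real used
    for the adversarial reward term.
    """

    def __init__(self, reward_config: RewardConfig | None = None,
                 property_models: dict | None = None,
                 discriminator=None,
                 atom_types: tuple[str, ...] = DEFAULT_ATOM_TYPES,
                 max_steps: int | None = None):
        self.cfg = reward_config or RewardConfig()
        self.property_models = property_models or {}
        self.discriminator = discriminator
        self.atom_types = tuple(atom_types)
        self.max_steps = max_steps or 10 * self.cfg.max_heavy_atoms
        for name in self.cfg.property_weights:
            if name not in self.property_models:
                raise ValueError(f"no property model supplied for weight {name!r}")

    @property
    def n_atom_types(self) -> int:
        return len(self.atom_types)

    def reset(self, init: str = "C") -> EnvState:
        """Fresh state from a single atom or a seed SMILES."""
        mol = smiles_to_mol(init, kekulize=True)
        if mol.GetNumAtoms() > self.cfg.max_heavy_atoms:
            raise ValueError(
                f"seed molecule has {mol.GetNumAtoms()} heavy atoms, "
                f"cap is {self.cfg.max_heavy_atoms}")
        return EnvState(mol=mol, steps=0, done=False, seed_smiles=init)

    # -- dynamics ----------------------------------------------------------
    def _try_apply(self, mol: Chem.Mol, action: ActionVector) -> Chem.Mol | None:
        """Apply a bond-addition action; None when chemistry rejects it."""
        n = mol.GetNumAtoms()
        if not (0 <= action.first < n):
            return None
        if not (0 <= action.second < n + self.n_atom_types):
            return None
        if action.second < n and action.second == action.first:
            return None
        if not (0 <= action.edge < 3):
            return None
        rw = Chem.RWMol(mol)
        if action.second >= n:
            if n >= self.cfg.max_heavy_atoms:
                return None
            idx = rw.AddAtom(Chem.Atom(self.atom_types[action.second - n]))
        else:
            idx = action.second
            if mol.GetBondBetweenAtoms(action.first, idx) is not None:
                return None
        rw.AddBond(action.first, idx, _BOND_ORDERS[action.edge])
        new = rw.GetMol()
        try:
            Chem.SanitizeMol(new)
        except Exception:
            return None
        return _kekulized(new)

    def step(self, state: EnvState, action: ActionVector
             ) -> tuple[EnvState, float, bool, dict]:
        """One MDP transition; pure in (state, action).

        Returns (next_state, step_reward, done, info); on termination the
        reward is the final-reward total and ``info['breakdown']`` itemises
        it.
        """
        if state.done:
            raise RuntimeError("cannot step a finished episode")
        if action.stop:
            nxt = replace(state, done=True, steps=state.steps + 1)
            bd = self.final_reward(nxt.mol)
            return nxt, bd.total, True, {"breakdown": bd}
        new_mol = self._try_apply(state.mol, action)
        steps = state.steps + 1
        if new_mol is None:
            nxt = EnvState(mol=state.mol, steps=steps, done=False,
                           seed_smiles=state.seed_smiles)
            reward = -self.cfg.invalid_penalty
        else:
            nxt = EnvState(mol=new_mol, steps=steps, done=False,
                           seed_smiles=state.seed_smiles)
            reward = self.cfg.step_valid_bonus
        if nxt.n >= self.cfg.max_heavy_atoms or steps >= self.max_steps:
            nxt.done = True
            bd = self.final_reward(nxt.mol)
            return nxt, reward + bd.total, True, {"breakdown": bd}
        return nxt, reward, False, {}

    # -- rewards -----------------------------------------------------------
    def final_reward(self, mol: Chem.Mol) -> RewardBreakdown:
        cfg = self.cfg
        # re-perceive aromaticity so scoring sees the standard form
        mol = smiles_to_mol(Chem.MolToSmiles(mol))
        parts: dict[str, float] = {}
        for name, w in cfg.property_weights.items():
            parts[f"property:{name}"] = w * float(self.property_models[name](mol))
        parts["qed"] = cfg.qed_weight * QED.qed(mol)
        parts["sa"] = cfg.sa_weight * sa_norm(mol)
        parts["strain"] = cfg.strain_bonus * float(
            strain_ok(mol, threshold=cfg.strain_threshold))
        parts["filter"] = cfg.filter_bonus * float(zinc_filter_ok(mol))
        if self.discriminator is not None and cfg.adversarial_weight != 0.0:
            d = float(np.clip(self.discriminator(mol), 1e-6, 1 - 1e-6))
            parts["adversarial"] = cfg.adversarial_weight * (-math.log(1.0 - d))
        return RewardBreakdown.from_parts(parts)
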