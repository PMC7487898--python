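"""Synthetic fixtures: a deterministic property oracle and dataset generators.

Real transporter-binding data (pKi labels from heterogeneous assays) is large,
external and noisy, with a known pathology: weak binders are often recorded
with censored labels such as "~1000 nM", which become gross one-sided
outliers after the log transform. The generators here emulate that
statistical structure offline so every stage of the pipeline is testable:

* :func:`toy_oracle` — a deterministic, bounded pseudo-pKi computed from
  interpretable whole-molecule descriptors (ring counts, heteroatom fraction,
  size, a hydrophobicity-like carbon fraction). It stands in for a trained
  binding model wherever a property scorer is needed.
* :func:`make_property_dataset` — labelled molecules with Gaussian label
  noise plus a fraction of gross negative label shifts (the censored-label
  contamination).
* :func:`make_expert_set` — a pool of valid, drug-like-ish molecules (<= 25
  heavy atoms) standing in for a commercial-compound expert dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .molgraph import smiles_to_mol

__all__ = [
    "ToyOracleParams",
    "descriptors",
    "toy_oracle",
    "make_property_dataset",
    "make_expert_set",
    "ki_to_pki",
    "SCAFFOLD_POOL",
]

#: Drug-like-ish scaffolds (all <= 20 heavy atoms, all sanitizable).
SCAFFOLD_POOL: tuple[str, ...] = (
    "c1ccccc1", "Cc1ccccc1", "c1ccncc1", "c1ccc2ccccc2c1", "c1ccoc1",
    "c1ccsc1", "c1cc[nH]c1", "c1cnc2[nH]ccc2c1", "C1CCCCC1", "C1CCNCC1",
    "C1CCOC1", "C1CCNC1", "O=C1CCCCC1", "c1ccc(-c2ccccc2)cc1",
    "c1ccc(Cc2ccccc2)cc1", "O=C(C)Oc1ccccc1C(=O)O", "CC(=O)Nc1ccccc1",
    "c1ccc(N2CCNCC2)cc1", "c1ccc(N2CCOCC2)cc1", "O=C(Nc1ccccc1)C1CC1",
    "CC(N)Cc1ccccc1", "NCCc1ccc(O)c(O)c1", "CN1CCC(c2ccccc2)CC1",
    "O=C(O)c1ccccc1", "COc1ccccc1", "CC(C)Cc1ccccc1", "c1ccc(F)cc1",
    "Clc1ccccc1", "c1ccc(S(N)(=O)=O)cc1", "CC(=O)c1ccccc1",
    "c1cnc2ccccc2c1", "c1ccc2[nH]ccc2c1", "C1COCCN1", "C1CN(CCN1)C",
    "OCCc1ccccc1", "N#Cc1ccccc1", "CC1CCCCC1", "O=C1NC(=O)c2ccccc21",
    "c1cnoc1", "c1con[nH0]1", "CC(C)NCC(O)c1ccccc1", "CCN(CC)CCc1ccccc1",
)

#: Small substituents used to decorate scaffolds (attached by a single bond).
_SUBSTITUENTS: tuple[str, ...] = ("C", "N", "O", "F", "Cl", "CC", "C(C)C", "OC", "C#N")


@dataclass(frozen=True)
class ToyOracleParams:
    """Weights of the descriptor-linear pseudo-pKi oracle.

    The output is clamped to a pKi-like [2, 10] range. Defaults give a
    spread of roughly 4-9 over the fixture pool, comparable to real binding
    datasets.
    """

    w_rings: float = 0.5
    w_aromatic_rings: float = 0.8
    w_hetero_frac: float = 3.0
    w_heavy_atoms: float = 0.05
    w_carbon_frac: float = -1.0        # hydrophobicity-like term
    bias: float = 5.0
    clamp: tuple[float, float] = (2.0, 10.0)


def descriptors(mol: Chem.Mol) -> dict[str, float]:
    n_heavy = mol.GetNumHeavyAtoms()
    n_carbon = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    n_hetero = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() not in (1, 6))
    return {
        "rings": float(rdMolDescriptors.CalcNumRings(mol)),
        "aromatic_rings": float(rdMolDescriptors.CalcNumAromaticRings(mol)),
        "hetero_frac": n_hetero / max(n_heavy, 1),
        "heavy_atoms": float(n_heavy),
        "carbon_frac": n_carbon / max(n_heavy, 1),
    }


def toy_oracle(mol: Chem.Mol | str, params: ToyOracleParams | None = None) -> float:
    """Deterministic bounded pseudo-pKi of a molecule."""
    if isinstance(mol, str):
        mol = smiles_to_mol(mol)
    p = params or ToyOracleParams()
    d = descriptors(mol)
    score = (p.bias
             + p.w_rings * d["rings"]
             + p.w_aromatic_rings * d["aromatic_rings"]
             + p.w_hetero_frac * d["hetero_frac"]
             + p.w_heavy_atoms * d["heavy_atoms"]
             + p.w_carbon_frac * d["carbon_frac"])
    lo, hi = p.clamp
    return float(min(max(score, lo), hi))


def _attachment_points(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms()
            if a.GetImplicitValence() >= 1 and a.GetAtomicNum() == 6]


def _decorate(smiles: str, rng: np.random.Generator, max_subs: int = 2,
              max_heavy: int = 25) -> str:
    """Attach up to ``max_subs`` small substituents at random carbons."""
    mol = smiles_to_mol(smiles)
    for _ in range(int(rng.integers(0, max_subs + 1))):
        sub = smiles_to_mol(_SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))])
        if mol.GetNumHeavyAtoms() + sub.GetNumHeavyAtoms() > max_heavy:
            break
        points = _attachment_points(mol)
        if not points:
            break
        at = points[int(rng.integers(len(points)))]
        combo = Chem.RWMol(Chem.CombineMols(mol, sub))
        combo.AddBond(at, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        cand = combo.GetMol()
        try:
            Chem.SanitizeMol(cand)
        except Exception:
            continue
        mol = cand
    return Chem.MolToSmiles(mol)


def sample_molecules(n: int, seed: int, max_heavy: int = 25) -> list[str]:
    """Deterministically sample ``n`` decorated fixture molecules."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        scaf = SCAFFOLD_POOL[int(rng.integers(len(SCAFFOLD_POOL)))]
        out.append(_decorate(scaf, rng, max_heavy=max_heavy))
    return out


def make_property_dataset(n: int, noise_sd: float, outlier_fraction: float,
                          outlier_shift: float, seed: int,
                          params: ToyOracleParams | None = None,
                          path: str | None = None) -> pd.DataFrame:
    """Labelled dataset ``smiles,target`` with heavy-tailed contamination.

    target = toy_oracle + N(0, noise_sd), except a ``outlier_fraction`` of
    rows additionally shifted by ``outlier_shift`` (gross, one-sided label
    errors mimicking censored weak-binder labels). Deterministic per seed.
    """
    if n < 10:
        raise ValueError("dataset size must be at least 10")
    if not 0.0 <= outlier_fraction <= 1.0:
        raise ValueError(f"outlier_fraction must be in [0, 1], got {outlier_fraction}")
    rng = np.random.default_rng(seed)
    smiles = sample_molecules(n, seed=int(rng.integers(2 ** 31)))
    clean = np.array([toy_oracle(s, params) for s in smiles])
    targets = clean + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    n_out = int(round(n * outlier_fraction))
    outlier_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    targets = targets.astype(float)
    targets[outlier_idx] += outlier_shift
    is_outlier = np.zeros(n, dtype=bool)
    is_outlier[outlier_idx] = True
    df = pd.DataFrame({"smiles": smiles, "target": targets,
                       "clean_target": clean, "is_outlier": is_outlier})
    if path is not None:
        df[["smiles", "target"]].to_csv(path, index=False)
    return df


def make_expert_set(n: int, seed: int, path: str | None = None,
                    max_heavy: int = 25) -> list[str]:
    """Expert molecule pool: ``n`` valid fixture molecules, <= 25 heavy atoms."""
    if n < 1:
        raise ValueError("expert set needs at least one molecule")
    smiles = sample_molecules(n, seed=seed, max_heavy=max_heavy)
    if path is not None:
        with open(path, "w") as fh:
            fh.write("\n".join(smiles) + "\n")
    return smiles


def ki_to_pki(value: float, unit: str = "nM") -> float:
    """pKi from a Ki or IC50 value: pKi = 9 - log10(Ki[nM]) = -log10(Ki[M])."""
    if value <= 0:
        raise ValueError(f"Ki/IC50 must be positive, got {value}")
    if unit == "nM":
        return 9.0 - math.log10(value)
    if unit == "M":
        return -math.log10(value)
    raise ValueError(f"unsupported unit {unit!r} (use 'nM' or 'M')")
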