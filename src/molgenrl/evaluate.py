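"""Post-hoc analysis of generated molecules.

Top-k reporting with drug-likeness / synthesizability filters, Tanimoto
similarity of generated molecules to a reference set (nearest neighbour and
its distribution), and Pareto-front extraction for two-objective runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .molgraph import canonical, smiles_to_mol

__all__ = ["fingerprint", "tanimoto", "nearest_reference",
           "similarity_distribution", "pareto_front", "topk_report",
           "GeneratedRecord"]

FINGERPRINT_KINDS = ("path", "pattern", "morgan")


def fingerprint(mol: Chem.Mol | str, kind: str = "path",
                n_bits: int = 2048) -> np.ndarray:
    """Binary fingerprint as a boolean vector.

    ``path`` is the RDKit path-based (Daylight-like) fingerprint, ``pattern``
    the substructure-screening patterned fingerprint, ``morgan`` the
    radius-2 circular fingerprint.
    """
    if isinstance(mol, str):
        mol = smiles_to_mol(mol)
    if kind == "path":
        bv = Chem.RDKFingerprint(mol, fpSize=n_bits)
    elif kind == "pattern":
        bv = Chem.PatternFingerprint(mol, fpSize=n_bits)
    elif kind == "morgan":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
        bv = gen.GetFingerprint(mol)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}; use {FINGERPRINT_KINDS}")
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| over bit vectors; 1.0 when both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def nearest_reference(mol: Chem.Mol | str, reference: list[str],
                      kind: str = "path",
                      ref_fps: list[np.ndarray] | None = None
                      ) -> tuple[str, float]:
    """Closest reference molecule by Tanimoto similarity.

    Ties break deterministically to the first molecule in reference order.
    ``ref_fps`` may carry precomputed fingerprints for the reference set.
    """
    if not reference:
        raise ValueError("reference set must be non-empty")
    fp = fingerprint(mol, kind)
    if ref_fps is None:
        ref_fps = [fingerprint(s, kind) for s in reference]
    sims = np.array([tanimoto(fp, r) for r in ref_fps])
    i = int(np.argmax(sims))
    return reference[i], float(sims[i])


def similarity_distribution(records: list[str] | pd.DataFrame,
                            reference: list[str], kind: str = "path",
                            bins: int = 20) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histogram over [0, 1] of nearest-reference Tanimoto similarities.

    ``records`` is a list of SMILES (e.g. the top-500 generated molecules) or
    a frame with a ``smiles`` column. Returns (counts, bin_edges, ts_values);
    counts sum to the number of records.
    """
    smiles = records["smiles"].tolist() if isinstance(records, pd.DataFrame) else list(records)
    ref_fps = [fingerprint(s, kind) for s in reference]
    ts = np.array([nearest_reference(s, reference, kind, ref_fps)[1] for s in smiles])
    counts, edges = np.histogram(ts, bins=bins, range=(0.0, 1.0))
    return counts, edges, ts


def pareto_front(points, senses: list[str] | None = None) -> np.ndarray:
    """Indices of non-dominated points.

    A point is kept iff no other point is at least as good in every objective
    and strictly better in one. ``senses`` gives "max"/"min" per objective
    (default: maximize all).
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2:
        raise ValueError("points must be 2-D (n_points x n_objectives)")
    if not np.all(np.isfinite(P)):
        raise ValueError("objective values must be finite")
    senses = senses or ["max"] * P.shape[1]
    signs = np.array([1.0 if s == "max" else -1.0 for s in senses])
    Q = P * signs
    n = Q.shape[0]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        geq = (Q >= Q[i]).all(axis=1)
        gt = (Q > Q[i]).any(axis=1)
        if np.any(geq & gt):
            keep[i] = False
    return np.flatnonzero(keep)


@dataclass
class GeneratedRecord:
    smiles: str
    properties: dict[str, float]
    qed: float
    sa_norm: float
    reward: float
    nearest_smiles: str | None = None
    nearest_ts: float | None = None


def topk_report(records: list[dict] | pd.DataFrame, k: int = 10,
                qed_min: float = 0.8, sa_min: float = 0.8,
                rank_by: str = "reward",
                reference: list[str] | None = None,
                fingerprint_kind: str = "path") -> pd.DataFrame:
    """Ranked table of the top-k generated molecules.

    Records (episode-log dicts or a frame with at least ``smiles``,
    ``reward``, ``qed``, ``sa_norm`` columns) are deduplicated by canonical
    SMILES (best reward kept), filtered on QED > ``qed_min`` and normalized
    SA > ``sa_min``, ranked by ``rank_by`` descending and truncated to k.
    When a reference set is given, nearest-reference SMILES and Tanimoto
    similarity columns are added.
    """
    if not isinstance(records, pd.DataFrame):
        rows = [{"smiles": r["smiles"], "reward": r.get("reward", 0.0),
                 "qed": r.get("qed", np.nan), "sa_norm": r.get("sa_norm", np.nan)}
                for r in records]
        records = pd.DataFrame(rows)
    df = records.copy()
    df["smiles"] = df["smiles"].map(canonical)
    df = (df.sort_values(rank_by, ascending=False)
            .drop_duplicates(subset="smiles", keep="first"))
    df = df[(df["qed"] > qed_min) & (df["sa_norm"] > sa_min)]
    if df.empty:
        import warnings
        warnings.warn("no molecules pass the QED/SA filters; empty report")
    df = df.head(k).reset_index(drop=True)
    if reference and not df.empty:
        ref_fps = [fingerprint(s, fingerprint_kind) for s in reference]
        near = [nearest_reference(s, reference, fingerprint_kind, ref_fps)
                for s in df["smiles"]]
        df["nearest_smiles"] = [n[0] for n in near]
        df["nearest_ts"] = [n[1] for n in near]
    return df
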