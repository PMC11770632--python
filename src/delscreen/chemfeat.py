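"""Morgan-fingerprint featurization and Tanimoto similarity.

Two feature conventions are used across the pipeline, mirroring common
virtual-screening practice: radius 2 / 1024 bits (ECFP4-style) for the
random-forest models, and radius 3 / 2048 bits (ECFP6-style) for the
fingerprint DNN.  "ECFP6" always means Morgan radius 3 (environment
diameter 6 bonds) here.  PTE similarity profiling uses ECFP6 folded to
1024 bits.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

# PTE similarity profiling convention: 1024-bit ECFP6
PTE_SIM_RADIUS = 3
PTE_SIM_NBITS = 1024


@dataclass(frozen=True)
class Fingerprint:
    """A folded circular fingerprint with its generation parameters."""

    bits: frozenset[int]
    radius: int
    nbits: int
    smiles_hash: str

    @property
    def popcount(self) -> int:
        return len(self.bits)

    def to_array(self) -> np.ndarray:
        arr = np.zeros(self.nbits, dtype=np.uint8)
        arr[list(self.bits)] = 1
        return arr


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def fingerprint(smiles: str, radius: int = 2, nbits: int = 1024) -> Fingerprint:
    """Morgan fingerprint of one molecule.

    Deterministic and invariant to atom ordering: different SMILES for the
    same molecule produce identical bits.
    """
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(
        bits=frozenset(bv.GetOnBits()),
        radius=radius,
        nbits=nbits,
        smiles_hash=hashlib.sha1(Chem.MolToSmiles(mol).encode()).hexdigest()[:12],
    )


def fingerprint_matrix(
    smiles_list: list[str], radius: int = 2, nbits: int = 1024
) -> np.ndarray:
    """Dense uint8 feature matrix (n_molecules x nbits) for model training."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    out = np.zeros((len(smiles_list), nbits), dtype=np.uint8)
    for i, smi in enumerate(smiles_list):
        mol = _mol_from_smiles(smi)
        DataStructs.ConvertToNumpyArray(gen.GetFingerprint(mol), out[i])
    return out


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |A∩B| / |A∪B|; distance is 1 - similarity."""
    if (a.radius, a.nbits) != (b.radius, b.nbits):
        raise ValueError(
            f"fingerprint parameters differ: ({a.radius},{a.nbits}) vs ({b.radius},{b.nbits})"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        warnings.warn("tanimoto of two empty fingerprints defined as 0")
        return 0.0
    return len(a.bits & b.bits) / union


def _bulk_fps(smiles_list: list[str], radius: int, nbits: int):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    fps = []
    for smi in smiles_list:
        fps.append(gen.GetFingerprint(_mol_from_smiles(smi)))
    return fps


def bulk_similarity(
    query_smiles: str, smiles_list: list[str], radius: int = 3, nbits: int = 1024
) -> np.ndarray:
    """Tanimoto similarity of one query against a list (RDKit bulk kernel)."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    q = gen.GetFingerprint(_mol_from_smiles(query_smiles))
    return np.array(DataStructs.BulkTanimotoSimilarity(q, _bulk_fps(smiles_list, radius, nbits)))


def pte_similarity_profile(
    predictions: list[str],
    ptes: list[str],
    k: int = 10,
    radius: int = PTE_SIM_RADIUS,
    nbits: int = PTE_SIM_NBITS,
):
    """Structural-novelty profile of model predictions against the PTEs.

    For each predicted compound, reports the similarity to its most similar
    positive training example and the mean similarity over the ``k`` most
    similar PTEs (``k`` capped at the number of PTEs).  Low values flag
    predictions that are structurally novel relative to the training hits.

    Returns a DataFrame (smiles, max_sim, mean_top_k).
    """
    import pandas as pd

    if not ptes:
        raise ValueError("PTE list must be non-empty")
    k_eff = min(k, len(ptes))
    pte_fps = _bulk_fps(ptes, radius, nbits)
    rows = []
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    for smi in predictions:
        q = gen.GetFingerprint(_mol_from_smiles(smi))
        sims = np.array(DataStructs.BulkTanimotoSimilarity(q, pte_fps))
        top = np.sort(sims)[::-1][:k_eff]
        rows.append({"smiles": smi, "max_sim": float(sims.max()), "mean_top_k": float(top.mean())})
    return pd.DataFrame(rows)
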