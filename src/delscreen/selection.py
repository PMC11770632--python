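"""Purchase-list construction: property filtering, directed sphere
exclusion (DISE), and model-guided hit expansion.

DISE scans candidates in descending model score — the "direction" — and
keeps a candidate only if its Tanimoto *distance* (1 - similarity) to every
already-kept compound exceeds the exclusion radius.  The kept set is
therefore pairwise separated by more than the radius, and high-scoring
compounds always get first claim on their neighbourhood.  The 0.2 default
radius matches the analog-diversification setting used for hit expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit import DataStructs

from .chemfeat import _mol_from_smiles


@dataclass
class PropertyRules:
    """Drug-like property windows; conventional defaults, fully configurable."""

    mw: tuple[float, float] = (250.0, 550.0)
    heavy_atoms: tuple[int, int] = (17, 40)
    elements: frozenset[str] = field(
        default_factory=lambda: frozenset({"C", "N", "O", "S", "F", "Cl", "Br", "H"})
    )


@dataclass
class SelectionConfig:
    dise_radius: float = 0.2       # Tanimoto distance cutoff
    rules: PropertyRules = field(default_factory=PropertyRules)
    sim_radius: int = 3            # ECFP6 for similarity
    sim_nbits: int = 1024

    def __post_init__(self) -> None:
        if not 0.0 <= self.dise_radius <= 1.0:
            raise ValueError("dise_radius must lie in [0, 1]")


def property_filter(
    compounds: pd.DataFrame, rules: PropertyRules | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep compounds passing every property rule; tally rejections per rule.

    A compound failing several rules is tallied once per failed rule, so the
    tallies describe rule pressure, while survivors + rejected compounds
    always sum to the input count.
    """
    rules = rules or PropertyRules()
    tally = {"mw": 0, "heavy_atoms": 0, "elements": 0}
    keep = np.ones(len(compounds), dtype=bool)
    for i, smi in enumerate(compounds["smiles"]):
        mol = _mol_from_smiles(smi)
        mw = Descriptors.MolWt(mol)
        if not rules.mw[0] <= mw <= rules.mw[1]:
            tally["mw"] += 1
            keep[i] = False
        ha = mol.GetNumHeavyAtoms()
        if not rules.heavy_atoms[0] <= ha <= rules.heavy_atoms[1]:
            tally["heavy_atoms"] += 1
            keep[i] = False
        if any(a.GetSymbol() not in rules.elements for a in mol.GetAtoms()):
            tally["elements"] += 1
            keep[i] = False
    return compounds[keep].reset_index(drop=True), tally


def sphere_exclusion(
    fps: list,
    order: np.ndarray,
    radius: float,
    max_n: int | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy sphere exclusion over pre-ranked fingerprints.

    ``fps`` are RDKit bit vectors; ``order`` is the scan order (best first).
    Keeps an item iff its Tanimoto distance to every kept item is strictly
    greater than ``radius``.  Returns kept positions (into ``order``'s frame)
    and the distance of each kept item to its nearest previously-kept
    neighbour (NaN for the first).
    """
    kept: list[int] = []
    kept_fps: list = []
    nearest: list[float] = []
    for i in order:
        fp = fps[int(i)]
        if kept_fps:
            max_sim = max(DataStructs.BulkTanimotoSimilarity(fp, kept_fps))
            if 1.0 - max_sim <= radius:
                continue
            nearest.append(1.0 - max_sim)
        else:
            nearest.append(float("nan"))
        kept.append(int(i))
        kept_fps.append(fp)
        if max_n is not None and len(kept) >= max_n:
            break
    return kept, nearest


def dise_select(
    candidates: pd.DataFrame,
    radius: float = 0.2,
    max_n: int | None = None,
    sim_radius: int = 3,
    sim_nbits: int = 1024,
) -> pd.DataFrame:
    """Directed sphere exclusion over score-ranked candidates.

    ``candidates`` must carry ``smiles`` and ``score`` columns; they are
    scanned in descending score (stable for ties).  A candidate is kept iff
    its Tanimoto distance to every kept compound is strictly greater than
    ``radius``.  Stops once ``max_n`` compounds are kept.
    """
    ranked = candidates.sort_values("score", ascending=False, kind="stable")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=sim_radius, fpSize=sim_nbits)
    fps = [gen.GetFingerprint(_mol_from_smiles(s)) for s in ranked["smiles"]]
    kept, nearest = sphere_exclusion(fps, np.arange(len(fps)), radius, max_n)
    out = ranked.iloc[kept].reset_index(drop=True)
    out["nearest_kept_distance"] = nearest
    return out


def hit_expand(
    hit_smiles: str,
    catalog: pd.DataFrame,
    sim_threshold: float = 0.35,
    scorer=None,
    radius: float = 0.2,
    max_n: int | None = None,
    sim_radius: int = 3,
    sim_nbits: int = 1024,
) -> pd.DataFrame:
    """Model-guided analog expansion around a confirmed hit.

    Catalog compounds with ECFP6 Tanimoto similarity to the hit strictly
    above ``sim_threshold`` are ranked by the model score and diversified by
    DISE at the given radius.  Without a scorer, similarity to the hit is
    used as the ranking score.
    """
    if not 0.0 < sim_threshold <= 1.0:
        raise ValueError("sim_threshold must lie in (0, 1]")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=sim_radius, fpSize=sim_nbits)
    hit_fp = gen.GetFingerprint(_mol_from_smiles(hit_smiles))
    fps = [gen.GetFingerprint(_mol_from_smiles(s)) for s in catalog["smiles"]]
    sims = np.array(DataStructs.BulkTanimotoSimilarity(hit_fp, fps))
    mask = sims > sim_threshold
    if not mask.any():
        warnings.warn("no catalog compound passes the similarity threshold")
        return pd.DataFrame(columns=[*catalog.columns, "similarity_to_hit", "score"])
    analogs = catalog[mask].copy()
    analogs["similarity_to_hit"] = sims[mask]
    if scorer is not None:
        analogs["score"] = np.asarray(scorer.score(analogs["smiles"].tolist()), dtype=float)
    else:
        analogs["score"] = analogs["similarity_to_hit"]
    return dise_select(analogs, radius=radius, max_n=max_n, sim_radius=sim_radius, sim_nbits=sim_nbits)
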