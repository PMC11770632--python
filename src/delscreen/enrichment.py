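"""Disynthon aggregation, enrichment statistics, and five-class labeling.

Members are aggregated into disynthons — pairs of building blocks from two
synthesis cycles — before hit calling, because signal from a productive
block pair is spread over every member sharing it.  For a 2-cycle library
the member *is* its disynthon; a 3-cycle member contributes its count to
each of its three cycle-pair views.

Enrichment is a pseudocounted two-proportion z-score between a selection
condition and a reference condition.  Each disynthon then receives exactly
one of five classes (precedence top-down):

  matrix_binder       enriched in the no-target control vs the input pool
  promiscuous_binder  enriched (target vs no-target) for most targets of a
                      multi-target panel (needs a panel of >= 3 targets)
  competitive_hit     enriched in target vs no-target AND the enrichment
                      collapses when the site-blocking competitor is present
  noncompetitive_hit  enriched in target vs no-target AND still enriched
                      with the competitor present
  non_hit             everything else

Without a competitor arm the two hit classes merge into ``target_hit``.
The positive training examples (PTEs) for the ML stage are the competitive
hits when a competitor arm exists, else the target hits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .del_decode import CountTable
from .synthetic_del import EncodedLibrary

CLASSES = (
    "matrix_binder",
    "promiscuous_binder",
    "competitive_hit",
    "noncompetitive_hit",
    "target_hit",
    "non_hit",
)


@dataclass
class Thresholds:
    """Hit-calling knobs.

    ``z_star``: enrichment z-score cutoff (default 6 — conservative, keeps
    the family-wise false-positive rate negligible across thousands of
    disynthons without formal FDR control).
    ``min_k``: minimum unique count in the selected condition (guards
    against singleton artifacts).
    ``competitor_relief``: "not enriched with competitor" means
    z_competitor < competitor_relief * z_star.
    ``promiscuity_fraction``: fraction of panel targets that must show
    enrichment for the promiscuous class.
    """

    z_star: float = 6.0
    min_k: int = 5
    pseudocount: float = 0.5
    competitor_relief: float = 0.5
    promiscuity_fraction: float = 0.5


def aggregate_disynthons(counts: CountTable, n_cycles: int) -> pd.DataFrame:
    """Sum member unique counts into disynthon rows.

    Disynthon key format: ``"i,j:blockA|blockB"`` where (i, j) is the
    ordered cycle pair.  A 2-cycle library aggregates to itself (one view);
    a 3-cycle member contributes its full count to each of its 3 views.

    Returns a DataFrame (library_id, disynthon, condition, unique_count).
    """
    df = counts.df
    if df.empty:
        return pd.DataFrame(columns=["library_id", "disynthon", "condition", "unique_count"])
    split = df["blocks"].str.split("|", expand=True)
    pieces = []
    for i, j in combinations(range(n_cycles), 2):
        part = pd.DataFrame(
            {
                "library_id": df["library_id"],
                "disynthon": f"{i + 1},{j + 1}:" + split[i] + "|" + split[j],
                "condition": df["condition"],
                "unique_count": df["unique_count"],
            }
        )
        pieces.append(part)
    out = (
        pd.concat(pieces, ignore_index=True)
        .groupby(["library_id", "disynthon", "condition"], as_index=False)["unique_count"]
        .sum()
    )
    return out


def enrichment_statistic(
    k_sel, n_sel, k_ref, n_ref, pseudocount: float = 0.5
):
    """Pseudocounted two-proportion z-score (vectorized).

    p_i = (k_i + c) / (N_i + c); z = (p_sel - p_ref) / sqrt(pbar (1-pbar)
    (1/N_sel + 1/N_ref)) with the pooled pbar also pseudocounted.  Swapping
    the selected and reference roles negates z.
    """
    k_sel = np.asarray(k_sel, dtype=float)
    k_ref = np.asarray(k_ref, dtype=float)
    n_sel = np.asarray(n_sel, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    if np.any(n_sel <= 0) or np.any(n_ref <= 0):
        raise ValueError("condition totals must be positive")
    c = pseudocount
    p_sel = (k_sel + c) / (n_sel + c)
    p_ref = (k_ref + c) / (n_ref + c)
    pbar = (k_sel + k_ref + 2 * c) / (n_sel + n_ref + 2 * c)
    se = np.sqrt(pbar * (1.0 - pbar) * (1.0 / n_sel + 1.0 / n_ref))
    z = (p_sel - p_ref) / se
    return float(z) if z.ndim == 0 else z


def all_disynthon_keys(lib: EncodedLibrary) -> pd.DataFrame:
    """Every disynthon key of a library, including those with zero reads."""
    keys = set()
    for m in lib.members:
        for i, j in combinations(range(lib.n_cycles), 2):
            keys.add(f"{i + 1},{j + 1}:{m.block_ids[i]}|{m.block_ids[j]}")
    return pd.DataFrame(
        {"library_id": lib.library_id, "disynthon": sorted(keys)}
    )


def _condition_matrix(disynthons: pd.DataFrame) -> pd.DataFrame:
    wide = disynthons.pivot_table(
        index=["library_id", "disynthon"],
        columns="condition",
        values="unique_count",
        fill_value=0,
        aggfunc="sum",
    )
    wide.columns.name = None
    return wide.reset_index()


def assign_classes(
    disynthons: pd.DataFrame,
    thresholds: Thresholds | None = None,
    panel: dict[str, pd.DataFrame] | None = None,
    input_pool: pd.DataFrame | None = None,
    all_keys: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label every disynthon with exactly one of the five classes.

    ``disynthons`` is the long table from :func:`aggregate_disynthons` and
    must contain ``no_target`` and ``target`` conditions; a
    ``target_plus_competitor`` condition is optional (without it the hit
    classes merge into ``target_hit``).  ``input_pool`` optionally gives
    pre-selection disynthon counts as the matrix-binder reference; absent
    that, a uniform pool is assumed.  ``panel`` maps other target names to
    their disynthon tables for promiscuity calling (needs >= 3 targets
    total).

    Returns a wide DataFrame with per-condition counts, z-scores, the class
    and the PTE flag.
    """
    th = thresholds or Thresholds()
    wide = _condition_matrix(disynthons)
    if all_keys is not None:
        # include disynthons that never produced a read (they can only be non_hit)
        wide = all_keys.merge(wide, on=["library_id", "disynthon"], how="left").fillna(0)
    for required in ("no_target", "target"):
        if required not in wide.columns:
            raise ValueError(f"missing required condition {required!r}")
    has_comp = "target_plus_competitor" in wide.columns

    n_no = wide["no_target"].sum()
    n_t = wide["target"].sum()
    wide["z_target"] = enrichment_statistic(
        wide["target"], n_t, wide["no_target"], n_no, th.pseudocount
    )
    if has_comp:
        n_c = wide["target_plus_competitor"].sum()
        wide["z_competitor"] = enrichment_statistic(
            wide["target_plus_competitor"], n_c, wide["no_target"], n_no, th.pseudocount
        )

    # matrix reference: observed input pool, else uniform expectation
    if input_pool is not None:
        ref = wide[["library_id", "disynthon"]].merge(
            input_pool.rename(columns={"unique_count": "pool_count"}),
            on=["library_id", "disynthon"],
            how="left",
        )["pool_count"].fillna(0)
        n_pool = float(ref.sum())
    else:
        n_pool = float(n_no)
        ref = np.full(len(wide), n_pool / len(wide))
    wide["z_matrix"] = enrichment_statistic(
        wide["no_target"], n_no, ref, n_pool, th.pseudocount
    )

    enriched_target = (
        (wide["z_target"] >= th.z_star) & (wide["target"] >= th.min_k)
    ).to_numpy()
    matrix = ((wide["z_matrix"] >= th.z_star) & (wide["no_target"] >= th.min_k)).to_numpy()

    promiscuous = np.zeros(len(wide), dtype=bool)
    if panel is not None and len(panel) + 1 >= 3:
        frac = enriched_target.astype(float).copy()
        frac = pd.Series(frac)
        for other in panel.values():
            ow = _condition_matrix(other)
            oz = enrichment_statistic(
                ow["target"], ow["target"].sum(), ow["no_target"], ow["no_target"].sum(),
                th.pseudocount,
            )
            o_enriched = pd.Series(
                (oz >= th.z_star) & (ow["target"] >= th.min_k), dtype=float
            )
            okey = ow[["library_id", "disynthon"]].assign(e=o_enriched.to_numpy())
            merged = wide[["library_id", "disynthon"]].merge(
                okey, on=["library_id", "disynthon"], how="left"
            )["e"].fillna(0)
            frac += merged.to_numpy()
        frac /= len(panel) + 1
        promiscuous = frac.to_numpy() > th.promiscuity_fraction

    labels = np.full(len(wide), "non_hit", dtype=object)
    if has_comp:
        comp_relieved = (wide["z_competitor"] < th.competitor_relief * th.z_star).to_numpy()
        labels[enriched_target & comp_relieved] = "competitive_hit"
        labels[enriched_target & ~comp_relieved] = "noncompetitive_hit"
    else:
        labels[enriched_target] = "target_hit"
    labels[promiscuous] = "promiscuous_binder"
    labels[matrix] = "matrix_binder"
    wide["label"] = labels

    positive_class = "competitive_hit" if has_comp else "target_hit"
    wide["is_pte"] = wide["label"] == positive_class
    return wide


def select_ptes(
    labels: pd.DataFrame,
    lib: EncodedLibrary,
    competitor_present: bool | None = None,
) -> pd.DataFrame:
    """Expand PTE disynthons to member SMILES for featurization.

    Returns a DataFrame (member_id, smiles, disynthon).  Empty PTE sets get
    a warning — downstream model training cannot proceed without positives.
    """
    if competitor_present is None:
        competitor_present = "z_competitor" in labels.columns
    positive_class = "competitive_hit" if competitor_present else "target_hit"
    pte_keys = labels.loc[labels["label"] == positive_class, ["library_id", "disynthon"]]
    if pte_keys.empty:
        warnings.warn("empty PTE set: no positive training examples available")
        return pd.DataFrame(columns=["member_id", "smiles", "disynthon"])

    keys = set(map(tuple, pte_keys.to_numpy()))
    rows = []
    for m in lib.members:
        for i, j in combinations(range(lib.n_cycles), 2):
            key = f"{i + 1},{j + 1}:{m.block_ids[i]}|{m.block_ids[j]}"
            if (lib.library_id, key) in keys:
                rows.append({"member_id": m.member_id, "smiles": m.smiles, "disynthon": key})
    return pd.DataFrame(rows).drop_duplicates(subset=["member_id", "disynthon"]).reset_index(drop=True)


def nonhit_members(labels: pd.DataFrame, lib: EncodedLibrary) -> pd.DataFrame:
    """Members whose every disynthon view is labeled non_hit (negative pool)."""
    nonhit_keys = set(
        map(tuple, labels.loc[labels["label"] == "non_hit", ["library_id", "disynthon"]].to_numpy())
    )
    rows = []
    for m in lib.members:
        views = [
            (lib.library_id, f"{i + 1},{j + 1}:{m.block_ids[i]}|{m.block_ids[j]}")
            for i, j in combinations(range(lib.n_cycles), 2)
        ]
        if all(v in nonhit_keys for v in views):
            rows.append({"member_id": m.member_id, "smiles": m.smiles})
    return pd.DataFrame(rows)
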