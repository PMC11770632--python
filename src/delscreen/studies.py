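"""Validation studies: planted-truth recovery experiments run at desk scale.

These functions execute the full pipeline path on synthetic screens with
known ground truth and measure how well each stage recovers it.  They are
used by the test suite and the reproduction script; the scales (library
size, sequencing depth, forest size, catalog size) are chosen so a study
finishes in minutes on one CPU while keeping enough statistical headroom
to be meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import del_decode, enrichment, models, synthetic_del


def run_screen(
    lib: synthetic_del.EncodedLibrary,
    depth: int = 100_000,
    pcr_dup_rate: float = 0.2,
    seq_error_rate: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate all three arms, decode, count, aggregate, and label."""
    schema = del_decode.TagSchema.from_libraries([lib])
    decoded = {}
    for i, cond in enumerate(synthetic_del.standard_conditions()):
        rs = synthetic_del.simulate_selection(
            lib, cond, depth, pcr_dup_rate, seq_error_rate, seed=seed + i
        )
        decoded[cond.kind], _ = del_decode.decode_reads(rs, schema)
    counts = del_decode.build_count_table(decoded)
    disynthons = enrichment.aggregate_disynthons(counts, lib.n_cycles)
    return enrichment.assign_classes(
        disynthons, all_keys=enrichment.all_disynthon_keys(lib)
    )


def truth_by_disynthon(lib: synthetic_del.EncodedLibrary) -> dict[str, synthetic_del.BindingTruth]:
    """Ground-truth lookup per disynthon key (2-cycle libraries: the member)."""
    if lib.n_cycles != 2:
        raise ValueError("truth lookup implemented for 2-cycle screens")
    return {
        f"1,2:{m.block_ids[0]}|{m.block_ids[1]}": m.truth for m in lib.members
    }


def label_recovery_study(
    n_seeds: int = 10,
    blocks: tuple[int, int] = (50, 50),
    depth: int = 100_000,
    n_competitive: int = 3,
    n_noncompetitive: int = 2,
    n_matrix: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Sensitivity / specificity of the five-class labeling on planted screens.

    One screen per seed; returns per-seed rates:
    ``competitive_sensitivity`` (planted competitive members labeled
    competitive_hit), ``matrix_sensitivity``, and ``nonhit_specificity``
    (null-truth disynthons labeled non_hit).
    """
    lib0 = synthetic_del.generate_library(list(blocks), 2, seed=base_seed + 777)
    rows = []
    for s in range(n_seeds):
        lib = synthetic_del.plant_binders(
            lib0,
            n_competitive=n_competitive,
            n_noncompetitive=n_noncompetitive,
            n_matrix=n_matrix,
            seed=base_seed + 1000 + s,
        )
        labels = run_screen(lib, depth=depth, seed=base_seed + 2000 + 10 * s)
        lab = dict(zip(labels["disynthon"], labels["label"]))
        truth = truth_by_disynthon(lib)
        comp = [k for k, t in truth.items() if t.competitive]
        matrix = [k for k, t in truth.items() if t.is_matrix_binder]
        null = [
            k for k, t in truth.items()
            if t.target_affinity is None and not t.is_matrix_binder
        ]
        rows.append(
            {
                "seed": s,
                "competitive_sensitivity": np.mean(
                    [lab[k] == "competitive_hit" for k in comp]
                ),
                "matrix_sensitivity": np.mean([lab[k] == "matrix_binder" for k in matrix]),
                "nonhit_specificity": np.mean([lab[k] == "non_hit" for k in null]),
            }
        )
    return pd.DataFrame(rows)


def planted_analog_study(
    n_seeds: int = 5,
    blocks: tuple[int, int] = (100, 100),
    n_forest_models: int = 5,
    n_trees: int = 100,
    n_negatives: int = 10_000,
    catalog_size: int = 50_000,
    n_planted: int = 100,
    top_n: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Planted-analog retrieval by the forest ensemble.

    Per seed: plant competitive motifs in a library, train the forest
    ensemble on the planted truth (positives = active members, negatives =
    null members), score a synthetic catalog seeded with analogs of one
    active motif, and count planted analogs in the ensemble's top
    ``top_n``.  The random expectation is ``top_n * n_planted /
    catalog_size``.
    """
    rows = []
    for s in range(n_seeds):
        lib = synthetic_del.generate_library(list(blocks), 2, seed=base_seed + 100 + s)
        lib = synthetic_del.plant_binders(lib, n_competitive=2, seed=base_seed + 200 + s)
        pos = sorted({m.smiles for m in lib.members if m.truth.competitive})
        posset = set(pos)
        neg = [
            m.smiles
            for m in lib.members
            if m.truth.target_affinity is None and m.smiles not in posset
        ]
        frag = next(
            lib.blocks[0][m.block_indices[0]].fragment
            for m in lib.members
            if m.truth.competitive
        )
        catalog = synthetic_del.generate_catalog(
            catalog_size,
            seed=base_seed + 300 + s,
            planted_fragments=[frag],
            n_planted=n_planted,
            n_cycles=3,
        )
        sets = models.build_training_sets(
            pos, neg, n_models=n_forest_models, n_negatives=n_negatives,
            seed=base_seed + 400 + s,
        )
        scored = [models.train_forest(ts, n_trees=n_trees, seed=ts.seed) for ts in sets]
        ensemble = models.ScorerEnsemble(runs=[[sc for sc, _ in scored]])
        ranked = models.ensemble_score(ensemble, catalog)
        top = ranked.merge(catalog[["id", "is_planted"]], on="id").head(top_n)
        rows.append(
            {
                "seed": s,
                "planted_in_top": int(top["is_planted"].sum()),
                "random_expectation": top_n * n_planted / catalog_size,
                "best_test_accuracy": max(a for _, a in scored),
            }
        )
    return pd.DataFrame(rows)


def fit_recovery_study(n_seeds: int = 100, base_seed: int = 0) -> dict[str, float]:
    """Parameter recovery of the binding-model fits under realistic noise.

    Steady state (KD 18 uM, 2% noise), kinetics (ka 1e5, kd 1e-2, 2%),
    DSF (Tm 52 C, 1%); reports the median relative (or absolute, Tm)
    errors over ``n_seeds`` replicates, plus the worst noiseless residual
    across all four fit kinds.
    """
    from . import bindfit as bf

    conc = bf.dilution_series(90e-6, 3.0, 8)
    kin_design = {
        "time": np.linspace(0, 600, 301),
        "association_window": (0.0, 300.0),
        "dissociation_window": (300.0, 600.0),
        "concentrations": [1e-7, 3e-7, 1e-6, 3e-6, 1e-5],
    }
    temps = np.arange(35.0, 70.0, 1.0)
    doses = bf.dilution_series(100e-6, 3.0, 10)

    kd_err, ka_err, kdis_err, tm_err = [], [], [], []
    for s in range(n_seeds):
        ts = bf.simulate_assay(
            "steady_state", {"KD": 18e-6, "Rmax": 50.0},
            {"concentrations": conc}, noise_cv=0.02, seed=base_seed + s,
        )
        kd_err.append(abs(bf.fit_steady_state(ts)["KD"] - 18e-6) / 18e-6)
        sg = bf.simulate_assay(
            "kinetic", {"ka": 1e5, "kd": 1e-2, "Rmax": 80.0}, kin_design,
            noise_cv=0.02, seed=base_seed + 10_000 + s,
        )
        res = bf.fit_kinetic_1to1(sg)
        ka_err.append(abs(res["ka"] - 1e5) / 1e5)
        kdis_err.append(abs(res["kd"] - 1e-2) / 1e-2)
        temp, fl = bf.simulate_assay(
            "dsf", {"Tm": 52.0, "Fmin": 10, "Fmax": 90},
            {"temperatures": temps}, noise_cv=0.01, seed=base_seed + 20_000 + s,
        )
        tm_err.append(abs(bf.fit_boltzmann_tm(temp, fl)["Tm"] - 52.0))

    # noiseless residuals for every fit kind
    resids = []
    ts0 = bf.simulate_assay("steady_state", {"KD": 18e-6, "Rmax": 50.0}, {"concentrations": conc})
    resids.append(bf.fit_steady_state(ts0).residual_norm / 50.0)
    sg0 = bf.simulate_assay("kinetic", {"ka": 1e5, "kd": 1e-2, "Rmax": 80.0}, kin_design)
    resids.append(bf.fit_kinetic_1to1(sg0).residual_norm / 80.0)
    t0, f0 = bf.simulate_assay("dsf", {"Tm": 52.0, "Fmin": 10, "Fmax": 90}, {"temperatures": temps})
    resids.append(bf.fit_boltzmann_tm(t0, f0).residual_norm / 90.0)
    fp0 = bf.simulate_assay("fp", {"Kdisp": 1e-6}, {"doses": doses})
    resids.append(bf.fit_fp_displacement(fp0).residual_norm / 200.0)

    return {
        "steady_state_kd_median_rel_err": float(np.median(kd_err)),
        "kinetic_ka_median_rel_err": float(np.median(ka_err)),
        "kinetic_kd_median_rel_err": float(np.median(kdis_err)),
        "dsf_tm_median_abs_err_C": float(np.median(tm_err)),
        "max_noiseless_relative_residual": float(max(resids)),
    }
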