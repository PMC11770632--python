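"""End-to-end orchestration: simulate -> decode -> enrich -> train ->
predict -> select, with per-stage derived seeds and a reproducibility
manifest.

Every stochastic stage derives its seed from the root seed and the stage
name, so reruns from one config reproduce all artifacts.  The manifest
records per-stage row counts, seeds, and SHA-256 digests of every written
artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import del_decode, enrichment, models, selection, synthetic_del

logger = logging.getLogger("delscreen.pipeline")

STAGES = ("simulate", "decode", "enrich", "train", "predict", "select")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed."""
    return (root_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """All pipeline knobs with desk-scale defaults.

    ``profile`` picks a preset scale: ``toy`` (seconds, smoke testing) or
    ``desk`` (minutes, the scale used for validation runs).
    """

    root_seed: int = 0
    profile: str = "toy"

    # library / screen
    n_blocks_per_cycle: list[int] = field(default_factory=lambda: [10, 10])
    n_cycles: int = 2
    n_competitive_motifs: int = 2
    n_noncompetitive_motifs: int = 1
    n_matrix_binders: int = 3
    affinity_range: tuple[float, float] = (1e-7, 1e-6)
    target_concentration: float = 1e-6
    competitor_concentration: float = 1e-4
    matrix_capture_prob: float = 0.01
    depth: int = 10_000
    pcr_dup_rate: float = 0.2
    seq_error_rate: float = 0.001
    include_competitor: bool = True

    # enrichment
    z_star: float = 6.0
    min_k: int = 5

    # models
    n_forest_models: int = 2
    n_trees: int = 50
    n_negatives: int = 500

    # catalog / selection
    catalog_size: int = 2000
    n_planted_analogs: int = 20
    dise_radius: float = 0.2
    purchase_list_size: int = 50

    @classmethod
    def preset(cls, profile: str, root_seed: int = 0) -> "RunConfig":
        if profile == "toy":
            return cls(root_seed=root_seed, profile="toy")
        if profile == "desk":
            return cls(
                root_seed=root_seed,
                profile="desk",
                n_blocks_per_cycle=[50, 50],
                depth=100_000,
                n_competitive_motifs=3,
                n_noncompetitive_motifs=2,
                n_matrix_binders=10,
                n_forest_models=5,
                n_trees=100,
                n_negatives=2000,
                catalog_size=10_000,
                n_planted_analogs=50,
                purchase_list_size=100,
            )
        raise ValueError(f"unknown profile {profile!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        obj["n_blocks_per_cycle"] = list(obj["n_blocks_per_cycle"])
        obj["affinity_range"] = tuple(obj["affinity_range"])
        return cls(**obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full screen and write artifacts plus a manifest.

    Returns the manifest dict.  A stage failure raises with the stage name
    attached; artifacts of completed stages remain on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"profile": config.profile, "root_seed": config.root_seed, "stages": {}}

    def record(stage: str, seed: int | None, counts: dict, artifacts: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": seed,
            "counts": counts,
            "artifacts": {p.name: _sha256(p) for p in artifacts},
        }

    try:
        # ---- simulate -------------------------------------------------
        stage = "simulate"
        seed = stage_seed(config.root_seed, stage)
        lib = synthetic_del.generate_library(
            config.n_blocks_per_cycle, config.n_cycles, seed=seed
        )
        lib = synthetic_del.plant_binders(
            lib,
            n_competitive=config.n_competitive_motifs,
            n_noncompetitive=config.n_noncompetitive_motifs,
            n_matrix=config.n_matrix_binders,
            affinity_range=config.affinity_range,
            seed=seed + 1,
        )
        conds = synthetic_del.standard_conditions(
            target_concentration=config.target_concentration,
            competitor_concentration=config.competitor_concentration,
            matrix_capture_prob=config.matrix_capture_prob,
            include_competitor=config.include_competitor,
        )
        schema = del_decode.TagSchema.from_libraries([lib])
        artifacts = []
        readsets = {}
        for i, cond in enumerate(conds):
            rs = synthetic_del.simulate_selection(
                lib, cond, config.depth, config.pcr_dup_rate, config.seq_error_rate,
                seed=seed + 10 + i,
            )
            fq = out / f"reads_{cond.kind}.fastq"
            rs.write_fastq(fq)
            readsets[cond.kind] = rs
            artifacts.append(fq)
        lib_csv = out / "library.csv"
        lib.to_table().to_csv(lib_csv, index=False)
        schema_json = out / "schema.json"
        schema_json.write_text(json.dumps(schema.to_json(), indent=1, sort_keys=True))
        artifacts += [lib_csv, schema_json]
        record(stage, seed, {"members": lib.n_members, "reads_per_condition": config.depth}, artifacts)

        # ---- decode ---------------------------------------------------
        stage = "decode"
        decoded = {}
        rejections = {}
        for kind, rs in readsets.items():
            dec, rej = del_decode.decode_reads(rs, schema)
            decoded[kind] = dec
            rejections[kind] = rej
        counts = del_decode.build_count_table(decoded)
        counts_tsv = out / "counts.tsv"
        counts.write_tsv(counts_tsv)
        record(
            stage, None,
            {"rows": len(counts), "rejections": rejections},
            [counts_tsv],
        )

        # ---- enrich ---------------------------------------------------
        stage = "enrich"
        disynthons = enrichment.aggregate_disynthons(counts, lib.n_cycles)
        th = enrichment.Thresholds(z_star=config.z_star, min_k=config.min_k)
        labels = enrichment.assign_classes(
            disynthons, th, all_keys=enrichment.all_disynthon_keys(lib)
        )
        labels_tsv = out / "enrichment.tsv"
        labels.to_csv(labels_tsv, sep="\t", index=False)
        ptes = enrichment.select_ptes(labels, lib)
        pte_smi = out / "ptes.smi"
        with open(pte_smi, "w") as fh:
            for _, row in ptes.iterrows():
                fh.write(f"{row['smiles']} {row['member_id']}\n")
        record(
            stage, None,
            {
                "disynthons": len(labels),
                "classes": labels["label"].value_counts().to_dict(),
                "ptes": len(ptes),
            },
            [labels_tsv, pte_smi],
        )

        # ---- train ----------------------------------------------------
        stage = "train"
        seed = stage_seed(config.root_seed, stage)
        if ptes.empty:
            raise RuntimeError("no PTEs found: model training blocked")
        negatives = enrichment.nonhit_members(labels, lib)
        neg_smiles = [s for s in negatives["smiles"] if s not in set(ptes["smiles"])]
        sets = models.build_training_sets(
            ptes["smiles"].drop_duplicates().tolist(),
            neg_smiles,
            n_models=config.n_forest_models,
            n_negatives=min(config.n_negatives, len(neg_smiles)),
            seed=seed,
        )
        scored = [
            models.train_forest(ts, n_trees=config.n_trees, seed=ts.seed) for ts in sets
        ]
        manifest_models = [
            {"model_index": i, "seed": sets[i].seed, "test_accuracy": acc}
            for i, (_, acc) in enumerate(scored)
        ]
        ensemble = models.ScorerEnsemble(runs=[[s for s, _ in scored]])
        models_json = out / "models.json"
        models_json.write_text(json.dumps(manifest_models, indent=1))
        record(stage, seed, {"n_models": len(scored)}, [models_json])

        # ---- predict --------------------------------------------------
        stage = "predict"
        seed = stage_seed(config.root_seed, stage)
        planted_frag = None
        for m in lib.members:
            if m.truth.competitive:
                planted_frag = lib.blocks[0][m.block_indices[0]].fragment
                break
        catalog = synthetic_del.generate_catalog(
            config.catalog_size,
            seed=seed,
            planted_fragments=[planted_frag] if planted_frag else None,
            n_planted=config.n_planted_analogs if planted_frag else 0,
            n_cycles=3,
        )
        ranked = models.ensemble_score(ensemble, catalog)
        ranked = ranked.merge(catalog[["id", "is_planted"]], on="id")
        pred_csv = out / "predictions.csv"
        ranked.to_csv(pred_csv, index=False, float_format="%.10g")
        record(stage, seed, {"catalog": len(catalog)}, [pred_csv])

        # ---- select ---------------------------------------------------
        stage = "select"
        survivors, tally = selection.property_filter(ranked)
        purchase = selection.dise_select(
            survivors, radius=config.dise_radius, max_n=config.purchase_list_size
        )
        purchase_csv = out / "purchase_list.csv"
        purchase.to_csv(purchase_csv, index=False, float_format="%.10g")
        record(
            stage, None,
            {"survivors": len(survivors), "rejection_tally": tally, "purchased": len(purchase)},
            [purchase_csv],
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def make_fixtures(profile: str, seed: int, outdir) -> dict:
    """Write the canonical synthetic screen used by the test suite."""
    config = RunConfig.preset(profile, root_seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    return run_pipeline(config, out)
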