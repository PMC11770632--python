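# Methods

This note documents the models behind `delscreen`, the choices made where
the design was genuinely open, and what the synthetic validation does and
does not demonstrate.

## Synthetic screen model

**Library chemistry.** Libraries are split-and-pool combinatorial
assemblies over a packaged pool of 112 substituent fragments, each carrying
one attachment point. Members are formed by joining per-cycle fragments
through an amide linker scaffold (`R1-C(=O)N(CH3)-R2` for two cycles, a
bis-amide for three). This is a deliberately simple, always-valid chemistry:
the goal is SMILES that parse, fingerprint, and share substructure with
their building blocks — not synthetic realism. Tags are random unique DNA
8-mers per cycle; reads are `[12 nt UMI][per-cycle tags][10 nt constant]`,
all lengths configurable.

**Selection.** One selection cycle captures a member with probability

    θ = occupancy + matrix_term,  clamped to 1
    occupancy = [T] / ([T] + KD_eff)

with `KD_eff = KD` except for competitive binders in the competitor arm,
where `KD_eff = KD · (1 + [C]/KD_comp)`. Two cycles give weight θ². This is
the simplest physical picture consistent with equilibrium capture and
independent cycles; wash kinetics, bead chemistry, and avidity are not
modeled.

Defaults defining the standard study conditions: target 1 µM; planted
affinities log-uniform in 0.1–1 µM (so occupancy 0.5–0.9 per cycle);
baseline nonspecific (matrix) capture probability 0.01, giving planted
binders a ≥50× single-cycle occupancy advantage over background; competitor
at 100 µM with `KD_comp = 0.1 µM`. The competitor constant is chosen so the
inhibition factor (~10³) saturates the *entire* planted affinity range: the
planted `competitive` flag means "displaced by the competitor", and a weaker
competitor would leave the strongest planted binders with ~10% residual
occupancy, silently breaking that contract. Matrix binders capture at
`50 × baseline` (clamped): matrix binding must exceed the background that
every DNA-linked molecule experiences, or the no-target control could not
reveal it; the factor 50 mirrors the occupancy advantage given to planted
target binders.

**Sequencing.** Surviving molecules are drawn multinomially with weights
θ²; each pre-PCR molecule receives a UMI (base-4 encoding of its index —
collision-free by construction, which makes UMI-count conservation exact),
is amplified to `1 + Geometric(pcr_dup_rate)` read copies, and every read
base is substituted at `seq_error_rate` with a uniformly chosen different
base. Exactly the requested depth is emitted. The simulator keeps a ledger
of pre-PCR molecules per member; at zero error and zero duplication the
decoder must reproduce it exactly, which is the strongest invariant the
decode stage is tested against.

What this generator does **not** emulate: sequence-dependent PCR bias,
quality-score structure, tag synthesis errors, library yield differences,
chimeric reads, and trisynthon-specific chemistry. Passing tests therefore
demonstrate the correctness of the analysis logic under the stated
statistical model, not performance on any real screening platform.

## Decoding

Strict exact-match decoding: a read is kept only if its constant region and
every cycle tag match the schema exactly; rejects are tallied by reason
(length, bad constant, unknown tag). Discarding, rather than correcting,
error-containing reads is the conservative convention for counting
applications. An optional single-mismatch rescue mode exists but refuses to
run unless the schema's minimum inter-tag Hamming distance is ≥ 3.
Deduplication key is (UMI, full block tuple); counts are normalized to
reads-per-million within each (library, condition).

## Enrichment and labeling

The enrichment statistic is a two-proportion z-score with pseudocount
c = 0.5 on both proportions and the pooled estimate. The field's production
systems use proprietary statistics; a pseudocounted z was chosen because it
is symmetric, finite at zero counts, and monotone in the selected count.
Default cutoff `z* = 6` with a minimum selected count of 5: across ~10³–10⁴
disynthons this keeps the family-wise false-positive rate negligible
without formal FDR machinery, at the cost of sensitivity to weakly enriched
disynthons — an accepted trade in hit-calling, where precision of the
positive class matters most.

Class precedence is matrix > promiscuous > competitive > noncompetitive >
non-hit. "Not enriched in the competitor arm" is operationalized as
`z_comp < z*/2`; the boundary between competitive and noncompetitive is the
least sharp part of the labeling and members near the threshold can swap
between the two hit classes. The matrix-binder reference is the observed
input pool when provided, else a uniform expectation. Promiscuity requires
a panel of ≥ 3 targets and is unreachable in single-target runs.

## Models

Forests: scikit-learn `RandomForestClassifier`, features Morgan radius 2 /
1024 bits, defaults `n_estimators = 2000`, `min_samples_split = 5`; each of
the (default 30) models resamples its own negatives and positives, splits
90/10 stratified, doubles positives in the training partition only, and the
model with the best holdout accuracy serves inference. The forest score is
the fraction of trees voting positive.

The fingerprint DNN is a (2000, 100) ReLU MLP on Morgan radius-3 / 2048-bit
features trained by mini-batch SGD (batch 128) on log-loss, with
checkpoints every `checkpoint_every` steps; the checkpoint with the highest
`top_100_actives` on a disjoint tuning set is selected. Optimizer, batch
size, and loss are this package's defaults — the production systems this
emulates do not pin them. Graph-convolutional models are deliberately not
re-implemented (they are defined by external, accelerator-scale systems);
any object with `score(smiles) -> array` plugs into the ensembling, V2.1
filtering, and hit-expansion stages, and the fingerprint DNN plays that
role in tests.

Ensembling is median-of-replicas within a run, then median-over-runs;
`top_100_actives` breaks score ties by stable input order.

## Selection

DISE "radius" is interpreted as a Tanimoto **distance** cutoff
(1 − similarity), the standard sphere-exclusion convention; candidates are
scanned in descending model score and kept iff strictly farther than the
radius from every kept compound. Property-filter defaults (MW 250–550,
17–40 heavy atoms, elements C/N/O/S/F/Cl/Br/H) are conventional drug-like
windows, fully configurable, since no canonical rule set exists for this
step. Hit expansion filters the catalog at ECFP6 similarity strictly above
the threshold (default 0.35), ranks by the model score (similarity to the
hit when no model is supplied), and diversifies by DISE at radius 0.2.

## Binding fits

All fits are least squares (SciPy) on the closed forms in the module
docstring. Kinetic fits are global across concentrations with shared
(ka, kd, Rmax) and per-curve dissociation amplitudes, parameterized in log
space to enforce positivity; standard errors come from the Jacobian at the
optimum. Degenerate-data flags: steady-state fits with `KD > 50·Cmax` are
marked non-converged (no curvature — the data cannot bound KD);
dissociation windows with `kd·t < 0.01` flag unobservable decay and
infinite rate-constant errors; FP curves with < 20% dynamic range are
non-displacing. `Kdisp` is reported as the logistic IC50; Cheng–Prusoff
conversion to Ki is a separate helper because it needs the probe's KD and
concentration. The selectivity matrix normalizes replicate-mean responses
to the theoretical saturation response (surface capacity × analyte/ligand
mass ratio), clamped to [0, 120]% with an over-range flag; the exact
normalization convention behind published selectivity panels is not
standardized, so it is isolated in one function.

## Validation scales

The studies in `delscreen.studies` (used by the test suite and
`scripts/acceptance.py`) run at desk scale, chosen so the full suite
completes in minutes on one CPU while keeping clear statistical headroom:

* Label recovery: 50×50 two-cycle screens, depth 10⁵ reads per arm, 3
  competitive + 2 noncompetitive motifs + 10 matrix binders, 10 seeds.
* Planted-analog retrieval: 100×100 library, 5 forests × 100 trees, 10⁴
  negatives, 5×10⁴-compound catalog with 100 planted analogs sharing an
  active motif's fragment, 5 seeds. Training positives/negatives come from
  the planted truth, isolating model behavior from labeling noise.
* Fit recovery: 100 noisy replicates per assay (2% CV for SPR forms, 1%
  for DSF), plus noiseless inversion of all four fit kinds.

## Known limitations

* The 2-cycle "disynthon" is the member itself; trisynthon-level calling
  and cross-library disynthon pooling are out of scope.
* No FDR control across disynthons; the z* threshold is deliberately
  conservative instead.
* The DNN is CPU-scale; production-scale step counts (10⁶ steps) are
  defaults in the signature but tests and studies use scaled-down runs.
* Selectivity normalization and the competitive/noncompetitive boundary are
  interpretations, each isolated behind a single function/threshold.
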