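"""Synthetic DNA-encoded library (DEL) screens.

Generates seeded combinatorial libraries, plants ground-truth binders, and
simulates affinity selection plus sequencing so that the downstream decode /
enrichment / ML stages can be exercised and validated against known truth.

The selection model is a simple equilibrium-occupancy picture: a library
member with dissociation constant ``KD`` is captured in one selection cycle
with probability

    theta = [T] / ([T] + KD_eff) + matrix_term        (clamped to 1)

where ``[T]`` is the target concentration and ``KD_eff`` inflates to
``KD * (1 + [C]/KD_comp)`` for competitive binders when a site-blocking
competitor at concentration ``[C]`` is present.  Members that bind the
capture matrix rather than the target survive through an elevated
``matrix_term``; everything else survives only through the baseline
nonspecific capture probability.  Two independent selection cycles give a
``theta**2`` survival weight.  Surviving molecules are drawn multinomially,
PCR-duplicated geometrically, and emitted as FASTQ-style reads with per-base
substitution errors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("delscreen.synthetic_del")

# ---------------------------------------------------------------------------
# Defaults of the synthetic platform (all configurable at call sites)
# ---------------------------------------------------------------------------

UMI_LENGTH = 12
TAG_LENGTH = 8
CONSTANT_REGION = "GTCAGGTCAG"  # 10 nt 3' constant region
DNA_ALPHABET = "ACGT"

#: Competitor dissociation constant used by the competitive-inhibition model
#: (molar).  The competitor emulates a tight site-blocking ligand (e.g. a
#: native peptide), so at the default working concentration the inhibition
#: factor 1 + [C]/KD_comp is saturating relative to the planted affinity
#: range — the "displaced by competitor" truth flag then means what it says
#: even for the strongest planted binders.
KD_COMPETITOR = 1e-7

#: Capture-probability multiplier for matrix binders relative to the
#: baseline nonspecific capture probability of the condition.  Matrix
#: binders stick to the resin itself, so their survival must exceed the
#: background for the no-target control to reveal them.
MATRIX_BINDER_BOOST = 50.0

#: Substituent pool used as building-block side chains.  Each entry carries
#: exactly one attachment point and was verified to assemble into valid
#: molecules through the amide linker templates below.
FRAGMENT_POOL: list[str] = [
    '[*]C', '[*]CC', '[*]CCC', '[*]C(C)C', '[*]CCCC', '[*]C(C)(C)C',
    '[*]C1CC1', '[*]C1CCC1', '[*]C1CCCC1', '[*]C1CCCCC1', '[*]CC1CC1', '[*]CC(C)C',
    '[*]C(F)(F)F', '[*]CF', '[*]CCF', '[*]CC(F)F', '[*]CCl', '[*]CCCl',
    '[*]CBr', '[*]CCBr', '[*]C(F)F', '[*]COC', '[*]CCOC', '[*]COCC',
    '[*]CCOCC', '[*]CCO', '[*]CO', '[*]C1CCOCC1', '[*]C1CCOC1', '[*]COC1CC1',
    '[*]CN(C)C', '[*]CCN(C)C', '[*]CN1CCCC1', '[*]CN1CCOCC1', '[*]CCN1CCCC1', '[*]CC#N',
    '[*]CCC#N', '[*]c1ccccc1', '[*]c1ccccc1C', '[*]c1ccccc1F', '[*]c1ccccc1Cl', '[*]c1ccccc1OC',
    '[*]c1ccc(C)cc1', '[*]c1ccc(F)cc1', '[*]c1ccc(Cl)cc1', '[*]c1ccc(Br)cc1', '[*]c1ccc(OC)cc1', '[*]c1ccc(C(F)(F)F)cc1',
    '[*]c1ccc(C#N)cc1', '[*]c1cccc(F)c1', '[*]c1cccc(Cl)c1', '[*]c1cccc(OC)c1', '[*]c1cccc(C)c1', '[*]c1ccc(CC)cc1',
    '[*]c1ccc(F)c(F)c1', '[*]c1ccc(Cl)c(Cl)c1', '[*]c1ccc(C)c(C)c1', '[*]Cc1ccccc1', '[*]CCc1ccccc1', '[*]Cc1ccc(F)cc1',
    '[*]Cc1ccc(OC)cc1', '[*]Cc1ccc(Cl)cc1', '[*]c1ccncc1', '[*]c1cccnc1', '[*]c1ccccn1', '[*]c1ccco1',
    '[*]c1cccs1', '[*]c1ccc(C)o1', '[*]c1ccc(C)s1', '[*]c1cnccn1', '[*]c1ccnnc1', '[*]c1cn(C)cn1',
    '[*]c1csc(C)n1', '[*]c1nc(C)cs1', '[*]c1ccc2ccccc2c1', '[*]c1ccc(C)nc1', '[*]c1ccc(F)cn1', '[*]c1ccc(OC)nc1',
    '[*]Cc1ccncc1', '[*]Cc1cccnc1', '[*]Cc1ccco1', '[*]Cc1cccs1', '[*]c1cnn(C)c1', '[*]c1ccn(C)c1',
    '[*]c1cnc(C)s1', '[*]CC(=O)OC', '[*]CCC(=O)OC', '[*]CC(=O)N(C)C', '[*]CS(C)(=O)=O', '[*]CCS(C)(=O)=O',
    '[*]CC(C)O', '[*]CCCO', '[*]C(C)CO', '[*]CC(F)(F)F', '[*]CCOC(C)C', '[*]C1CCNCC1',
    '[*]CC1CCOCC1', '[*]CC1CCCCC1', '[*]C1CCCO1', '[*]C=C', '[*]CC=C', '[*]C#C',
    '[*]CC#C', '[*]C(C)CC', '[*]CC(C)CC', '[*]C(CC)CC', '[*]CCCCC', '[*]CCCCCC',
    '[*]C1CC2CCC1CC2', '[*]CC(C)(C)O', '[*]C(C)c1ccccc1', '[*]CCOCCO',
]

#: Amide linker scaffolds joining the per-cycle side chains.
ASSEMBLY_CORES = {
    2: "[*:1]C(=O)N(C)[*:2]",
    3: "[*:1]C(=O)N([*:2])CC(=O)N(C)[*:3]",
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BuildingBlock:
    """One synthon: a side-chain fragment plus its DNA tag."""

    id: str
    cycle: int          # 1-based synthesis cycle
    fragment: str       # SMILES with exactly one [*] attachment point
    tag: str            # DNA tag, fixed length per cycle


@dataclass
class BindingTruth:
    """Planted ground truth for one library member."""

    target_affinity: float | None = None   # KD in molar, None = non-binder
    is_matrix_binder: bool = False
    is_promiscuous: bool = False
    competitive: bool = False              # displaced by the competitor

    def __post_init__(self) -> None:
        if self.competitive and self.target_affinity is None:
            raise ValueError("competitive binders must carry a target affinity")


@dataclass
class LibraryMember:
    member_id: str
    block_ids: tuple[str, ...]
    block_indices: tuple[int, ...]  # per-cycle index into lib.blocks[cycle]
    smiles: str
    tag: str                        # concatenated per-cycle tags
    truth: BindingTruth = field(default_factory=BindingTruth)


@dataclass
class EncodedLibrary:
    """A split-and-pool combinatorial library with DNA encoding."""

    library_id: str
    n_cycles: int
    blocks: list[list[BuildingBlock]]   # blocks[c] = building blocks of cycle c+1
    members: list[LibraryMember]
    seed: int | None = None

    def __post_init__(self) -> None:
        expected = int(np.prod([len(b) for b in self.blocks]))
        if len(self.members) != expected:
            raise ValueError(
                f"member count {len(self.members)} != product of block counts {expected}"
            )

    @property
    def n_members(self) -> int:
        return len(self.members)

    def tag_maps(self) -> list[dict[str, str]]:
        """Per-cycle tag -> block-id maps."""
        return [{b.tag: b.id for b in cyc} for cyc in self.blocks]

    def to_table(self):
        """Member table as a pandas DataFrame (one row per member)."""
        import pandas as pd

        rows = []
        for m in self.members:
            row = {
                "library_id": self.library_id,
                "member_id": m.member_id,
                "smiles": m.smiles,
                "tag": m.tag,
                "target_affinity": m.truth.target_affinity,
                "is_matrix_binder": m.truth.is_matrix_binder,
                "is_promiscuous": m.truth.is_promiscuous,
                "competitive": m.truth.competitive,
            }
            for c, bid in enumerate(m.block_ids, 1):
                row[f"block_{c}"] = bid
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SelectionCondition:
    """One parallel selection arm.

    ``matrix_capture_prob`` is the baseline probability that any DNA-linked
    molecule sticks nonspecifically to the capture resin in one cycle.
    """

    kind: str                                # no_target | target | target_plus_competitor
    target_concentration: float = 0.0        # molar
    competitor_concentration: float = 0.0    # molar
    matrix_capture_prob: float = 0.01
    n_cycles_of_selection: int = 2

    _KINDS = ("no_target", "target", "target_plus_competitor")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown condition kind {self.kind!r}")
        if self.kind == "no_target" and self.target_concentration != 0:
            raise ValueError("no_target condition must have target_concentration = 0")
        if not 0.0 <= self.matrix_capture_prob <= 1.0:
            raise ValueError("matrix_capture_prob must lie in [0, 1]")


@dataclass
class ReadSet:
    """Sequencing output of one selection arm.

    Read layout: ``[UMI][cycle-1 tag][cycle-2 tag][(cycle-3 tag)][constant]``.
    ``ledger`` records, per member index, the number of pre-PCR unique
    molecules that produced reads — the ground truth the decoder should
    recover at zero sequencing error.
    """

    sequences: list[str]
    library_id: str
    condition: str
    seed: int
    umi_length: int = UMI_LENGTH
    ledger: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def write_fastq(self, path) -> None:
        qual = "I" * (len(self.sequences[0]) if self.sequences else 0)
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences):
                fh.write(f"@{self.library_id}:{self.condition}:r{i}\n{seq}\n+\n{qual}\n")

    @classmethod
    def read_fastq(cls, path, library_id: str = "", condition: str = "") -> "ReadSet":
        from Bio import SeqIO

        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
        return cls(sequences=seqs, library_id=library_id, condition=condition, seed=-1)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _random_unique_tags(n: int, length: int, rng: np.random.Generator) -> list[str]:
    tags: list[str] = []
    seen: set[str] = set()
    while len(tags) < n:
        draw = rng.integers(0, 4, size=(n, length))
        for row in draw:
            t = "".join(DNA_ALPHABET[i] for i in row)
            if t not in seen:
                seen.add(t)
                tags.append(t)
                if len(tags) == n:
                    break
    return tags


def assemble_member(fragments: list[str]) -> str:
    """Join per-cycle side chains through the amide linker scaffold."""
    core = ASSEMBLY_CORES[len(fragments)]
    mol = Chem.MolFromSmiles(core)
    for i, frag in enumerate(fragments, 1):
        fmol = Chem.MolFromSmiles(frag.replace("[*]", f"[*:{i}]"))
        if fmol is None:
            raise ValueError(f"unparseable fragment SMILES: {frag!r}")
        mol = rdmolops.CombineMols(mol, fmol)
    out = Chem.molzip(mol)
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_library(
    n_blocks_per_cycle: list[int],
    n_cycles: int,
    seed: int,
    library_id: str = "L01",
    tag_length: int = TAG_LENGTH,
) -> EncodedLibrary:
    """Build a random split-and-pool encoded library.

    Deterministic for a fixed seed; every member SMILES is chemically valid
    (RDKit-parseable) and every concatenated tag decodes uniquely back to its
    building-block tuple.
    """
    if n_cycles not in (2, 3):
        raise ValueError("n_cycles must be 2 or 3")
    if len(n_blocks_per_cycle) != n_cycles:
        raise ValueError("n_blocks_per_cycle length must equal n_cycles")
    if any(n < 2 for n in n_blocks_per_cycle):
        raise ValueError("need at least 2 building blocks per cycle")
    if any(n > len(FRAGMENT_POOL) for n in n_blocks_per_cycle):
        raise ValueError(
            f"block count exceeds fragment pool size ({len(FRAGMENT_POOL)})"
        )

    rng = np.random.default_rng(seed)
    blocks: list[list[BuildingBlock]] = []
    for cycle in range(1, n_cycles + 1):
        n = n_blocks_per_cycle[cycle - 1]
        frag_idx = rng.choice(len(FRAGMENT_POOL), size=n, replace=False)
        tags = _random_unique_tags(n, tag_length, rng)
        blocks.append(
            [
                BuildingBlock(
                    id=f"c{cycle}b{j:03d}",
                    cycle=cycle,
                    fragment=FRAGMENT_POOL[int(frag_idx[j])],
                    tag=tags[j],
                )
                for j in range(n)
            ]
        )

    members: list[LibraryMember] = []
    shape = tuple(n_blocks_per_cycle)
    for flat in range(int(np.prod(shape))):
        idx = np.unravel_index(flat, shape)
        chosen = [blocks[c][int(idx[c])] for c in range(n_cycles)]
        smiles = assemble_member([b.fragment for b in chosen])
        members.append(
            LibraryMember(
                member_id=f"{library_id}m{flat:06d}",
                block_ids=tuple(b.id for b in chosen),
                block_indices=tuple(int(i) for i in idx),
                smiles=smiles,
                tag="".join(b.tag for b in chosen),
            )
        )
    return EncodedLibrary(
        library_id=library_id, n_cycles=n_cycles, blocks=blocks, members=members, seed=seed
    )


# ---------------------------------------------------------------------------
# Planting ground-truth binders
# ---------------------------------------------------------------------------

def _motif_members(lib: EncodedLibrary, motif: tuple[int, ...]) -> list[int]:
    """Member indices sharing fixed blocks in all cycles but the last.

    A motif fixes one block per cycle for cycles 1..n-1 and leaves the final
    cycle free: a single synthon in a 2-cycle library, a disynthon in a
    3-cycle library.
    """
    out = []
    for i, m in enumerate(lib.members):
        if m.block_indices[: lib.n_cycles - 1] == motif:
            out.append(i)
    return out


def plant_binders(
    lib: EncodedLibrary,
    n_competitive: int = 0,
    n_noncompetitive: int = 0,
    n_matrix: int = 0,
    n_promiscuous: int = 0,
    affinity_range: tuple[float, float] = (1e-7, 1e-6),
    motif_mode: bool = True,
    seed: int = 0,
) -> EncodedLibrary:
    """Return a copy of ``lib`` with ground-truth binding roles planted.

    In ``motif_mode`` the competitive / noncompetitive / promiscuous counts
    refer to *motifs* (all-but-last-cycle block combinations) so every member
    sharing the motif inherits the planted affinity — this is what makes
    disynthon aggregation downstream meaningful.  Matrix binders are always
    individual members (resin stickiness is a whole-molecule property).

    Role collisions are resolved by precedence matrix > promiscuous >
    competitive > noncompetitive (the earlier assignment wins, logged).
    """
    rng = np.random.default_rng(seed)
    members = [replace(m, truth=BindingTruth()) for m in lib.members]
    lo, hi = affinity_range
    if not (0 < lo <= hi):
        raise ValueError("affinity_range must satisfy 0 < lo <= hi")

    def draw_kd() -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    assigned: set[int] = set()

    # matrix binders first (highest precedence): individual members
    if n_matrix > lib.n_members:
        raise ValueError("more matrix binders requested than members")
    for i in rng.choice(lib.n_members, size=n_matrix, replace=False):
        members[int(i)].truth = BindingTruth(is_matrix_binder=True)
        assigned.add(int(i))

    def plant_role(n_motifs: int, make_truth) -> None:
        if n_motifs == 0:
            return
        if motif_mode:
            prefix_shape = tuple(len(b) for b in lib.blocks[:-1])
            n_prefix = int(np.prod(prefix_shape))
            order = rng.permutation(n_prefix)
            planted = 0
            for flat in order:
                if planted == n_motifs:
                    break
                motif = tuple(int(x) for x in np.unravel_index(int(flat), prefix_shape))
                kd = draw_kd()
                for i in _motif_members(lib, motif):
                    if i in assigned:
                        logger.info(
                            "member %s already assigned; precedence keeps earlier role",
                            lib.members[i].member_id,
                        )
                        continue
                    members[i].truth = make_truth(kd)
                    assigned.add(i)
                planted += 1
            if planted < n_motifs:
                raise ValueError("not enough free motifs to plant")
        else:
            free = [i for i in range(lib.n_members) if i not in assigned]
            if n_motifs > len(free):
                raise ValueError("not enough free members to plant")
            for i in rng.choice(free, size=n_motifs, replace=False):
                members[int(i)].truth = make_truth(draw_kd())
                assigned.add(int(i))

    plant_role(n_promiscuous, lambda kd: BindingTruth(target_affinity=kd, is_promiscuous=True))
    plant_role(n_competitive, lambda kd: BindingTruth(target_affinity=kd, competitive=True))
    plant_role(n_noncompetitive, lambda kd: BindingTruth(target_affinity=kd))

    return EncodedLibrary(
        library_id=lib.library_id,
        n_cycles=lib.n_cycles,
        blocks=lib.blocks,
        members=members,
        seed=lib.seed,
    )


# ---------------------------------------------------------------------------
# Selection + sequencing simulation
# ---------------------------------------------------------------------------

def capture_probabilities(
    lib: EncodedLibrary,
    cond: SelectionCondition,
    kd_comp: float = KD_COMPETITOR,
    matrix_binder_boost: float = MATRIX_BINDER_BOOST,
) -> np.ndarray:
    """Per-member single-cycle capture probability theta."""
    n = lib.n_members
    theta = np.zeros(n)
    t_conc = cond.target_concentration
    for i, m in enumerate(lib.members):
        tr = m.truth
        matrix_term = cond.matrix_capture_prob
        if tr.is_matrix_binder:
            matrix_term = min(1.0, cond.matrix_capture_prob * matrix_binder_boost)
        occ = 0.0
        if tr.target_affinity is not None and t_conc > 0:
            kd_eff = tr.target_affinity
            if (
                tr.competitive
                and cond.kind == "target_plus_competitor"
                and cond.competitor_concentration > 0
            ):
                kd_eff = kd_eff * (1.0 + cond.competitor_concentration / kd_comp)
            occ = t_conc / (t_conc + kd_eff)
        theta[i] = min(1.0, occ + matrix_term)
    return theta


def _encode_umis(indices: np.ndarray, length: int) -> np.ndarray:
    """Base-4 encode molecule indices as DNA of fixed length (unique by construction)."""
    n = indices.shape[0]
    digits = np.empty((n, length), dtype=np.uint8)
    x = indices.astype(np.int64).copy()
    for pos in range(length - 1, -1, -1):
        digits[:, pos] = x % 4
        x //= 4
    return digits


_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_selection(
    lib: EncodedLibrary,
    cond: SelectionCondition,
    depth: int,
    pcr_dup_rate: float = 0.0,
    seq_error_rate: float = 0.0,
    seed: int = 0,
    kd_comp: float = KD_COMPETITOR,
    matrix_binder_boost: float = MATRIX_BINDER_BOOST,
    umi_length: int = UMI_LENGTH,
    constant_region: str = CONSTANT_REGION,
) -> ReadSet:
    """Simulate one selection arm and return its sequencing reads.

    Molecules surviving ``n_cycles_of_selection`` rounds (weight theta**c)
    are sampled multinomially, each pre-PCR molecule receives a unique UMI,
    is amplified to ``1 + Geometric(pcr_dup_rate)`` read copies, and every
    emitted read is mutated per-base at ``seq_error_rate``.  Exactly
    ``depth`` reads are returned (the final molecule's copies truncated).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if not (0.0 <= pcr_dup_rate < 1.0) or not (0.0 <= seq_error_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    if depth == 0:
        warnings.warn("depth 0 requested: returning empty ReadSet")
        return ReadSet([], lib.library_id, cond.kind, seed, umi_length, {})

    rng = np.random.default_rng(seed)
    theta = capture_probabilities(lib, cond, kd_comp, matrix_binder_boost)
    weights = theta ** cond.n_cycles_of_selection
    total = weights.sum()
    if total == 0:
        raise ValueError("no member has a positive survival probability")
    probs = weights / total

    # draw pre-PCR molecules until their amplified copies cover `depth` reads
    mol_members: list[np.ndarray] = []
    mol_copies: list[np.ndarray] = []
    covered = 0
    while covered < depth:
        batch = max(1024, int((depth - covered) * (1.0 - pcr_dup_rate)) + 1)
        mem = rng.choice(lib.n_members, size=batch, p=probs)
        cop = (
            rng.geometric(1.0 - pcr_dup_rate, size=batch)
            if pcr_dup_rate > 0
            else np.ones(batch, dtype=np.int64)
        )
        mol_members.append(mem)
        mol_copies.append(cop)
        covered += int(cop.sum())
    members_arr = np.concatenate(mol_members)
    copies_arr = np.concatenate(mol_copies)
    cum = np.cumsum(copies_arr)
    n_mol = int(np.searchsorted(cum, depth) + 1)
    members_arr = members_arr[:n_mol]
    copies_arr = copies_arr[:n_mol].copy()
    copies_arr[-1] -= int(cum[n_mol - 1] - depth)  # truncate final molecule

    ledger: dict[int, int] = {}
    for mi in members_arr:
        ledger[int(mi)] = ledger.get(int(mi), 0) + 1

    # assemble reads as a byte matrix: [UMI][tags][constant]
    tag_len = len(lib.members[0].tag)
    read_len = umi_length + tag_len + len(constant_region)
    read_member = np.repeat(members_arr, copies_arr)
    read_molidx = np.repeat(np.arange(n_mol), copies_arr)

    mat = np.empty((depth, read_len), dtype=np.uint8)
    umi_digits = _encode_umis(read_molidx, umi_length)
    mat[:, :umi_length] = _BASE_LUT[umi_digits]
    member_tags = np.array(
        [m.tag for m in lib.members], dtype=f"S{tag_len}"
    ).view(np.uint8).reshape(lib.n_members, tag_len)
    mat[:, umi_length : umi_length + tag_len] = member_tags[read_member]
    const_bytes = np.frombuffer(constant_region.encode(), dtype=np.uint8)
    mat[:, umi_length + tag_len :] = const_bytes

    if seq_error_rate > 0:
        err_mask = rng.random((depth, read_len)) < seq_error_rate
        n_err = int(err_mask.sum())
        if n_err:
            # substitute with a uniformly chosen *different* base
            cur = mat[err_mask]
            # map A,C,G,T -> 0..3
            code = np.zeros(256, dtype=np.uint8)
            code[_BASE_LUT] = np.arange(4, dtype=np.uint8)
            shifted = (code[cur] + rng.integers(1, 4, size=n_err)) % 4
            mat[err_mask] = _BASE_LUT[shifted]

    sequences = [row.tobytes().decode() for row in mat]
    return ReadSet(
        sequences=sequences,
        library_id=lib.library_id,
        condition=cond.kind,
        seed=seed,
        umi_length=umi_length,
        ledger=ledger,
    )


def standard_conditions(
    target_concentration: float = 1e-6,
    competitor_concentration: float = 1e-4,
    matrix_capture_prob: float = 0.01,
    n_cycles_of_selection: int = 2,
    include_competitor: bool = True,
) -> list[SelectionCondition]:
    """The parallel selection arms of one screen: no-target control, target,
    and (optionally) target plus site-blocking competitor."""
    conds = [
        SelectionCondition(
            "no_target",
            0.0,
            0.0,
            matrix_capture_prob,
            n_cycles_of_selection,
        ),
        SelectionCondition(
            "target",
            target_concentration,
            0.0,
            matrix_capture_prob,
            n_cycles_of_selection,
        ),
    ]
    if include_competitor:
        conds.append(
            SelectionCondition(
                "target_plus_competitor",
                target_concentration,
                competitor_concentration,
                matrix_capture_prob,
                n_cycles_of_selection,
            )
        )
    return conds


# ---------------------------------------------------------------------------
# Synthetic commercial catalog
# ---------------------------------------------------------------------------

def generate_catalog(
    n_compounds: int,
    seed: int,
    planted_fragments: list[str] | None = None,
    n_planted: int = 0,
    n_cycles: int = 2,
):
    """Random fragment-assembled compounds emulating a purchasable catalog.

    ``n_planted`` compounds are analogs of a planted active motif: they carry
    ``planted_fragments`` in their leading positions with only the final
    position varied, mirroring how commercial analogs of a DEL hit share its
    core disynthon.  Returns a DataFrame (id, smiles, is_planted).
    """
    import pandas as pd

    if n_planted and not planted_fragments:
        raise ValueError("planted analogs require planted_fragments")
    rng = np.random.default_rng(seed)
    pool = FRAGMENT_POOL
    rows = []
    seen: set[str] = set()
    n_fixed = len(planted_fragments) if planted_fragments else 0
    i = 0
    while len(rows) < n_compounds:
        planted = len(rows) < n_planted
        if planted:
            frags = list(planted_fragments) + [
                pool[int(k)] for k in rng.integers(0, len(pool), size=n_cycles - n_fixed)
            ]
        else:
            frags = [pool[int(k)] for k in rng.integers(0, len(pool), size=n_cycles)]
        smi = assemble_member(frags)
        if smi in seen and not planted:
            continue
        seen.add(smi)
        rows.append({"id": f"cat{i:07d}", "smiles": smi, "is_planted": planted})
        i += 1
    return pd.DataFrame(rows)
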