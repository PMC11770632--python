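"""Decode DEL selection reads into deduplicated, normalized count tables.

Reads are parsed against a :class:`TagSchema` (UMI span, per-cycle tag maps,
constant region).  Decoding is strict by default: any read whose constant
region or any cycle tag fails an exact lookup is discarded and tallied by
reason, matching the convention that error-containing sequences are thrown
away rather than corrected.  An optional single-mismatch rescue mode exists
but requires the schema's tags to be separated by Hamming distance >= 3.

Amplification duplicates are collapsed on the (UMI, building-block tuple)
key, and counts are normalized to reads-per-million within each
(library, condition) — the scale implied by million-read-per-library
sequencing depth.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_del import (
    CONSTANT_REGION,
    UMI_LENGTH,
    EncodedLibrary,
    ReadSet,
)

REJECT_REASONS = ("length", "bad_constant", "unknown_tag")


@dataclass
class TagSchema:
    """Read layout plus tag -> building-block lookup tables.

    ``libraries`` maps library_id -> per-cycle {tag: block_id} dicts.  When
    several libraries share a schema, their cycle-1 tags must be disjoint so
    the cycle-1 tag demultiplexes the library.
    """

    umi_length: int
    tag_length: int
    n_cycles: int
    constant_region: str
    libraries: dict[str, list[dict[str, str]]]
    lib_by_cycle1_tag: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.lib_by_cycle1_tag = {}
        for lib_id, maps in self.libraries.items():
            if len(maps) != self.n_cycles:
                raise ValueError(f"library {lib_id} has wrong cycle count")
            for tag in maps[0]:
                if tag in self.lib_by_cycle1_tag:
                    raise ValueError(
                        f"cycle-1 tag {tag} not unique across libraries; cannot demultiplex"
                    )
                self.lib_by_cycle1_tag[tag] = lib_id

    @property
    def read_length(self) -> int:
        return self.umi_length + self.n_cycles * self.tag_length + len(self.constant_region)

    def tag_spans(self) -> list[tuple[int, int]]:
        return [
            (
                self.umi_length + c * self.tag_length,
                self.umi_length + (c + 1) * self.tag_length,
            )
            for c in range(self.n_cycles)
        ]

    def min_tag_hamming(self) -> int:
        """Minimum pairwise Hamming distance among tags within any cycle."""
        best = self.tag_length
        for maps in self.libraries.values():
            for cyc in maps:
                tags = list(cyc)
                for a, b in itertools.combinations(tags, 2):
                    d = sum(x != y for x, y in zip(a, b))
                    best = min(best, d)
        return best

    @classmethod
    def from_libraries(
        cls,
        libs: list[EncodedLibrary],
        umi_length: int = UMI_LENGTH,
        constant_region: str = CONSTANT_REGION,
    ) -> "TagSchema":
        n_cycles = libs[0].n_cycles
        tag_length = len(libs[0].blocks[0][0].tag)
        if any(l.n_cycles != n_cycles for l in libs):
            raise ValueError("all libraries in one schema must share the cycle count")
        return cls(
            umi_length=umi_length,
            tag_length=tag_length,
            n_cycles=n_cycles,
            constant_region=constant_region,
            libraries={l.library_id: l.tag_maps() for l in libs},
        )

    def to_json(self) -> dict:
        return {
            "umi_length": self.umi_length,
            "tag_length": self.tag_length,
            "n_cycles": self.n_cycles,
            "constant_region": self.constant_region,
            "libraries": self.libraries,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TagSchema":
        return cls(
            umi_length=obj["umi_length"],
            tag_length=obj["tag_length"],
            n_cycles=obj["n_cycles"],
            constant_region=obj["constant_region"],
            libraries={k: list(v) for k, v in obj["libraries"].items()},
        )


def _rescue(tag: str, table: dict[str, str]) -> str | None:
    """Return the unique block whose tag is within Hamming distance 1."""
    hits = [
        bid
        for t, bid in table.items()
        if sum(a != b for a, b in zip(tag, t)) <= 1
    ]
    return hits[0] if len(hits) == 1 else None


def decode_reads(
    reads: ReadSet | list[str],
    schema: TagSchema,
    mode: str = "strict",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Decode reads to (library, block tuple, UMI) rows plus a rejection tally.

    ``strict`` keeps only reads whose constant region and every cycle tag
    match the schema exactly.  ``rescue1`` additionally accepts tags with a
    single mismatch, provided the schema's minimum inter-tag Hamming
    distance is >= 3 (so a 1-mismatch neighbourhood is unambiguous).
    """
    if mode not in ("strict", "rescue1"):
        raise ValueError(f"unknown decode mode {mode!r}")
    if mode == "rescue1" and schema.min_tag_hamming() < 3:
        raise ValueError("rescue1 mode requires min inter-tag Hamming distance >= 3")

    seqs = reads.sequences if isinstance(reads, ReadSet) else list(reads)
    rejects = dict.fromkeys(REJECT_REASONS, 0)
    L = schema.read_length
    spans = schema.tag_spans()
    const_start = schema.umi_length + schema.n_cycles * schema.tag_length

    if mode == "strict":
        return _decode_strict_vectorized(seqs, schema, rejects, L, spans, const_start)

    rows: list[tuple] = []
    for seq in seqs:
        if len(seq) != L:
            rejects["length"] += 1
            continue
        if seq[const_start:] != schema.constant_region:
            rejects["bad_constant"] += 1
            continue
        umi = seq[: schema.umi_length]
        tag1 = seq[spans[0][0] : spans[0][1]]
        lib_id = schema.lib_by_cycle1_tag.get(tag1)
        if lib_id is None and mode == "rescue1":
            for cand, lid in schema.lib_by_cycle1_tag.items():
                if sum(a != b for a, b in zip(tag1, cand)) <= 1:
                    lib_id, tag1 = lid, cand
                    break
        if lib_id is None:
            rejects["unknown_tag"] += 1
            continue
        maps = schema.libraries[lib_id]
        blocks = [maps[0][tag1]]
        ok = True
        for c in range(1, schema.n_cycles):
            tag = seq[spans[c][0] : spans[c][1]]
            bid = maps[c].get(tag)
            if bid is None and mode == "rescue1":
                bid = _rescue(tag, maps[c])
            if bid is None:
                ok = False
                break
            blocks.append(bid)
        if not ok:
            rejects["unknown_tag"] += 1
            continue
        rows.append((lib_id, "|".join(blocks), umi))

    df = pd.DataFrame(rows, columns=["library_id", "blocks", "umi"])
    return df, rejects


def _decode_strict_vectorized(
    seqs: list[str],
    schema: TagSchema,
    rejects: dict[str, int],
    L: int,
    spans: list[tuple[int, int]],
    const_start: int,
) -> tuple[pd.DataFrame, dict[str, int]]:
    empty = pd.DataFrame(columns=["library_id", "blocks", "umi"])
    if not seqs:
        return empty, rejects
    s = pd.Series(seqs, dtype="object")
    len_ok = s.str.len() == L
    rejects["length"] = int((~len_ok).sum())
    s = s[len_ok]
    if s.empty:
        return empty, rejects
    const_ok = s.str[const_start:] == schema.constant_region
    rejects["bad_constant"] = int((~const_ok).sum())
    s = s[const_ok]
    if s.empty:
        return empty, rejects

    tag1 = s.str[spans[0][0] : spans[0][1]]
    lib_id = tag1.map(schema.lib_by_cycle1_tag)
    ok = lib_id.notna()
    block_cols = {}
    # tag lookups must agree with the library selected by the cycle-1 tag,
    # so per-cycle maps are applied library by library
    for lid, maps in schema.libraries.items():
        in_lib = lib_id == lid
        if not in_lib.any():
            continue
        block_cols.setdefault(0, pd.Series(index=s.index, dtype="object"))
        block_cols[0][in_lib] = tag1[in_lib].map(maps[0])
        for c in range(1, schema.n_cycles):
            tag = s[in_lib].str[spans[c][0] : spans[c][1]]
            block_cols.setdefault(c, pd.Series(index=s.index, dtype="object"))
            block_cols[c][in_lib] = tag.map(maps[c])
    for c in range(schema.n_cycles):
        col = block_cols.get(c)
        ok &= col.notna() if col is not None else False
    rejects["unknown_tag"] = int((~ok).sum())
    s = s[ok]
    if s.empty:
        return empty, rejects
    blocks = block_cols[0][ok].str.cat([block_cols[c][ok] for c in range(1, schema.n_cycles)], sep="|")
    df = pd.DataFrame(
        {
            "library_id": lib_id[ok].to_numpy(),
            "blocks": blocks.to_numpy(),
            "umi": s.str[: schema.umi_length].to_numpy(),
        }
    )
    return df, rejects


def dedupe(decoded: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse amplification duplicates on the (UMI, block tuple) key.

    Returns the unique-molecule stream and the number of reads collapsed.
    Keys include every column present (so a condition column, if already
    attached, separates arms).  Idempotent by construction.
    """
    if decoded.empty:
        return decoded.copy(), 0
    unique = decoded.drop_duplicates().reset_index(drop=True)
    return unique, len(decoded) - len(unique)


@dataclass
class CountTable:
    """Per (library, block tuple, condition) read counts.

    ``unique_count`` is post-deduplication, ``raw_count`` pre-deduplication;
    ``norm_rpm`` rescales unique counts to reads-per-million within each
    (library, condition).
    """

    df: pd.DataFrame
    totals: pd.DataFrame  # per (library_id, condition): raw / unique totals

    def __len__(self) -> int:
        return len(self.df)

    def write_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df=df, totals=_totals(df))


def _totals(df: pd.DataFrame) -> pd.DataFrame:
    return (
        df.groupby(["library_id", "condition"], as_index=False)
        .agg(raw_total=("raw_count", "sum"), unique_total=("unique_count", "sum"))
    )


def build_count_table(decoded_by_condition: dict[str, pd.DataFrame]) -> CountTable:
    """Aggregate decoded streams (one per condition, pre-dedup) into counts.

    Deduplication happens internally per condition; a condition with zero
    decodable reads is flagged with a warning and yields no rows.
    """
    pieces = []
    for cond, dec in decoded_by_condition.items():
        if dec.empty:
            warnings.warn(f"condition {cond!r} has no decoded reads; normalization undefined")
            continue
        raw = (
            dec.groupby(["library_id", "blocks"], as_index=False)
            .size()
            .rename(columns={"size": "raw_count"})
        )
        uniq_stream, _ = dedupe(dec)
        uniq = (
            uniq_stream.groupby(["library_id", "blocks"], as_index=False)
            .size()
            .rename(columns={"size": "unique_count"})
        )
        merged = raw.merge(uniq, on=["library_id", "blocks"], how="outer").fillna(0)
        merged["condition"] = cond
        pieces.append(merged)
    if not pieces:
        df = pd.DataFrame(
            columns=["library_id", "blocks", "condition", "raw_count", "unique_count", "norm_rpm"]
        )
        return CountTable(df=df, totals=_totals(df) if len(df) else pd.DataFrame())
    df = pd.concat(pieces, ignore_index=True)
    df[["raw_count", "unique_count"]] = df[["raw_count", "unique_count"]].astype(np.int64)
    tot = df.groupby(["library_id", "condition"])["unique_count"].transform("sum")
    df["norm_rpm"] = df["unique_count"] / tot * 1e6
    df = df[
        ["library_id", "blocks", "condition", "raw_count", "unique_count", "norm_rpm"]
    ].sort_values(["library_id", "condition", "blocks"], kind="stable").reset_index(drop=True)
    return CountTable(df=df, totals=_totals(df))
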