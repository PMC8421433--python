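"""Readers and writers for epiread TSV, BED, gene-model/expression tables,
and wiggle tracks, plus the domain types shared by every analysis module.

Coordinate conventions
----------------------
All intervals are 0-based, half-open ``[start, end)`` internally, as in BED.
A CpG coordinate is the position of the C on the forward strand; reverse-
strand observations are collapsed onto it (CpG dyads are symmetric).
Wiggle output is 1-based per the variableStep convention.

The epiread TSV dialect is::

    chrom <TAB> read_id <TAB> strand <TAB> pos1,pos2,... <TAB> calls

where positions are strictly increasing forward-strand C coordinates and
``calls`` is a string over ``{0,1,?}`` of the same length ('?' = missing).
Lines starting with '#' are comments.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

__all__ = [
    "GenomicInterval",
    "EpireadRecord",
    "GeneModel",
    "EpireadParseError",
    "read_epireads",
    "write_epireads",
    "read_bed",
    "read_gene_models",
    "read_expression",
    "read_anchor_pairs",
    "write_wiggle",
    "extract_epireads_from_alignment",
]

MISSING = None  # sentinel for a '?' call


class EpireadParseError(ValueError):
    """Malformed epiread line; message carries the 1-based line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class EpireadRecord:
    """One sequencing read's ordered CpG positions and binary calls.

    ``calls`` holds 1 (methylated), 0 (unmethylated) or None (missing).
    At least one call must be non-missing.
    """

    chrom: str
    read_id: str
    cpg_positions: tuple[int, ...]
    calls: tuple[int | None, ...]
    strand: str = "."

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.cpg_positions):
            raise ValueError(
                f"read {self.read_id}: {len(self.cpg_positions)} positions "
                f"but {len(self.calls)} calls"
            )
        if any(b <= a for a, b in zip(self.cpg_positions, self.cpg_positions[1:])):
            raise ValueError(
                f"read {self.read_id}: CpG positions not strictly increasing"
            )
        if all(c is None for c in self.calls):
            raise ValueError(f"read {self.read_id}: all calls missing")

    @property
    def observed(self) -> list[tuple[int, int]]:
        """(position, call) pairs with missing calls dropped."""
        return [
            (p, c) for p, c in zip(self.cpg_positions, self.calls) if c is not None
        ]


@dataclass(frozen=True)
class GeneModel:
    """Gene coordinates; tss/tts are 0-based positions of the boundary bases.

    Promoter = 1 kb upstream of the TSS through 500 bp downstream; gene body
    = 500 bp downstream of the TSS through the TTS. Both are oriented by
    strand: on '-' genes the windows are mirrored around the TSS with the
    same lengths, the TSS base included in the promoter.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and self.tts <= self.tss:
            raise ValueError(f"gene {self.gene_id}: TTS must follow TSS on +")
        if self.strand == "-" and self.tts >= self.tss:
            raise ValueError(f"gene {self.gene_id}: TTS must precede TSS on -")

    def promoter(self, upstream: int = 1000, downstream: int = 500) -> GenomicInterval:
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream + 1, self.tss + upstream + 1
        return GenomicInterval(self.chrom, max(0, start), end,
                               name=self.gene_id, strand=self.strand)

    def gene_body(self, tss_offset: int = 500) -> GenomicInterval:
        if self.strand == "+":
            start, end = self.tss + tss_offset, self.tts
        else:
            start, end = self.tts, self.tss - tss_offset + 1
        if end <= start:
            # gene shorter than the promoter's downstream extent
            raise ValueError(f"gene {self.gene_id}: no gene body beyond "
                             f"{tss_offset} bp downstream of TSS")
        return GenomicInterval(self.chrom, max(0, start), end,
                               name=self.gene_id, strand=self.strand)


# ---------------------------------------------------------------------------
# epiread TSV


def _parse_epiread_line(line: str, lineno: int) -> EpireadRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 5:
        raise EpireadParseError(
            f"line {lineno}: expected 5 tab-separated columns, got {len(fields)}"
        )
    chrom, read_id, strand, pos_s, call_s = fields[:5]
    try:
        positions = tuple(int(p) for p in pos_s.split(","))
    except ValueError as exc:
        raise EpireadParseError(f"line {lineno}: bad position field: {exc}") from exc
    calls: list[int | None] = []
    for ch in call_s.strip():
        if ch == "1":
            calls.append(1)
        elif ch == "0":
            calls.append(0)
        elif ch == "?":
            calls.append(None)
        else:
            raise EpireadParseError(f"line {lineno}: invalid call character {ch!r}")
    try:
        return EpireadRecord(chrom, read_id, positions, tuple(calls), strand=strand)
    except ValueError as exc:
        raise EpireadParseError(f"line {lineno}: {exc}") from exc


def read_epireads(
    path, region_filter: GenomicInterval | None = None
) -> list[EpireadRecord]:
    """Read an epiread TSV; returns records sorted by (chrom, first position).

    ``region_filter`` keeps only reads with at least one CpG inside the
    region. Malformed lines raise :class:`EpireadParseError` naming the line.
    """
    records: list[EpireadRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            rec = _parse_epiread_line(line, lineno)
            if region_filter is not None and not any(
                region_filter.contains(rec.chrom, p) for p in rec.cpg_positions
            ):
                continue
            records.append(rec)
    records.sort(key=lambda r: (r.chrom, r.cpg_positions[0]))
    return records


def write_epireads(records: Iterable[EpireadRecord], path) -> None:
    """Write records in the epiread TSV dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        for rec in records:
            calls = "".join("?" if c is None else str(c) for c in rec.calls)
            fh.write(
                f"{rec.chrom}\t{rec.read_id}\t{rec.strand}\t"
                f"{','.join(str(p) for p in rec.cpg_positions)}\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# BED and tables


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3-BED6; intervals stay 0-based half-open."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_anchor_pairs(path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Read a 6-column pair file: chrom1 start1 end1 chrom2 start2 end2."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 6:
                raise ValueError(f"{path}: line {lineno}: need 6 columns")
            pairs.append(
                (
                    GenomicInterval(f[0], int(f[1]), int(f[2])),
                    GenomicInterval(f[3], int(f[4]), int(f[5])),
                )
            )
    return pairs


def read_gene_models(path) -> list[GeneModel]:
    """Read a gene-model TSV: gene_id chrom strand tss tts."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gid, chrom, strand, tss, tts = line.split()[:5]
            genes.append(GeneModel(gid, chrom, strand, int(tss), int(tts)))
    return genes


def read_expression(path) -> dict[str, float]:
    """Read a two-column TSV of gene_id -> non-negative expression value."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            gid, val = line.split()[:2]
            v = float(val)
            if v < 0:
                raise ValueError(f"{path}: line {lineno}: negative expression {v}")
            table[gid] = v
    return table


# ---------------------------------------------------------------------------
# wiggle


def write_wiggle(track, path, chrom: str | None = None) -> None:
    """Write a per-position track as variableStep wiggle (1-based output).

    ``track`` is either ``{position: value}`` with ``chrom`` given, or
    ``{chrom: {position: value}}``. Position/value pair sequences are also
    accepted and must already be sorted by position.
    """
    if chrom is not None:
        by_chrom: dict[str, object] = {chrom: track}
    else:
        by_chrom = dict(track)

    def _pairs(t) -> list[tuple[int, float]]:
        if isinstance(t, Mapping):
            return sorted(t.items())
        pairs = list(t)
        if any(b[0] <= a[0] for a, b in zip(pairs, pairs[1:])):
            raise ValueError("wiggle positions must be sorted and unique")
        return pairs

    with open(path, "w") as fh:
        for c in sorted(by_chrom):
            fh.write(f"variableStep chrom={c}\n")
            for pos, val in _pairs(by_chrom[c]):
                fh.write(f"{pos + 1} {val:.6g}\n")


# ---------------------------------------------------------------------------
# alignment extraction (pysam)


def _call_from_base(base: str, reverse: bool) -> int | None:
    base = base.upper()
    if not reverse:  # bisulfite-informative on the C of the forward CpG
        return 1 if base == "C" else 0 if base == "T" else None
    # reverse-strand read: informative base is the G of the dyad; after
    # bisulfite, unmethylated G-complement reads out as A
    return 1 if base == "G" else 0 if base == "A" else None


def extract_epireads_from_alignment(
    alignments: Iterable,
    cpg_map: Mapping[str, Sequence[int]],
    conflict_to_missing: bool = False,
    warn_stream: TextIO | None = None,
) -> list[EpireadRecord]:
    """Build epireads from aligned bisulfite reads (pysam AlignedSegment).

    ``cpg_map`` gives sorted forward-strand C positions per chromosome.
    Mate pairs are merged so every CpG is counted once; on a conflicting
    double observation the first mate's call wins (or becomes missing when
    ``conflict_to_missing``). Reads on chromosomes absent from the map are
    skipped with a warning; reads covering no CpG emit nothing.
    """
    import bisect

    per_template: dict[tuple[str, str], dict[int, int | None]] = {}
    order: list[tuple[str, str]] = []
    warned: set[str] = set()

    for aln in alignments:
        if aln.is_unmapped:
            continue
        chrom = aln.reference_name
        sites = cpg_map.get(chrom)
        if sites is None:
            if chrom not in warned:
                warned.add(chrom)
                print(f"warning: no CpG map for {chrom}; reads skipped",
                      file=warn_stream or sys.stderr)
            continue
        reverse = aln.is_reverse
        calls: dict[int, int | None] = {}
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            site = rpos - 1 if reverse else rpos  # G of the dyad -> C position
            i = bisect.bisect_left(sites, site)
            if i == len(sites) or sites[i] != site:
                continue
            calls[site] = _call_from_base(aln.query_sequence[qpos], reverse)
        if not calls:
            continue
        key = (chrom, aln.query_name)
        if key not in per_template:
            per_template[key] = {}
            order.append(key)
        merged = per_template[key]
        first_mate = not aln.is_read2
        for pos, call in calls.items():
            if pos not in merged:
                merged[pos] = call
            elif merged[pos] != call:
                if conflict_to_missing:
                    merged[pos] = None
                elif first_mate:
                    merged[pos] = call
    records = []
    for chrom, name in order:
        calls = per_template[(chrom, name)]
        if all(c is None for c in calls.values()):
            continue
        positions = tuple(sorted(calls))
        records.append(
            EpireadRecord(chrom, name, positions,
                          tuple(calls[p] for p in positions))
        )
    return records
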