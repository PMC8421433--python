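"""Shared fixtures: compact epiread construction helpers."""

from __future__ import annotations

import pytest

from methconc.io import EpireadRecord, GenomicInterval


def make_read(
    calls: str,
    start: int = 100,
    spacing: int = 10,
    chrom: str = "chr1",
    read_id: str = "r",
) -> EpireadRecord:
    """Build a read from a call string over {0,1,?} at evenly spaced CpGs."""
    positions = tuple(start + i * spacing for i in range(len(calls)))
    parsed = tuple(None if c == "?" else int(c) for c in calls)
    return EpireadRecord(chrom, read_id, positions, parsed)


def make_reads(patterns: list[str], **kwargs) -> list[EpireadRecord]:
    """Reads over a shared CpG grid, one per call-string pattern."""
    return [
        make_read(p, read_id=f"r{i}", **kwargs) for i, p in enumerate(patterns)
    ]


@pytest.fixture
def wide_region() -> GenomicInterval:
    return GenomicInterval("chr1", 0, 10_000_000)
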