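"""Window-based methylation heterogeneity over 4-CpG loci.

A locus is four adjacent CpGs of the CpG map; a read supports a locus only
when it has non-missing calls at all four positions, so only a minority of
short reads contribute (unlike the concurrence ratio, which uses every
read). Per-locus scores:

* Shannon entropy of the 16 epiallele pattern frequencies (default base 2,
  so the maximum over 16 patterns is 4 bits),
* Epipolymorphism ``1 - sum(p_i^2)``,
* PDR, the proportion of discordant (mixed-call) reads.

A region's score is the plain average over loci whose first CpG lies in the
region.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import EpireadRecord, GenomicInterval

__all__ = [
    "EpialleleTable",
    "HeterogeneityScores",
    "enumerate_loci",
    "entropy",
    "epipolymorphism",
    "pdr",
    "region_heterogeneity",
]

LOCUS_SIZE = 4


@dataclass(frozen=True)
class EpialleleTable:
    """Read-pattern counts at one 4-CpG locus."""

    chrom: str
    positions: tuple[int, ...]  # the 4 CpG coordinates
    counts: dict[str, int]  # pattern (e.g. '1010') -> read count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> list[float]:
        total = self.total
        return [n / total for n in self.counts.values()]


@dataclass(frozen=True)
class HeterogeneityScores:
    entropy: float
    epipolymorphism: float
    pdr: float
    n_loci: int


def enumerate_loci(
    records: Sequence[EpireadRecord],
    region: GenomicInterval | None = None,
    coverage_min: int = 4,
) -> list[EpialleleTable]:
    """All 4-CpG windows (consecutive CpGs of the observed map) supported by
    at least ``coverage_min`` fully informative reads.

    With ``region``, only windows whose first CpG lies inside it are kept.
    """
    by_chrom: dict[str, set[int]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, set()).update(rec.cpg_positions)
    out: list[EpialleleTable] = []
    for chrom in sorted(by_chrom):
        if region is not None and chrom != region.chrom:
            continue
        cpg_map = sorted(by_chrom[chrom])
        index = {p: i for i, p in enumerate(cpg_map)}
        window_counts: dict[int, Counter] = {}
        for rec in records:
            if rec.chrom != chrom:
                continue
            calls = dict(rec.observed)
            idx = sorted(index[p] for p in calls)
            # maximal runs of consecutive map indices with observed calls
            run_start = 0
            for j in range(1, len(idx) + 1):
                if j == len(idx) or idx[j] != idx[j - 1] + 1:
                    run = idx[run_start:j]
                    for k in range(len(run) - LOCUS_SIZE + 1):
                        first = run[k]
                        pattern = "".join(
                            str(calls[cpg_map[first + m]]) for m in range(LOCUS_SIZE)
                        )
                        window_counts.setdefault(first, Counter())[pattern] += 1
                    run_start = j
        for first in sorted(window_counts):
            counts = window_counts[first]
            if sum(counts.values()) < coverage_min:
                continue
            first_pos = cpg_map[first]
            if region is not None and not (region.start <= first_pos < region.end):
                continue
            out.append(
                EpialleleTable(
                    chrom,
                    tuple(cpg_map[first + m] for m in range(LOCUS_SIZE)),
                    dict(counts),
                )
            )
    return out


def entropy(table: EpialleleTable, log_base: float = 2) -> float:
    """Shannon entropy of the epiallele distribution; base 2 by default so
    the 16-pattern maximum is exactly 4."""
    return -sum(p * math.log(p, log_base) for p in table.frequencies() if p > 0)


def epipolymorphism(table: EpialleleTable) -> float:
    """1 - sum of squared pattern frequencies (in [0, 15/16])."""
    return 1.0 - sum(p * p for p in table.frequencies())


def pdr(table: EpialleleTable) -> float:
    """Proportion of discordant reads: patterns containing both 0 and 1."""
    discordant = sum(
        n for pattern, n in table.counts.items() if "0" in pattern and "1" in pattern
    )
    return discordant / table.total


def region_heterogeneity(
    records: Sequence[EpireadRecord],
    region: GenomicInterval,
    coverage_min: int = 4,
    log_base: float = 2,
) -> HeterogeneityScores | None:
    """Average per-locus scores over the region's qualifying 4-CpG loci;
    None when the region holds no qualifying locus."""
    loci = enumerate_loci(records, region=region, coverage_min=coverage_min)
    if not loci:
        return None
    ents = [entropy(t, log_base) for t in loci]
    epis = [epipolymorphism(t) for t in loci]
    pdrs = [pdr(t) for t in loci]
    n = len(loci)
    return HeterogeneityScores(sum(ents) / n, sum(epis) / n, sum(pdrs) / n, n)
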