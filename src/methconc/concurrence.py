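"""Read dissection and the methylation concurrence ratio.

A bisulfite read is dissected into maximal runs of same-state CpGs:
``M`` fragments (runs of methylated CpGs), one ``U`` fragment when the whole
read is unmethylated, and ``C`` fragments — runs of unmethylated CpGs inside
a *partially methylated* read. C fragments are the footprint of methylation/
demethylation concurrence on a single molecule: they only exist where the
same read carries both states.

The concurrence ratio of a region is the summed weight of C fragments over
the summed weight of all fragments, with a fragment's weight equal to its
in-region CpG count (weighted) or 1 (unweighted). The weighted form equals
the proportion of CpG observations carrying a C label, so it is defined down
to a single CpG. Fragment labels are always assigned from the FULL read;
only the weights are clipped to the region.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import EpireadRecord, GenomicInterval

__all__ = [
    "Fragment",
    "CpGCounts",
    "RegionMetrics",
    "dissect_read",
    "cpg_label_counts",
    "concurrence_ratio",
    "concurrence_track",
    "mean_methylation_track",
    "mean_methylation",
    "chalm",
    "region_metrics",
]


@dataclass(frozen=True)
class Fragment:
    """A maximal same-state run of CpGs within one read."""

    label: str  # 'M', 'U' or 'C'
    positions: tuple[int, ...]

    @property
    def weight(self) -> int:
        return len(self.positions)


@dataclass
class CpGCounts:
    """Per-CpG observation tallies across reads."""

    n_reads: int = 0
    n_meth: int = 0
    n_m: int = 0
    n_u: int = 0
    n_c: int = 0


@dataclass(frozen=True)
class RegionMetrics:
    """Per-region bundle of read-level methylation metrics.

    ``None`` marks a metric that is undefined on this region (no qualifying
    CpG or read), never coerced to 0.
    """

    interval: GenomicInterval
    concurrence_weighted: float | None
    concurrence_unweighted: float | None
    mean_meth: float | None
    chalm: float | None
    n_cpgs_used: int
    n_reads_used: int
    mode: str = "strict"


def dissect_read(record: EpireadRecord) -> list[Fragment]:
    """Split a read into M/U/C fragments over its non-missing calls.

    Missing calls are skipped without breaking a run of equal state. An
    all-methylated read is one M fragment, an all-unmethylated read one U
    fragment; in a mixed read runs of 1s are M and runs of 0s are C.
    """
    observed = record.observed
    if not observed:
        raise ValueError(f"read {record.read_id}: all calls missing")
    states = {c for _, c in observed}
    if states == {1}:
        return [Fragment("M", tuple(p for p, _ in observed))]
    if states == {0}:
        return [Fragment("U", tuple(p for p, _ in observed))]
    frags: list[Fragment] = []
    run: list[int] = [observed[0][0]]
    cur = observed[0][1]
    for pos, call in observed[1:]:
        if call == cur:
            run.append(pos)
        else:
            frags.append(Fragment("M" if cur == 1 else "C", tuple(run)))
            run, cur = [pos], call
    frags.append(Fragment("M" if cur == 1 else "C", tuple(run)))
    return frags


def cpg_label_counts(
    records: Iterable[EpireadRecord],
) -> dict[str, dict[int, CpGCounts]]:
    """Tally per-CpG read coverage, methylated calls and M/U/C labels."""
    counts: dict[str, dict[int, CpGCounts]] = defaultdict(dict)
    for rec in records:
        chrom_counts = counts[rec.chrom]
        for frag in dissect_read(rec):
            for pos in frag.positions:
                c = chrom_counts.get(pos)
                if c is None:
                    c = chrom_counts[pos] = CpGCounts()
                c.n_reads += 1
                if frag.label == "M":
                    c.n_m += 1
                    c.n_meth += 1
                elif frag.label == "U":
                    c.n_u += 1
                else:
                    c.n_c += 1
    return dict(counts)


def _qualifying_positions(
    counts: Mapping[str, Mapping[int, CpGCounts]],
    region: GenomicInterval,
    coverage_min: int,
) -> set[int]:
    chrom_counts = counts.get(region.chrom, {})
    return {
        p
        for p, c in chrom_counts.items()
        if region.start <= p < region.end and c.n_reads >= coverage_min
    }


def concurrence_ratio(
    records: Sequence[EpireadRecord],
    region: GenomicInterval,
    weighted: bool = True,
    coverage_min: int = 4,
) -> float | None:
    """Concurrence ratio of a region from fragment weight sums.

    Fragment labels come from whole reads; weights count only the region's
    CpGs that pass the coverage filter. Returns None when no CpG qualifies.
    """
    counts = cpg_label_counts(records)
    qual = _qualifying_positions(counts, region, coverage_min)
    if not qual:
        return None
    w_c = 0.0
    w_all = 0.0
    for rec in records:
        if rec.chrom != region.chrom:
            continue
        for frag in dissect_read(rec):
            w = sum(1 for p in frag.positions if p in qual)
            if w == 0:
                continue
            if not weighted:
                w = 1
            w_all += w
            if frag.label == "C":
                w_c += w
    if w_all == 0:
        return None
    return w_c / w_all


def concurrence_track(
    records: Iterable[EpireadRecord], coverage_min: int = 4
) -> dict[str, dict[int, float]]:
    """Per-CpG concurrence: C-labeled observations / coverage, per chrom.

    CpGs covered by fewer than ``coverage_min`` reads are absent.
    """
    out: dict[str, dict[int, float]] = {}
    for chrom, chrom_counts in cpg_label_counts(records).items():
        track = {
            p: c.n_c / c.n_reads
            for p, c in sorted(chrom_counts.items())
            if c.n_reads >= coverage_min
        }
        if track:
            out[chrom] = track
    return out


def mean_methylation_track(
    records: Iterable[EpireadRecord], coverage_min: int = 4
) -> dict[str, dict[int, tuple[float, int]]]:
    """Per-CpG (methylation ratio, coverage) for CpGs passing the filter."""
    out: dict[str, dict[int, tuple[float, int]]] = {}
    for chrom, chrom_counts in cpg_label_counts(records).items():
        track = {
            p: (c.n_meth / c.n_reads, c.n_reads)
            for p, c in sorted(chrom_counts.items())
            if c.n_reads >= coverage_min
        }
        if track:
            out[chrom] = track
    return out


def mean_methylation(
    records: Sequence[EpireadRecord],
    region: GenomicInterval,
    coverage_min: int = 4,
) -> float | None:
    """Traditional mean methylation: methylated CpG observations over all
    CpG observations at qualifying in-region CpGs."""
    counts = cpg_label_counts(records)
    qual = _qualifying_positions(counts, region, coverage_min)
    if not qual:
        return None
    chrom_counts = counts[region.chrom]
    n_meth = sum(chrom_counts[p].n_meth for p in qual)
    n_obs = sum(chrom_counts[p].n_reads for p in qual)
    return n_meth / n_obs


def chalm(
    records: Sequence[EpireadRecord],
    region: GenomicInterval,
    coverage_min: int = 4,
) -> float | None:
    """CHALM: n_m / (n_m + n_u) where a read is methylated if it has >=1
    methylated call among qualifying in-region CpGs."""
    counts = cpg_label_counts(records)
    qual = _qualifying_positions(counts, region, coverage_min)
    if not qual:
        return None
    n_m = n_u = 0
    for rec in records:
        if rec.chrom != region.chrom:
            continue
        calls = [c for p, c in rec.observed if p in qual]
        if not calls:
            continue
        if any(c == 1 for c in calls):
            n_m += 1
        else:
            n_u += 1
    if n_m + n_u == 0:
        return None
    return n_m / (n_m + n_u)


def batch_region_concurrence(
    counts: Mapping[str, Mapping[int, CpGCounts]],
    regions: Sequence[GenomicInterval],
    coverage_min: int = 4,
) -> list[float | None]:
    """Weighted concurrence for many regions from precomputed label counts.

    Uses the per-CpG identity (weighted ratio = C-labeled observations over
    all observations at qualifying CpGs) with sorted position arrays, so the
    cost is O(reads + regions log CpGs) rather than a scan per region.
    """
    import numpy as np

    arrays: dict[str, tuple] = {}
    for chrom, chrom_counts in counts.items():
        items = sorted(
            (p, c) for p, c in chrom_counts.items() if c.n_reads >= coverage_min
        )
        if not items:
            continue
        pos = np.array([p for p, _ in items])
        n_c = np.cumsum([c.n_c for _, c in items])
        n_all = np.cumsum([c.n_reads for _, c in items])
        arrays[chrom] = (pos, np.concatenate([[0], n_c]), np.concatenate([[0], n_all]))
    out: list[float | None] = []
    for region in regions:
        arr = arrays.get(region.chrom)
        if arr is None:
            out.append(None)
            continue
        pos, cum_c, cum_all = arr
        lo = int(np.searchsorted(pos, region.start, side="left"))
        hi = int(np.searchsorted(pos, region.end, side="left"))
        total = cum_all[hi] - cum_all[lo]
        out.append(None if total == 0 else (cum_c[hi] - cum_c[lo]) / total)
    return out


def region_metrics(
    records: Sequence[EpireadRecord],
    regions: Sequence[GenomicInterval],
    coverage_min: int = 4,
    strict: bool = True,
) -> list[RegionMetrics]:
    """Compute all per-region metrics.

    Strict mode drops a region outright when any of its observed CpGs falls
    below ``coverage_min`` (every CpG must be sufficiently covered); lenient
    mode drops only the failing CpGs. Dropped regions appear with all
    metrics None so output rows align with input regions.
    """
    counts = cpg_label_counts(records)
    mode = "strict" if strict else "lenient"
    out: list[RegionMetrics] = []
    for region in regions:
        chrom_counts = counts.get(region.chrom, {})
        in_region = {
            p: c for p, c in chrom_counts.items() if region.start <= p < region.end
        }
        qual = {p for p, c in in_region.items() if c.n_reads >= coverage_min}
        dropped = strict and (not in_region or len(qual) < len(in_region))
        if dropped or not qual:
            out.append(
                RegionMetrics(region, None, None, None, None, 0, 0, mode=mode)
            )
            continue
        n_reads_used = 0
        for rec in records:
            if rec.chrom == region.chrom and any(
                p in qual for p, _ in rec.observed
            ):
                n_reads_used += 1
        out.append(
            RegionMetrics(
                interval=region,
                concurrence_weighted=concurrence_ratio(
                    records, region, weighted=True, coverage_min=coverage_min
                ),
                concurrence_unweighted=concurrence_ratio(
                    records, region, weighted=False, coverage_min=coverage_min
                ),
                mean_meth=mean_methylation(records, region, coverage_min),
                chalm=chalm(records, region, coverage_min),
                n_cpgs_used=len(qual),
                n_reads_used=n_reads_used,
                mode=mode,
            )
        )
    return out
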