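"""Region-level annotation statistics for canyons and genes.

Covers the binned methylation-expression correlation (120 bins of 100 bp
from 2 kb upstream to 10 kb downstream of the TSS, strand-oriented), motif
counts per kilobase (CPK) with aCanyon/pCanyon fold enrichment against
external 5mC binding preferences, transcription-factor occupancy ratios,
Hi-C anchor-pair classification (self- vs distant-interacting), and
length-matched region shuffling for controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .canyons import CpGMethTrack, sample_background
from .io import GeneModel, GenomicInterval

__all__ = [
    "MotifEnrichment",
    "binned_matrix",
    "per_bin_correlation",
    "cpk",
    "motif_fold_enrichment",
    "tf_odds_ratio",
    "classify_interactions",
    "shuffle_regions",
]

N_BINS = 120
BIN_SIZE = 100
UPSTREAM = 2000


@dataclass(frozen=True)
class MotifEnrichment:
    motif: str
    cpk_a: float
    cpk_p: float
    log2_fold: float
    preference: float
    klass: str  # 'methyl-plus' | 'methyl-minus'
    pseudocount: bool = False


def binned_matrix(
    tracks: Mapping[str, CpGMethTrack],
    genes: Sequence[GeneModel],
    coverage_min: int = 4,
    n_bins: int = N_BINS,
    bin_size: int = BIN_SIZE,
    upstream: int = UPSTREAM,
) -> pd.DataFrame:
    """Gene x bin matrix of mean methylation around the TSS.

    Bin b covers oriented offsets [-upstream + b*bin_size, -upstream +
    (b+1)*bin_size) relative to the TSS, reading in the direction of
    transcription; on '-' genes the windows are mirrored genomically. Bin
    value = coverage-weighted mean methylation of qualifying CpGs; NaN when
    the bin holds none.
    """
    mat = np.full((len(genes), n_bins), np.nan)
    for gi, gene in enumerate(genes):
        track = tracks.get(gene.chrom)
        if track is None:
            continue
        ok = track.coverage >= coverage_min
        pos, meth, cov = track.positions[ok], track.meth[ok], track.coverage[ok]
        for b in range(n_bins):
            lo_off = -upstream + b * bin_size
            hi_off = lo_off + bin_size
            if gene.strand == "+":
                lo, hi = gene.tss + lo_off, gene.tss + hi_off
            else:
                lo, hi = gene.tss - hi_off + 1, gene.tss - lo_off + 1
            i, j = np.searchsorted(pos, [lo, hi])
            if j > i:
                mat[gi, b] = np.sum(meth[i:j] * cov[i:j]) / np.sum(cov[i:j])
    return pd.DataFrame(mat, index=[g.gene_id for g in genes],
                        columns=range(n_bins))


def per_bin_correlation(
    matrix: pd.DataFrame,
    expression: Mapping[str, float],
    min_genes: int = 10,
) -> np.ndarray:
    """Spearman correlation of expression with each bin's methylation,
    pairwise-complete; NaN where fewer than ``min_genes`` genes or a
    constant column."""
    expr = pd.Series(expression).reindex(matrix.index)
    out = np.full(matrix.shape[1], np.nan)
    for b, col in enumerate(matrix.columns):
        vals = matrix[col]
        ok = vals.notna() & expr.notna()
        if ok.sum() < min_genes:
            continue
        x, y = vals[ok].to_numpy(), expr[ok].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        out[b] = stats.spearmanr(x, y).statistic
    return out


def _midpoint_hits(hits: Iterable[GenomicInterval],
                   regions: Sequence[GenomicInterval]) -> int:
    count = 0
    for h in hits:
        mid = h.midpoint
        if any(r.contains(h.chrom, mid) for r in regions):
            count += 1
    return count


def cpk(hits: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]) -> float:
    """Hits (by midpoint) per kilobase of the region set."""
    total_kb = sum(r.length for r in regions) / 1000
    if total_kb == 0:
        raise ValueError("region set has zero total length")
    return _midpoint_hits(hits, regions) / total_kb


def motif_fold_enrichment(
    hits_by_motif: Mapping[str, Sequence[GenomicInterval]],
    acanyons: Sequence[GenomicInterval],
    pcanyons: Sequence[GenomicInterval],
    preferences: Mapping[str, float],
) -> tuple[list[MotifEnrichment], float, float]:
    """Per-motif log2 fold enrichment of aCanyon vs pCanyon CPK, plus the
    Spearman correlation (rho, p) of fold against 5mC preference.

    A motif with zero hits in either canyon class gets one pseudo-hit added
    to both counts and is flagged.
    """
    kb_a = sum(r.length for r in acanyons) / 1000
    kb_p = sum(r.length for r in pcanyons) / 1000
    if kb_a == 0 or kb_p == 0:
        raise ValueError("both canyon sets must have positive total length")
    out: list[MotifEnrichment] = []
    for motif in sorted(hits_by_motif):
        if motif not in preferences:
            continue
        n_a = _midpoint_hits(hits_by_motif[motif], acanyons)
        n_p = _midpoint_hits(hits_by_motif[motif], pcanyons)
        pseudo = n_a == 0 or n_p == 0
        if pseudo:
            n_a += 1
            n_p += 1
        pref = preferences[motif]
        out.append(
            MotifEnrichment(
                motif=motif,
                cpk_a=n_a / kb_a,
                cpk_p=n_p / kb_p,
                log2_fold=math.log2((n_a / kb_a) / (n_p / kb_p)),
                preference=pref,
                klass="methyl-plus" if pref > 0 else "methyl-minus",
                pseudocount=pseudo,
            )
        )
    if len(out) >= 3:
        res = stats.spearmanr([m.log2_fold for m in out],
                              [m.preference for m in out])
        rho, pval = float(res.statistic), float(res.pvalue)
    else:
        rho, pval = float("nan"), float("nan")
    return out, rho, pval


def tf_odds_ratio(
    peaks: Sequence[GenomicInterval],
    acanyons: Sequence[GenomicInterval],
    pcanyons: Sequence[GenomicInterval],
) -> float:
    """Ratio of the fraction of aCanyons touched by >= 1 peak to the same
    fraction for pCanyons; +inf when no pCanyon is occupied."""
    if not acanyons or not pcanyons:
        raise ValueError("both canyon sets must be non-empty")

    def frac(regions: Sequence[GenomicInterval]) -> float:
        occupied = sum(
            1 for r in regions if any(p.overlaps(r) for p in peaks)
        )
        return occupied / len(regions)

    fa, fp = frac(acanyons), frac(pcanyons)
    if fp == 0:
        return math.inf if fa > 0 else math.nan
    return fa / fp


def classify_interactions(
    anchor_pairs: Sequence[tuple[GenomicInterval, GenomicInterval]],
    regions: Sequence[GenomicInterval],
) -> list[str]:
    """Label anchor pairs: 'self-interacting' when both anchors overlap the
    SAME region, 'distant-interacting' when at least one anchor is in a
    region but no single region holds both, 'none' otherwise."""
    labels = []
    for a, b in anchor_pairs:
        hits_a = {i for i, r in enumerate(regions) if r.overlaps(a)}
        hits_b = {i for i, r in enumerate(regions) if r.overlaps(b)}
        if hits_a & hits_b:
            labels.append("self-interacting")
        elif hits_a or hits_b:
            labels.append("distant-interacting")
        else:
            labels.append("none")
    return labels


def shuffle_regions(
    regions: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """One random region per input, of identical length, mutually
    non-overlapping; seeded and deterministic."""
    return sample_background(
        chrom_sizes,
        n=len(regions),
        lengths=[r.length for r in regions],
        seed=seed,
        resample=False,
    )
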