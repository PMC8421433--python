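"""Undermethylated region (UMR) and methylation-canyon calling.

UMRs are maximal runs of at least four consecutive sufficiently covered CpGs
whose per-CpG methylation ratio is below 10%; adjacent UMRs merge when the
merged span's methylation stays below the threshold. UMRs spanning >= 3.5 kb
are canyons. Canyons are split by their concurrence ratio against a genome
background: the concurrence of 10,000 non-overlapping random regions is
fitted by maximum likelihood to seven classical distribution families
(normal, log-normal, beta, gamma, uniform, exponential, logistic), the
family with the smallest Cramér-von Mises distance wins, and the 90th
percentile of the winning fit is the threshold. Canyons above it are
Polycomb-like pCanyons, the rest active aCanyons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import GeneModel, GenomicInterval

__all__ = [
    "CpGMethTrack",
    "UMRCall",
    "CanyonCall",
    "BackgroundFit",
    "meth_track_from_records",
    "call_umrs",
    "call_canyons",
    "sample_background",
    "fit_background",
    "classify_canyons",
    "assign_targets",
]


@dataclass(frozen=True)
class CpGMethTrack:
    """Per-CpG mean methylation with read coverage, one chromosome."""

    chrom: str
    positions: np.ndarray  # sorted CpG coordinates
    meth: np.ndarray  # methylation ratio per CpG
    coverage: np.ndarray  # reads per CpG

    def __post_init__(self):
        if not (len(self.positions) == len(self.meth) == len(self.coverage)):
            raise ValueError("track arrays must share a length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("track positions must be strictly increasing")


@dataclass(frozen=True)
class UMRCall:
    interval: GenomicInterval
    n_cpgs: int
    mean_meth: float


@dataclass(frozen=True)
class CanyonCall:
    umr: UMRCall
    concurrence: float | None = None
    klass: str | None = None  # 'aCanyon' | 'pCanyon'
    target_genes: tuple[str, ...] = ()

    @property
    def interval(self) -> GenomicInterval:
        return self.umr.interval


@dataclass(frozen=True)
class BackgroundFit:
    n: int
    fits: dict  # family -> {"params": tuple, "cvm": float}
    skipped: dict  # family -> reason
    best_family: str
    threshold: float  # 90th percentile of the best fitted distribution


def meth_track_from_records(records, coverage_min: int = 4) -> dict[str, CpGMethTrack]:
    """Build per-chromosome methylation tracks from epireads, keeping only
    CpGs covered by at least ``coverage_min`` reads."""
    from .concurrence import mean_methylation_track

    tracks = {}
    for chrom, t in mean_methylation_track(records, coverage_min).items():
        positions = np.array(sorted(t))
        tracks[chrom] = CpGMethTrack(
            chrom,
            positions,
            np.array([t[p][0] for p in positions]),
            np.array([t[p][1] for p in positions]),
        )
    return tracks


def _span_interval(track: CpGMethTrack, i: int, j: int) -> GenomicInterval:
    # CpGs i..j inclusive; half-open interval covering the member C positions
    return GenomicInterval(track.chrom, int(track.positions[i]),
                           int(track.positions[j]) + 1)


def _weighted_mean(track: CpGMethTrack, i: int, j: int) -> float:
    cov = track.coverage[i : j + 1]
    return float(np.sum(track.meth[i : j + 1] * cov) / np.sum(cov))


def call_umrs(
    track: CpGMethTrack, min_run: int = 4, max_meth: float = 0.10
) -> list[UMRCall]:
    """Maximal runs of >= min_run consecutive undermethylated CpGs, then a
    greedy left-to-right merge of consecutive UMR pairs whenever the merged
    span's coverage-weighted mean methylation (intervening CpGs included)
    stays below ``max_meth``, iterated until stable."""
    under = track.meth < max_meth
    runs: list[tuple[int, int]] = []  # inclusive CpG index spans
    start = None
    for i, u in enumerate(under):
        if u and start is None:
            start = i
        elif not u and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(under) - start >= min_run:
        runs.append((start, len(under) - 1))

    changed = True
    while changed:
        changed = False
        merged: list[tuple[int, int]] = []
        k = 0
        while k < len(runs):
            if merged:
                i, _ = merged[-1]
                _, j = runs[k]
                if _weighted_mean(track, merged[-1][0], j) < max_meth:
                    merged[-1] = (merged[-1][0], j)
                    changed = True
                    k += 1
                    continue
            merged.append(runs[k])
            k += 1
        runs = merged
    return [
        UMRCall(
            interval=_span_interval(track, i, j),
            n_cpgs=j - i + 1,
            mean_meth=_weighted_mean(track, i, j),
        )
        for i, j in runs
    ]


def call_canyons(umrs: Sequence[UMRCall], min_length_bp: int = 3500) -> list[CanyonCall]:
    """UMRs spanning at least ``min_length_bp`` become (unclassified) canyons."""
    return [CanyonCall(u) for u in umrs if u.interval.length >= min_length_bp]


def sample_background(
    chrom_sizes: Mapping[str, int],
    n: int = 10000,
    lengths: Sequence[int] | int = 1000,
    seed: int | np.random.Generator = 0,
    max_tries_per_region: int = 1000,
    resample: bool = True,
) -> list[GenomicInterval]:
    """Place ``n`` mutually non-overlapping random regions on the genome.

    ``lengths`` is either a fixed length or a pool resampled with
    replacement (e.g. observed canyon lengths); with ``resample=False`` the
    i-th region takes exactly ``lengths[i]`` (length-matched shuffling).
    Deterministic under seed; raises if a region cannot be placed within the
    retry budget.
    """
    if not resample and (isinstance(lengths, int) or len(lengths) != n):
        raise ValueError("resample=False requires one length per region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[GenomicInterval] = []
    import bisect

    for k in range(n):
        if isinstance(lengths, int):
            length = lengths
        elif resample:
            length = int(lengths[rng.integers(0, len(lengths))])
        else:
            length = int(lengths[k])
        for _try in range(max_tries_per_region):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            limit = chrom_sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            spans = placed[chrom]
            i = bisect.bisect_left(spans, (start, end))
            if i > 0 and spans[i - 1][1] > start:
                continue
            if i < len(spans) and spans[i][0] < end:
                continue
            spans.insert(i, (start, end))
            out.append(GenomicInterval(chrom, start, end))
            break
        else:
            raise RuntimeError(
                f"could not place region {len(out) + 1}/{n} without overlap; "
                "genome too small for the requested background"
            )
    return out


# family name -> (scipy distribution, fixed-fit kwargs, n free params)
_FAMILIES: list[tuple[str, object, dict, int]] = [
    ("normal", stats.norm, {}, 2),
    ("log-normal", stats.lognorm, {"floc": 0}, 2),
    ("beta", stats.beta, {"floc": 0, "fscale": 1}, 2),
    ("gamma", stats.gamma, {"floc": 0}, 2),
    ("uniform", stats.uniform, {}, 2),
    ("exponential", stats.expon, {"floc": 0}, 1),
    ("logistic", stats.logistic, {}, 2),
]

_POSITIVE_SUPPORT = {"log-normal", "beta", "gamma", "exponential"}


def fit_background(values: Sequence[float], quantile: float = 0.90) -> BackgroundFit:
    """MLE-fit the seven classical families to background concurrence values
    and select by Cramér-von Mises distance; threshold = the winning fit's
    90th percentile.

    Families whose support excludes an observed value (e.g. log-normal with
    zeros) are skipped with a note. Ties go to the family with fewer
    parameters, then to declaration order.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 100:
        raise ValueError(f"need >= 100 background values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all background values identical; nothing to fit")
    fits: dict[str, dict] = {}
    skipped: dict[str, str] = {}
    for name, dist, fkw, _nparam in _FAMILIES:
        if name in _POSITIVE_SUPPORT and x.min() <= 0:
            skipped[name] = "support excludes non-positive values"
            continue
        if name == "beta" and x.max() >= 1:
            skipped[name] = "support excludes values >= 1"
            continue
        try:
            params = dist.fit(x, **fkw)
            cvm = float(stats.cramervonmises(x, dist(*params).cdf).statistic)
        except Exception as exc:  # pragma: no cover - scipy fit edge cases
            skipped[name] = f"fit failed: {exc}"
            continue
        if not np.isfinite(cvm):
            skipped[name] = "non-finite CvM distance"
            continue
        fits[name] = {"params": tuple(float(p) for p in params), "cvm": cvm}
    if not fits:
        raise RuntimeError("no distribution family could be fitted")
    order = {name: i for i, (name, *_rest) in enumerate(_FAMILIES)}
    nparam = {name: k for name, _d, _f, k in _FAMILIES}
    best = min(fits, key=lambda f: (fits[f]["cvm"], nparam[f], order[f]))
    dist = next(d for nm, d, _f, _k in _FAMILIES if nm == best)
    threshold = float(dist(*fits[best]["params"]).ppf(quantile))
    return BackgroundFit(
        n=int(x.size), fits=fits, skipped=skipped,
        best_family=best, threshold=threshold,
    )


def classify_canyons(
    canyons: Sequence[CanyonCall], fit: BackgroundFit
) -> list[CanyonCall]:
    """pCanyon when concurrence strictly exceeds the background threshold,
    aCanyon otherwise (ties included)."""
    out = []
    for c in canyons:
        if c.concurrence is None:
            raise ValueError(f"canyon {c.interval} has no concurrence value")
        out.append(
            replace(c, klass="pCanyon" if c.concurrence > fit.threshold else "aCanyon")
        )
    return out


def assign_targets(
    canyons: Sequence[CanyonCall], genes: Sequence[GeneModel]
) -> list[CanyonCall]:
    """A gene targets a canyon when its promoter or gene body overlaps the
    canyon by >= 1 bp; many-to-many."""
    gene_regions: list[tuple[str, GenomicInterval]] = []
    for g in genes:
        gene_regions.append((g.gene_id, g.promoter()))
        try:
            gene_regions.append((g.gene_id, g.gene_body()))
        except ValueError:
            pass  # gene too short to have a body beyond the promoter
    out = []
    for c in canyons:
        targets = sorted(
            {gid for gid, region in gene_regions if region.overlaps(c.interval)}
        )
        out.append(replace(c, target_genes=tuple(targets)))
    return out
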