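"""Synthetic epiread generator with closed-form ground truth.

Reads are placed uniformly over a synthetic CpG map and calls are drawn from
a two-state Markov chain along the read: the first CpG is Bernoulli(p) and
each subsequent CpG copies the previous state with probability ``rho`` or
draws a fresh Bernoulli(p) otherwise. This keeps the stationary per-CpG
methylation level at ``p`` for every ``rho``, so ``rho`` is a pure
within-read concordance knob: rho=0 gives independent calls, rho=1 fully
concordant reads (which carry no concurrence signal at all).

Ground truth under this model is exact. For independent calls the expected
weighted concurrence of a k-CpG read set is ``(1-p) * (1 - (1-p)**(k-1))``
(an unmethylated CpG contributes a C label unless its whole read is
unmethylated); for rho > 0 the expectation is computed by enumerating the
2^k patterns of a read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import EpireadRecord, GenomicInterval

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "expected_concurrence_iid",
    "expected_metrics",
    "simulate_epireads",
    "plant_umrs",
    "simulate_knockout",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults give a 2,000-CpG map at 50x coverage
    with 4-CpG reads, 50% methylation and independent calls."""

    n_cpgs: int = 2000
    cpg_spacing: int | tuple[int, int] = 100  # fixed bp, or uniform (lo, hi)
    coverage: float = 50.0  # target reads per CpG
    cpgs_per_read: int = 4
    p_meth: float = 0.5
    rho: float = 0.0
    chrom: str = "chrSim"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.p_meth <= 1:
            raise ValueError(f"p_meth must be in [0,1], got {self.p_meth}")
        if not 0 <= self.rho <= 1:
            raise ValueError(f"rho must be in [0,1], got {self.rho}")
        if self.cpgs_per_read < 1 or self.n_cpgs < self.cpgs_per_read:
            raise ValueError("need cpgs_per_read >= 1 and n_cpgs >= cpgs_per_read")


@dataclass(frozen=True)
class GroundTruth:
    expected_concurrence: float
    expected_mean_meth: float
    expected_entropy: float  # bits, over 4-CpG epialleles
    config: SimulationConfig


def expected_concurrence_iid(p: float, k: int) -> float:
    """Closed-form expected weighted concurrence for i.i.d. Bernoulli(p)
    calls on k-CpG reads: (1-p) * (1 - (1-p)**(k-1))."""
    return (1 - p) * (1 - (1 - p) ** (k - 1))


def _pattern_probability(pattern: Sequence[int], p: float, rho: float) -> float:
    prob = p if pattern[0] == 1 else 1 - p
    for prev, cur in zip(pattern, pattern[1:]):
        step = (1 - rho) * (p if cur == 1 else 1 - p)
        if cur == prev:
            step += rho
        prob *= step
    return prob


def expected_metrics(p: float, rho: float, k: int) -> tuple[float, float, float]:
    """(expected concurrence, mean methylation, 4-CpG entropy in bits) under
    the Markov read model, by enumerating the 2^k read patterns."""
    if p in (0.0, 1.0):
        ent = 0.0
        return 0.0, p, ent
    exp_c = 0.0
    for pattern in itertools.product((0, 1), repeat=k):
        if 0 in pattern and 1 in pattern:
            exp_c += _pattern_probability(pattern, p, rho) * pattern.count(0)
    entropy = 0.0
    for pattern in itertools.product((0, 1), repeat=4):
        q = _pattern_probability(pattern, p, rho)
        if q > 0:
            entropy -= q * np.log2(q)
    return exp_c / k, p, float(entropy)


def _make_cpg_map(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.cpg_spacing, int):
        gaps = np.full(config.n_cpgs, config.cpg_spacing)
    else:
        lo, hi = config.cpg_spacing
        gaps = rng.integers(lo, hi + 1, size=config.n_cpgs)
    return np.cumsum(gaps) + 1000  # offset keeps coordinates comfortably > 0


def _draw_calls(
    n_reads: int, k: int, p: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized Markov draws; ``p`` is an (n_reads, k) matrix of per-CpG
    stationary probabilities (supports region-dependent methylation)."""
    calls = np.empty((n_reads, k), dtype=np.int8)
    calls[:, 0] = rng.random(n_reads) < p[:, 0]
    for j in range(1, k):
        fresh = rng.random(n_reads) < p[:, j]
        copy = rng.random(n_reads) < rho
        calls[:, j] = np.where(copy, calls[:, j - 1], fresh)
    return calls


def simulate_epireads(
    config: SimulationConfig,
    p_per_cpg: np.ndarray | None = None,
) -> tuple[list[EpireadRecord], GroundTruth]:
    """Generate epireads over a synthetic CpG map; returns (records, truth).

    ``p_per_cpg`` optionally overrides the scalar ``p_meth`` with a per-CpG
    stationary level (used for planting undermethylated spans).
    """
    rng = np.random.default_rng(config.seed)
    positions = _make_cpg_map(config, rng)
    k = config.cpgs_per_read
    n_reads = int(round(config.n_cpgs * config.coverage / k))
    starts = rng.integers(0, config.n_cpgs - k + 1, size=n_reads)
    if p_per_cpg is None:
        p_mat = np.full((n_reads, k), config.p_meth)
    else:
        p_per_cpg = np.asarray(p_per_cpg, dtype=float)
        if p_per_cpg.shape != (config.n_cpgs,):
            raise ValueError("p_per_cpg must have one probability per CpG")
        p_mat = p_per_cpg[starts[:, None] + np.arange(k)[None, :]]
    calls = _draw_calls(n_reads, k, p_mat, config.rho, rng)
    records = [
        EpireadRecord(
            config.chrom,
            f"sim_{i}",
            tuple(int(x) for x in positions[s : s + k]),
            tuple(int(c) for c in calls[i]),
        )
        for i, s in enumerate(starts)
    ]
    exp_c, exp_m, exp_h = expected_metrics(config.p_meth, config.rho, k)
    return records, GroundTruth(exp_c, exp_m, exp_h, config)


def plant_umrs(
    config: SimulationConfig,
    umr_spec: Sequence[tuple[int, int, float]],
    background_p: float = 0.8,
) -> tuple[list[EpireadRecord], list[GenomicInterval], np.ndarray]:
    """Plant low-methylation spans in a methylated background.

    ``umr_spec`` lists (start_bp, end_bp, p_inside) spans on the simulated
    chromosome; spans must not overlap. Returns (records, truth intervals
    spanning each span's first to last CpG, cpg position array).
    """
    spans = sorted(umr_spec)
    for (s1, e1, _), (s2, _e2, _p) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping planted spans at {s2} < {e1}")
    rng = np.random.default_rng(config.seed)
    positions = _make_cpg_map(config, rng)
    p_per_cpg = np.full(config.n_cpgs, background_p)
    truths = []
    for start, end, p_in in spans:
        inside = (positions >= start) & (positions < end)
        if not inside.any():
            raise ValueError(f"planted span [{start},{end}) covers no CpG")
        p_per_cpg[inside] = p_in
        member = positions[inside]
        truths.append(
            GenomicInterval(config.chrom, int(member[0]), int(member[-1]) + 1)
        )
    # regenerate the map with the same seed inside simulate_epireads
    records, _ = simulate_epireads(
        replace(config, p_meth=background_p), p_per_cpg=p_per_cpg
    )
    return records, truths, positions


def simulate_knockout(
    config: SimulationConfig,
    mode: str,
    effect: float = 0.5,
) -> tuple[list[EpireadRecord], list[EpireadRecord], GroundTruth, GroundTruth]:
    """Paired baseline/perturbed read sets sharing the CpG map and seed.

    ``dnmt_down`` pulls the methylation level toward 0 (lost
    methyltransferase), ``tet_down`` pushes it toward 1 (lost
    demethylation), and ``both_down`` drives within-read persistence toward
    1 (reads become concordant, erasing concurrence).
    """
    if mode == "dnmt_down":
        perturbed = replace(config, p_meth=config.p_meth * (1 - effect))
    elif mode == "tet_down":
        perturbed = replace(config, p_meth=config.p_meth + (1 - config.p_meth) * effect)
    elif mode == "both_down":
        perturbed = replace(config, rho=config.rho + (1 - config.rho) * effect)
    else:
        raise ValueError(f"unknown knockout mode {mode!r}")
    base_records, base_truth = simulate_epireads(config)
    pert_records, pert_truth = simulate_epireads(perturbed)
    return base_records, pert_records, base_truth, pert_truth
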