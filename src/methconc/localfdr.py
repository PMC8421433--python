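"""Replicate-free differential calling via local false discovery rate.

For matched sample pairs without replicates, the per-gene difference d of a
promoter metric is modelled as a two-group mixture: non-differential genes
with null density f0 and differential genes. Working on |d| (so one
threshold serves both directions), f0 is a half-normal whose scale is fitted
by truncated maximum likelihood on genes whose |d| falls in the middle third
of the null band [0, B] (the interval [B/3, 2B/3]); the near-zero peak and
the upper third, where differential genes start to mix in, are excluded.
The marginal f is a Gaussian kernel density on all |d|, reflected at zero.
local-fdr_j = f0(|d_j|)/f(|d_j|) upper-bounds the posterior probability that
gene j is non-differential (the null proportion p0 <= 1 is omitted); genes
below the cutoff (default 0.2) in the requested direction are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DiffRecord",
    "LocalFdrModel",
    "OverlapClasses",
    "metric_difference",
    "fit_halfnormal_truncated",
    "fit_localfdr",
    "classify_overlap",
    "filter_external_pvalues",
    "export_group_metric_table",
]


@dataclass(frozen=True)
class DiffRecord:
    gene_id: str
    d: float
    local_fdr: float | None = None
    flagged: bool = False

    @property
    def abs_d(self) -> float:
        return abs(self.d)


@dataclass(frozen=True)
class LocalFdrModel:
    sigma0: float
    null_band: float
    fit_window: tuple[float, float]
    cutoff: float
    direction: str
    kde_bandwidth: float
    n_fit: int


@dataclass(frozen=True)
class OverlapClasses:
    """Partition of flagged genes: concurrence-only (P1), mean-only (P2),
    both (P3)."""

    p1: frozenset[str]
    p2: frozenset[str]
    p3: frozenset[str]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.p1), len(self.p2), len(self.p3)


def metric_difference(
    metrics_a: Mapping[str, float],
    metrics_b: Mapping[str, float],
    genes: Iterable[str] | None = None,
) -> tuple[list[DiffRecord], int]:
    """Per-gene signed difference a - b; returns (records, n_dropped).

    Genes missing (or NaN) in either sample are dropped and counted.
    """
    universe = set(genes) if genes is not None else set(metrics_a) | set(metrics_b)
    records = []
    dropped = 0
    for g in sorted(universe):
        va, vb = metrics_a.get(g), metrics_b.get(g)
        if va is None or vb is None or math.isnan(va) or math.isnan(vb):
            dropped += 1
            continue
        records.append(DiffRecord(g, va - vb))
    if not records:
        raise ValueError("no genes shared by both samples")
    return records, dropped


def halfnormal_pdf(x, sigma: float):
    """Half-normal density on x >= 0 (mean-zero normal folded at 0)."""
    x = np.asarray(x, dtype=float)
    return np.where(
        x >= 0,
        math.sqrt(2 / math.pi) / sigma * np.exp(-(x**2) / (2 * sigma**2)),
        0.0,
    )


def _halfnormal_cdf(x: float, sigma: float) -> float:
    return math.erf(x / (sigma * math.sqrt(2)))


def fit_halfnormal_truncated(
    values: np.ndarray, lo: float, hi: float
) -> float:
    """MLE of the half-normal scale from a sample truncated to [lo, hi].

    Maximizes the truncated likelihood (the plain MLE on a truncated sample
    is inconsistent). Returns sigma.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values in the fitting interval")
    if np.ptp(values) == 0 and values[0] == 0:
        raise ValueError("degenerate (all-zero) differences; no null variance")

    ss = float(np.mean(values**2))

    def neg_loglik(log_sigma: float) -> float:
        sigma = math.exp(log_sigma)
        mass = _halfnormal_cdf(hi, sigma) - _halfnormal_cdf(lo, sigma)
        if mass <= 0:
            return 1e300  # finite penalty keeps the bounded optimizer stable
        return (
            values.size * math.log(sigma)
            + values.size * ss / (2 * sigma**2)
            + values.size * math.log(mass)
        )

    res = optimize.minimize_scalar(
        neg_loglik,
        bounds=(math.log(max(hi, 1e-12)) - 12, math.log(max(hi, 1e-12)) + 6),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError("half-normal truncated MLE failed to converge")
    return math.exp(res.x)


class _ReflectedKDE:
    """Gaussian KDE on non-negative data, reflected at zero."""

    def __init__(self, values: np.ndarray, bandwidth: float | None = None):
        values = np.asarray(values, dtype=float)
        if bandwidth is None:
            kde = stats.gaussian_kde(values, bw_method="silverman")
            self.bandwidth = float(kde.factor * values.std(ddof=1))
        else:
            self.bandwidth = float(bandwidth)
        if self.bandwidth <= 0:
            raise ValueError("KDE bandwidth must be positive")
        self._kde = stats.gaussian_kde(
            values, bw_method=self.bandwidth / values.std(ddof=1)
        )

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return self._kde(x) + self._kde(-x)


def fit_localfdr(
    records: Sequence[DiffRecord],
    null_band: float = 0.10,
    cutoff: float = 0.2,
    kde_bandwidth: float | None = None,
    direction: str = "both",
    min_null: int = 50,
    interval_mode: str = "range",
    min_effect: float | None = None,
) -> tuple[LocalFdrModel, list[DiffRecord]]:
    """Fit the half-normal/KDE local-fdr model and flag differential genes.

    ``interval_mode`` "range" takes the middle third of [0, null_band] as the
    fitting window; "rank" takes the middle tercile by rank of the |d| below
    the band. ``direction`` gates flags to d > 0 ("up"), d < 0 ("down") or
    both. ``min_effect`` additionally requires |d| >= min_effect for a flag
    (e.g. 0.4 for a notable entropy change); it does not affect the fit.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"invalid direction {direction!r}")
    abs_d = np.array([r.abs_d for r in records])
    if np.ptp(abs_d) == 0:
        raise ValueError("all differences identical; null model is degenerate")
    in_band = abs_d[abs_d < null_band]
    if in_band.size < min_null:
        raise ValueError(
            f"only {in_band.size} genes with |d| < {null_band}; "
            f"widen --null-band (floor is {min_null})"
        )
    if interval_mode == "range":
        lo, hi = null_band / 3, 2 * null_band / 3
    elif interval_mode == "rank":
        lo, hi = np.quantile(in_band, [1 / 3, 2 / 3])
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError(f"invalid interval_mode {interval_mode!r}")
    fit_sample = in_band[(in_band >= lo) & (in_band <= hi)]
    if fit_sample.size == 0:
        raise ValueError("no genes in the null fitting interval")
    sigma0 = fit_halfnormal_truncated(fit_sample, lo, hi)

    kde = _ReflectedKDE(abs_d, kde_bandwidth)
    f0 = halfnormal_pdf(abs_d, sigma0)
    f = np.maximum(kde(abs_d), np.finfo(float).tiny)
    lfdr = np.maximum(f0 / f, np.finfo(float).eps)

    annotated = []
    for rec, v in zip(records, lfdr):
        ok_dir = (
            direction == "both"
            or (direction == "up" and rec.d > 0)
            or (direction == "down" and rec.d < 0)
        )
        ok_effect = min_effect is None or rec.abs_d >= min_effect
        annotated.append(
            replace(
                rec,
                local_fdr=float(v),
                flagged=bool(v < cutoff and ok_dir and ok_effect),
            )
        )
    model = LocalFdrModel(
        sigma0=sigma0,
        null_band=null_band,
        fit_window=(lo, hi),
        cutoff=cutoff,
        direction=direction,
        kde_bandwidth=kde.bandwidth,
        n_fit=int(fit_sample.size),
    )
    return model, annotated


def classify_overlap(
    flagged_concurrence: Iterable[str], flagged_mean: Iterable[str]
) -> OverlapClasses:
    """Set algebra over the two flag lists: P1 = concurrence only,
    P2 = mean only, P3 = both."""
    conc, mean = set(flagged_concurrence), set(flagged_mean)
    return OverlapClasses(
        p1=frozenset(conc - mean),
        p2=frozenset(mean - conc),
        p3=frozenset(conc & mean),
    )


def filter_external_pvalues(table, alpha: float = 0.005, column: str = "p"):
    """Keep rows of an external differential-test table with p < alpha
    (strict); the test itself is run outside this package."""
    if column not in table.columns:
        raise ValueError(f"table lacks required p-value column {column!r}")
    return table[table[column] < alpha].copy()


def export_group_metric_table(
    groups: Mapping[str, Mapping[str, float]], path
) -> None:
    """Write a gene x sample metric matrix (TSV) for an external
    replicate-aware differential caller."""
    import pandas as pd

    df = pd.DataFrame(groups)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
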