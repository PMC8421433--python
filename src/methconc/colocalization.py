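"""DNMT/TET promoter binding standardization and the joint regulation score.

Binding intensity at a promoter is the z-score of its log2 RPKM across
promoters. The joint regulation score of a promoter multiplies the min-max
rescaled intensities of the methyltransferase (D) and the dioxygenase (T):

    score = (pi_D - min_D)/(max_D - min_D) * (pi_T - min_T)/(max_T - min_T)

so it lies in [0, 1], hits 0 when either enzyme is at its minimum and 1 only
at the joint maximum. Promoters can further be split into four co-occupancy
groups (D+T+, D+T-, D-T+, D-T-) by a per-enzyme threshold rule, and promoter
CpG density classed as HCP/ICP/LCP from the CpG ratio
(CpGs x length) / (Cs x Gs).
"""

from __future__ import annotations

import statistics
from typing import Mapping

__all__ = [
    "standardize_intensity",
    "joint_regulation_score",
    "group_promoters",
    "cpg_ratio",
]

# HCP/ICP/LCP cutoffs follow the common CpG-ratio convention used for
# promoter classification (high > 0.75, low < 0.48); they are not derived
# here and are fully configurable.
DEFAULT_HCP_MIN = 0.75
DEFAULT_LCP_MAX = 0.48


def standardize_intensity(
    rpkm_log2: Mapping[str, float], ddof: int = 0
) -> dict[str, float]:
    """Z-score intensities across promoters: pi = (x - mean)/sd.

    Population sd by default (``ddof=0``); raises on fewer than two
    promoters or zero variance.
    """
    if len(rpkm_log2) < 2:
        raise ValueError("need at least 2 promoters to standardize")
    xs = list(rpkm_log2.values())
    mu = statistics.fmean(xs)
    var = sum((x - mu) ** 2 for x in xs) / (len(xs) - ddof)
    if var == 0:
        raise ValueError("zero variance across promoters; cannot standardize")
    sd = var**0.5
    return {k: (x - mu) / sd for k, x in rpkm_log2.items()}


def joint_regulation_score(
    profile_d: Mapping[str, float], profile_t: Mapping[str, float]
) -> dict[str, float]:
    """Min-max rescaled product of the two standardized intensities."""
    if set(profile_d) != set(profile_t):
        raise ValueError("profiles must cover the same promoter universe")
    d_min, d_max = min(profile_d.values()), max(profile_d.values())
    t_min, t_max = min(profile_t.values()), max(profile_t.values())
    if d_max == d_min or t_max == t_min:
        raise ValueError("degenerate intensity range (max == min)")
    return {
        k: ((profile_d[k] - d_min) / (d_max - d_min))
        * ((profile_t[k] - t_min) / (t_max - t_min))
        for k in profile_d
    }


def group_promoters(
    profile_d: Mapping[str, float],
    profile_t: Mapping[str, float],
    rule: str = "median",
) -> dict[str, str]:
    """Label each promoter D+/-T+/- by per-enzyme threshold split.

    ``rule`` is "median" or "quantile:Q" (e.g. "quantile:0.75"); an enzyme is
    '+' where its intensity strictly exceeds the cutoff.
    """
    if set(profile_d) != set(profile_t):
        raise ValueError("profiles must cover the same promoter universe")
    if rule == "median":
        q = 0.5
    elif rule.startswith("quantile:"):
        q = float(rule.split(":", 1)[1])
        if not 0 < q < 1:
            raise ValueError(f"quantile must be in (0,1), got {q}")
    else:
        raise ValueError(f"unknown grouping rule {rule!r}")
    import numpy as np

    cut_d = float(np.quantile(list(profile_d.values()), q))
    cut_t = float(np.quantile(list(profile_t.values()), q))
    return {
        k: f"D{'+' if profile_d[k] > cut_d else '-'}"
        f"T{'+' if profile_t[k] > cut_t else '-'}"
        for k in profile_d
    }


def cpg_ratio(
    n_cpg: int,
    n_c: int,
    n_g: int,
    length_bp: int,
    hcp_min: float = DEFAULT_HCP_MIN,
    lcp_max: float = DEFAULT_LCP_MAX,
) -> tuple[float, str] | None:
    """CpG ratio (CpGs x bp)/(Cs x Gs) and HCP/ICP/LCP class.

    Returns None when the sequence has no C or no G (ratio undefined).
    """
    if n_c <= 0 or n_g <= 0:
        return None
    ratio = (n_cpg * length_bp) / (n_c * n_g)
    if ratio >= hcp_min:
        cls = "HCP"
    elif ratio < lcp_max:
        cls = "LCP"
    else:
        cls = "ICP"
    return ratio, cls
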