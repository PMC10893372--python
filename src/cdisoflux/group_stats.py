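"""Nonparametric group comparisons for pooled treatment designs.

The experimental design crosses hydroponic/foliar Fe and Zn, so treatments
sharing one design variable are pooled and compared with the Kruskal-Wallis
rank test (small samples, mostly non-normal variables). H and its
chi-square p-value come from scipy; for very small pooled samples
(n <= 12 by default) the p-value is replaced by the exact permutation
distribution of H, enumerated over all assignments of the pooled values to
the group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "exact_kruskal_pvalue",
    "pooled_group_compare",
    "SIGNIFICANCE_LEVEL",
]

#: Conventional significance threshold used by the reporting layer.
SIGNIFICANCE_LEVEL = 0.05

#: Largest pooled sample size for which the permutation null is enumerated.
EXACT_CUTOFF = 12


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    factor: str
    group_sizes: tuple[int, ...]
    h_statistic: float
    p_value: float
    method: str  # "chi-square approximation" | "exact permutation"

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def _h_statistic(pooled: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for groups laid out contiguously."""
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 0.0
    start = 0
    for size in sizes:
        rsum = ranks[start : start + size].sum()
        h += rsum * rsum / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n**3 - n)
    if denom <= 0:  # every value identical
        return 0.0
    return float(h / denom)


def exact_kruskal_pvalue(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Exact permutation p-value of the Kruskal-Wallis H statistic.

    Enumerates every assignment of the pooled observations to groups of the
    observed sizes (multinomial enumeration over index subsets) and returns
    (H_observed, P[H >= H_observed]). Only intended for small pooled n.
    """
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = _h_statistic(pooled, sizes)
    n = len(pooled)

    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], size_idx: int, chosen: list[int]) -> None:
        nonlocal count, total
        if size_idx == len(sizes) - 1:
            perm = pooled[np.array(chosen + list(remaining), dtype=int)]
            total += 1
            if _h_statistic(perm, sizes) >= h_obs - 1e-12:
                count += 1
            return
        for subset in combinations(remaining, sizes[size_idx]):
            rest = tuple(i for i in remaining if i not in subset)
            recurse(rest, size_idx + 1, chosen + list(subset))

    recurse(tuple(range(n)), 0, [])
    return h_obs, count / total


def kruskal_wallis(
    groups: Sequence[Sequence[float]],
    variable: str = "",
    factor: str = "",
    exact_cutoff: int = EXACT_CUTOFF,
) -> GroupComparison:
    """Kruskal-Wallis comparison of two or more groups.

    H carries the usual tie correction. The p-value uses the chi-square
    approximation (df = k - 1) except when the pooled sample is small
    (n <= ``exact_cutoff``), where the exact permutation distribution is
    enumerated instead. Degenerate data (all values identical) yield
    H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    sizes = tuple(len(a) for a in arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison(variable, factor, sizes, 0.0, 1.0, "degenerate (constant data)")
    if len(pooled) <= exact_cutoff:
        h, p = exact_kruskal_pvalue(arrays)
        method = "exact permutation"
    else:
        h, p = stats.kruskal(*arrays)
        method = "chi-square approximation"
    return GroupComparison(variable, factor, sizes, float(h), float(p), method)


def pooled_group_compare(
    records: pd.DataFrame,
    factor: str,
    variable: str,
    exact_cutoff: int = EXACT_CUTOFF,
) -> GroupComparison:
    """Compare a derived variable between plants pooled on one design flag.

    ``records`` is a per-plant table (e.g. from ``derived_to_frame``);
    ``factor`` a boolean column (hydro_fe, hydro_zn, foliar_fe, foliar_zn);
    ``variable`` a numeric column. Rows with missing values are dropped.
    """
    if factor not in records.columns:
        raise ValueError(f"unknown factor column {factor!r}")
    if variable not in records.columns:
        raise ValueError(f"unknown variable column {variable!r}")
    sub = records[[factor, variable]].dropna()
    flag = sub[factor].astype(bool)
    groups = [sub.loc[flag, variable].to_numpy(), sub.loc[~flag, variable].to_numpy()]
    if any(len(g) == 0 for g in groups):
        raise ValueError(f"factor {factor!r} does not split the records into two groups")
    return kruskal_wallis(groups, variable=variable, factor=factor, exact_cutoff=exact_cutoff)
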