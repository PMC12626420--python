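"""Genotype comparisons of the behavioral measure matrix.

Each named measure is compared between a mutant genotype group and its
wild-type siblings with a tie-corrected Kruskal-Wallis test, and the signed
effect size is the strictly standardized mean difference

    SSMD = (mean_a - mean_b) / sqrt(var_a + var_b)

(sample variances).  Results are rolled up into the screen's bubble summary:
per summarized category (frequency, magnitude, location, latency) and SSMD
sign, the percent of measures significant and the mean SSMD of those
significant measures.

For small cohorts (total n <= ``exact_max_n``) the Kruskal-Wallis p-value is
computed exactly by enumerating all assignments of the observed values to
groups; otherwise the chi-square approximation is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior_features import parse_measure_name, CATEGORY_BY_MEASURE
from .synthetic import GenotypeMap

__all__ = [
    "ComparisonResult",
    "ssmd",
    "kruskal_wallis",
    "compare_measure",
    "compare_all_measures",
    "summarize_categories",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    """One measure's genotype contrast."""

    measure: str
    group_a: str
    group_b: str
    p_value: float
    ssmd: float
    n_a: int
    n_b: int
    significant: bool
    testable: bool


def ssmd(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Strictly standardized mean difference, positive when group a is higher.

    NaN (flagged as undefined) when both groups have zero variance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def _h_statistic(values: np.ndarray, sizes: Sequence[int]) -> float:
    """Tie-corrected Kruskal-Wallis H for groups laid out contiguously."""
    n = values.size
    ranks = stats.rankdata(values)
    h = 0.0
    start = 0
    for m in sizes:
        h += ranks[start : start + m].sum() ** 2 / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0:
        return 0.0
    return h / tie


def kruskal_wallis(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "auto",
    exact_max_n: int = 10,
) -> tuple[float, float]:
    """Two-group Kruskal-Wallis test; returns (H, p).

    ``method`` is ``"auto"`` (exact enumeration when total n <= exact_max_n),
    ``"exact"`` or ``"asymptotic"``.  The exact p is the fraction of all
    assignments of the pooled values to groups of the observed sizes whose H
    is at least the observed H.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n = a.size + b.size
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if n <= exact_max_n else "asymptotic"
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0  # all values identical: no evidence against the null
    if method == "asymptotic":
        h, p = stats.kruskal(a, b)
        return float(h), float(p)
    pooled = np.concatenate([a, b])
    sizes = (a.size, b.size)
    h_obs = _h_statistic(pooled, sizes)
    idx_all = range(n)
    count = total = 0
    for comb in combinations(idx_all, a.size):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        h = _h_statistic(np.concatenate([pooled[mask], pooled[~mask]]), sizes)
        total += 1
        if h >= h_obs - 1e-12:
            count += 1
    return float(h_obs), count / total


def compare_measure(
    matrix: pd.DataFrame,
    genotypes: GenotypeMap,
    measure: str,
    group_pair: tuple[str, str] = ("-/-", "+/+"),
    alpha: float = DEFAULT_ALPHA,
    method: str = "auto",
    exact_max_n: int = 10,
    min_n: int = 2,
) -> ComparisonResult:
    """Compare one measure between two genotype groups.

    Missing values are dropped per group.  A group falling below ``min_n``
    non-missing values marks the result untestable (p = NaN, not
    significant) rather than raising.
    """
    if measure not in matrix.columns:
        raise KeyError(f"measure {measure!r} not in matrix")
    ga, gb = group_pair
    vals = {}
    for g in group_pair:
        ids = [i for i in genotypes.ids_of(g) if i in matrix.index]
        v = matrix.loc[ids, measure].dropna().to_numpy(dtype=float)
        vals[g] = v
    a, b = vals[ga], vals[gb]
    if a.size < min_n or b.size < min_n:
        return ComparisonResult(measure, ga, gb, float("nan"), float("nan"),
                                a.size, b.size, False, False)
    _, p = kruskal_wallis(a, b, method=method, exact_max_n=exact_max_n)
    effect = ssmd(a, b)
    return ComparisonResult(measure, ga, gb, p, effect, a.size, b.size,
                            bool(p < alpha), True)


def compare_all_measures(
    matrix: pd.DataFrame,
    genotypes: GenotypeMap,
    group_pair: tuple[str, str] = ("-/-", "+/+"),
    alpha: float = DEFAULT_ALPHA,
    method: str = "auto",
) -> pd.DataFrame:
    """Run :func:`compare_measure` over every column of the matrix."""
    rows = [
        compare_measure(matrix, genotypes, m, group_pair, alpha, method)
        for m in matrix.columns
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def summarize_categories(
    results: pd.DataFrame,
    category_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Roll per-measure results up into the bubble summary.

    Significant measures are split by SSMD sign into increased/decreased
    groups.  ``percent_significant`` uses the category's full measure count
    as denominator for each sign group; ``mean_ssmd`` averages the SSMDs of
    that sign group's significant measures only.  Categories with zero
    significant measures emit no rows.
    """
    if category_map is None:
        category_map = {
            m: CATEGORY_BY_MEASURE[parse_measure_name(m)[1]]
            for m in results["measure"]
        }
    unmapped = [m for m in results["measure"] if m not in category_map]
    if unmapped:
        raise KeyError(f"measures without a summarized category: {unmapped}")
    df = results.copy()
    df["category"] = [category_map[m] for m in df["measure"]]
    rows = []
    for category in sorted(df["category"].unique()):
        sub = df[df["category"] == category]
        n_measures = len(sub)
        sig = sub[sub["significant"]]
        for sign, label in ((1, "increased"), (-1, "decreased")):
            part = sig[np.sign(sig["ssmd"]) == sign]
            if len(part) == 0:
                continue
            rows.append(
                {
                    "category": category,
                    "sign": label,
                    "percent_significant": 100.0 * len(part) / n_measures,
                    "mean_ssmd": float(part["ssmd"].mean()),
                    "n_measures": n_measures,
                    "n_significant": len(part),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["category", "sign", "percent_significant", "mean_ssmd",
                 "n_measures", "n_significant"],
    )
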