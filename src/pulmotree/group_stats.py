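"""Two-group comparison of morphometric features, globally and per cluster.

Differences between experimental groups (e.g. hyperoxia-exposed vs
normoxic animals) are tested feature by feature with the two-sided
Mann-Whitney U test, which needs no distributional assumption and accepts
unequal sample sizes.  Each feature is compared once on all measured
segments pooled by group ("global") and once within every cluster of the
selected classification, so that a shift confined to one compartment is
not diluted away by the rest of the tree.

For significant shifts the nonparametric effect strength

    r = |z| / sqrt(N),   z = Phi^-1(p / 2),   N = n_A + n_B of the stratum

is reported and binned into the conventional categories (0.1-0.3 weak,
0.3-0.5 medium, > 0.5 strong).  Stars follow the usual convention:
* for p < 0.05, ** for p < 0.01.

No multiple-testing correction is applied by default; an optional
Benjamini-Hochberg adjustment over all computed rows can be switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import FEATURE_COLUMNS
from .ordering import ClassificationResult

__all__ = [
    "ComparisonResult",
    "mann_whitney",
    "effect_strength",
    "categorize_effect",
    "stars",
    "compare_groups",
    "comparison_table",
    "EXACT_LIMIT",
]

#: exact null distribution is enumerated when n*m <= this and there are no ties
EXACT_LIMIT = 400


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U the conventional min statistic
    min(U_x, U_y) = min(U_x, n*m - U_x), making the result invariant to
    swapping the samples.  The exact null distribution is used for small
    tie-free samples (n*m <= 400); otherwise the normal approximation with
    tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size * y.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x)
    return u, float(min(res.pvalue, 1.0))


def effect_strength(p: float, N: int) -> float:
    """Nonparametric effect strength r = |Phi^-1(p/2)| / sqrt(N).

    ``p`` is the two-sided Mann-Whitney p-value and ``N`` the total number
    of observations in the compared stratum.  Monotone decreasing in p at
    fixed N; halves when N quadruples.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    if N < 1:
        raise ValueError("N must be >= 1")
    z = stats.norm.ppf(p / 2.0)
    return float(abs(z) / math.sqrt(N))


def categorize_effect(r: float) -> str:
    """Bin an effect strength into none / weak / medium / strong.

    Bands closed on the left: [0.1, 0.3) weak, [0.3, 0.5) medium,
    >= 0.5 strong, below 0.1 none.
    """
    if r < 0:
        raise ValueError("effect strength must be non-negative")
    if r < 0.1:
        return "none"
    if r < 0.3:
        return "weak"
    if r < 0.5:
        return "medium"
    return "strong"


def stars(p: float | None) -> str:
    """Significance stars: ** for p < 0.01, * for p < 0.05, '' otherwise."""
    if p is None or not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonResult:
    """One stratum/feature two-group test."""

    feature: str
    stratum: str  # "global" or the cluster label as text
    n_a: int
    n_b: int
    U: float | None
    p: float | None
    significant: str
    effect_r: float | None
    effect_category: str | None


def _long_frame(
    tables: dict[str, pd.DataFrame],
    assignments: dict[str, ClassificationResult],
    group_labels: dict[str, str],
) -> pd.DataFrame:
    """Stack per-sample tables into sample/group/cluster long format,
    dropping artificial and unclassified segments."""
    frames = []
    for sample_id, table in tables.items():
        if sample_id not in assignments:
            raise ValueError(f"no classification for sample {sample_id!r}")
        if sample_id not in group_labels:
            raise ValueError(f"no group label for sample {sample_id!r}")
        labels = assignments[sample_id].measured_labels()
        sub = table[table["segment_id"].isin(labels)].copy()
        sub["cluster"] = sub["segment_id"].map(labels)
        sub["sample_id"] = sample_id
        sub["group"] = group_labels[sample_id]
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def compare_groups(
    tables: dict[str, pd.DataFrame],
    assignments: dict[str, ClassificationResult],
    group_labels: dict[str, str],
    features=("lumen", "wall", "layers"),
    bh_correct: bool = False,
) -> list[ComparisonResult]:
    """Global and cluster-stratified two-group comparison of every feature.

    ``tables`` maps sample_id to its MeasurementTable, ``assignments`` to a
    segment-level classification (only measured, non-artificial segments
    contribute), and ``group_labels`` to one of exactly two group names.
    For each feature one global row (all segments pooled by group) and one
    row per cluster are produced.  A stratum empty in either group yields a
    row with missing statistics rather than being dropped.  Rows with a
    missing feature value are excluded per feature.  The effect strength is
    attached only to significant rows (p < 0.05), with N the stratum's
    n_A + n_B.

    ``bh_correct=True`` applies a Benjamini-Hochberg adjustment across all
    rows with a computed p-value (off by default).
    """
    groups = sorted(set(group_labels.values()))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g_a, g_b = groups
    long = _long_frame(tables, assignments, group_labels)
    clusters = sorted(long["cluster"].unique())

    results: list[ComparisonResult] = []
    for feature in features:
        col = FEATURE_COLUMNS[feature]
        feat = long.dropna(subset=[col])
        for stratum in ["global", *[str(c) for c in clusters]]:
            if stratum == "global":
                sub = feat
            else:
                sub = feat[feat["cluster"].astype(str) == stratum]
            xa = sub.loc[sub["group"] == g_a, col].to_numpy()
            xb = sub.loc[sub["group"] == g_b, col].to_numpy()
            if xa.size == 0 or xb.size == 0:
                results.append(
                    ComparisonResult(feature, stratum, int(xa.size), int(xb.size),
                                     None, None, "", None, None)
                )
                continue
            U, p = mann_whitney(xa, xb)
            results.append(
                ComparisonResult(feature, stratum, int(xa.size), int(xb.size),
                                 U, p, stars(p), None, None)
            )

    if bh_correct:
        tested = [r for r in results if r.p is not None]
        m = len(tested)
        order = np.argsort([r.p for r in tested])
        adj = np.empty(m)
        prev = 1.0
        for rank_from_top in range(m - 1, -1, -1):
            i = order[rank_from_top]
            prev = min(prev, tested[i].p * m / (rank_from_top + 1))
            adj[i] = prev
        for r, q in zip(tested, adj):
            r.p = float(q)
            r.significant = stars(r.p)

    for r in results:
        if r.p is not None and r.p < 0.05:
            r.effect_r = effect_strength(r.p, r.n_a + r.n_b)
            r.effect_category = categorize_effect(r.effect_r)
    return results


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Results as a flat CSV-ready table."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "stratum": r.stratum,
                "n_A": r.n_a,
                "n_B": r.n_b,
                "U": r.U,
                "p": r.p,
                "stars": r.significant,
                "effect_r": r.effect_r,
                "category": r.effect_category,
            }
            for r in results
        ]
    )
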