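"""Descriptive subtype profiling: each subtype versus all other patients.

Binary features are compared with Pearson's chi-squared test (no
continuity correction) on the 2x2 subtype-vs-rest table; continuous
summaries use one-way ANOVA or the Wilcoxon rank-sum test.  All p-values
from a profiling run are adjusted together with the Benjamini-Hochberg
step-up procedure, and a feature is called significant at FDR q < 0.001.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

FDR_THRESHOLD = 0.001


def two_by_two_chi_squared(a: int, b: int, c: int, d: int) -> tuple:
    """Pearson chi-squared (1 df, no continuity correction) for the table
    [[a, b], [c, d]].  A zero margin makes the statistic undefined and
    returns (nan, nan)."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def anova_f(groups: list) -> tuple:
    """Classical one-way ANOVA F and p across >= 2 groups of values.
    Constant data (zero within- and between-group variance) is undefined."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return float("nan"), float("nan")
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> tuple:
    """Rank-sum (Mann-Whitney) statistic with normal approximation and
    tie correction; returns (rank sum of x, two-sided p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    # report the classical rank-sum W of the first sample
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[: len(x)].sum())
    return w, float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up FDR-adjusted q-values, monotone in sorted order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def profile_subtypes(
    matrix,
    assignment,
    fdr_threshold: float = FDR_THRESHOLD,
) -> dict:
    """Per-subtype feature profiles against all remaining patients.

    Parameters
    ----------
    matrix : FeatureMatrix (binary).
    assignment : ClusterAssignment over the same patients.

    Returns a dict: subtype label -> DataFrame with per-feature in/out
    proportions, chi-squared statistic, p, BH q (adjusted across *all*
    tests in the run), and the q < threshold significance flag.  Constant
    features are excluded from testing.
    """
    values = matrix.values
    labels = np.asarray(assignment.labels)
    if len(labels) != values.shape[0]:
        raise ValueError("assignment does not cover the matrix rows")
    col_sums = values.sum(axis=0)
    testable = [
        j for j in range(values.shape[1]) if 0 < col_sums[j] < values.shape[0]
    ]
    records = []  # (subtype, feature idx, a, b, c, d)
    for lab in sorted(set(labels.tolist())):
        inside = labels == lab
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        in_sums = values[inside].sum(axis=0)
        for j in testable:
            a = int(in_sums[j])
            b = n_in - a
            c = int(col_sums[j] - in_sums[j])
            d = n_out - c
            stat, p = two_by_two_chi_squared(a, b, c, d)
            records.append((lab, j, a / n_in, c / n_out if n_out else np.nan, stat, p))
    df = pd.DataFrame(
        records,
        columns=["subtype", "feature_idx", "prop_in", "prop_out", "chi2", "p"],
    )
    ok = df["p"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()] = benjamini_hochberg(df.loc[ok, "p"].to_numpy())
    df["q"] = q
    df["significant"] = df["q"] < fdr_threshold
    df["feature"] = [matrix.feature_names[j] for j in df["feature_idx"]]
    out = {}
    for lab, sub in df.groupby("subtype"):
        out[int(lab)] = (
            sub[["feature", "prop_in", "prop_out", "chi2", "p", "q", "significant"]]
            .sort_values(["q", "feature"])
            .reset_index(drop=True)
        )
    return out


def enriched_feature_sets(profiles: dict, fdr_threshold: float = FDR_THRESHOLD) -> dict:
    """Subtype -> frozenset of significantly *enriched* features
    (q below threshold and in-subtype proportion above the rest)."""
    out = {}
    for lab, df in profiles.items():
        sig = df[(df["q"] < fdr_threshold) & (df["prop_in"] > df["prop_out"])]
        out[lab] = frozenset(sig["feature"])
    return out
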