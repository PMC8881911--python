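"""Rarefaction and richness comparisons across protocol groups.

Presence/absence performance is compared by rarefying every sample to a
common read depth (removing the confound of unequal sequencing effort),
counting detected taxa, and testing group differences with a one-way
ANOVA followed by Tukey's Honest Significant Difference test.
"""

from __future__ import annotations

import itertools
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rarefy", "richness_table", "anova_oneway", "tukey_hsd", "AnovaResult"]


def rarefy(counts: pd.DataFrame, depth: int = 100_000, seed=None) -> pd.DataFrame:
    """Subsample each sample's reads without replacement to ``depth``.

    Each sample (column) is reduced to exactly ``depth`` reads by a
    multivariate hypergeometric draw.  Samples with fewer reads than
    ``depth`` are dropped with a warning; samples with exactly ``depth``
    reads are kept unchanged.  The same ``seed`` yields identical output.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = np.random.default_rng(seed)
    out = {}
    dropped = []
    for s in counts.columns:
        col = counts[s].to_numpy()
        if np.any(col < 0) or not np.allclose(col, np.round(col)):
            raise ValueError(f"sample {s!r}: counts must be non-negative integers")
        col = np.round(col).astype(np.int64)
        total = int(col.sum())
        if total < depth:
            dropped.append(s)
            continue
        if total == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    if dropped:
        warnings.warn(
            f"samples below rarefaction depth {depth}, dropped: {dropped}",
            stacklevel=2,
        )
    return pd.DataFrame(out, index=counts.index)


def richness_table(counts: pd.DataFrame, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Observed taxon count per sample, optionally joined to metadata."""
    rich = (counts > 0).sum(axis=0).rename("richness").to_frame()
    rich.index.name = "sample"
    if meta is not None:
        rich = rich.join(meta, how="left")
    return rich


class AnovaResult(NamedTuple):
    f: float
    df1: int
    df2: int
    p: float


def _split_groups(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    split = {g: values[groups == g] for g in pd.unique(groups)}
    for g, v in split.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} has no observations")
    return split


def anova_oneway(values, groups) -> AnovaResult:
    """One-way analysis of variance: F = MS(between) / MS(within).

    Degenerate case: when all observations are identical both sums of
    squares vanish and F is reported as 0 (p = 1) with a warning.
    """
    split = _split_groups(values, groups)
    if len(split) < 2:
        raise ValueError("need at least 2 groups")
    n = sum(v.size for v in split.values())
    k = len(split)
    if n - k < 1:
        raise ValueError("need at least one residual degree of freedom")
    grand = np.concatenate(list(split.values())).mean()
    ssb = sum(v.size * (v.mean() - grand) ** 2 for v in split.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in split.values())
    df1, df2 = k - 1, n - k
    if ssw == 0 and ssb == 0:
        warnings.warn("all observations identical; F reported as 0", stacklevel=2)
        return AnovaResult(0.0, df1, df2, 1.0)
    if ssw == 0:
        return AnovaResult(float("inf"), df1, df2, 0.0)
    f = (ssb / df1) / (ssw / df2)
    return AnovaResult(float(f), df1, df2, float(stats.f.sf(f, df1, df2)))


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons after a one-way ANOVA.

    For every pair of groups the mean difference is tested against the
    studentized-range distribution with k groups and the within-group
    degrees of freedom (Tukey-Kramer for unequal group sizes).  Returns a
    table with one row per pair: mean difference, adjusted p-value,
    simultaneous confidence bounds and a significance flag at ``alpha``.
    """
    split = _split_groups(values, groups)
    k = len(split)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = sum(v.size for v in split.values())
    df_w = n - k
    if df_w < 1:
        raise ValueError("need at least one within-group degree of freedom")
    msw = sum(((v - v.mean()) ** 2).sum() for v in split.values()) / df_w
    q_crit = stats.studentized_range.ppf(1 - alpha, k, df_w)
    rows = []
    for a, b in itertools.combinations(split, 2):
        va, vb = split[a], split[b]
        diff = va.mean() - vb.mean()
        se = np.sqrt(msw / 2 * (1 / va.size + 1 / vb.size))
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
            half = 0.0
        else:
            q = abs(diff) / se
            p = float(np.clip(stats.studentized_range.sf(q, k, df_w), 0, 1))
            half = q_crit * se
        rows.append(
            {
                "group1": a,
                "group2": b,
                "diff": diff,
                "p_adj": p,
                "ci_lo": diff - half,
                "ci_hi": diff + half,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
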