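"""Per-taxon detection-efficiency (bias) estimation with bootstrap errors.

A protocol's taxonomic bias is modelled multiplicatively: the observed
composition of a mock sample is, in expectation, the known composition with
each taxon's proportion multiplied by a taxon-specific efficiency, then
re-closed.  Because compositions are scale-free the efficiency vector is
identifiable only up to a constant, so estimates are geometrically centered
— each value is relative to the "average" (geometric-mean) taxon.

The estimator is the per-taxon geometric mean of single-sample
compositional errors across the replicate samples of a group, re-centered.
This is the closed form of a least-squares fit of taxon indicators to the
centered log-ratio errors.  Uncertainty comes from a nonparametric
bootstrap that resamples samples (pool replicates) with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .composition import (
    CompositionError,
    MockDesign,
    ZeroPolicy,
    center,
    close,
    compositional_error,
)

__all__ = [
    "BiasEstimate",
    "select_samples",
    "estimate_bias",
    "bootstrap_bias",
    "predict_composition",
    "observed_expected_pairs",
]

META_COLUMNS = ("pool", "stage", "extraction", "primer", "run")


class GroupError(ValueError):
    """Raised for empty or inconsistent sample groups."""


@dataclass
class BiasEstimate:
    """Centered detection-efficiency estimate for one sample group.

    Attributes
    ----------
    group
        The metadata selector that defined the group, e.g.
        ``{"stage": "insect", "extraction": "dneasy", "primer": ...}``.
    efficiency
        Centered per-taxon point estimate (geometric mean one).
    se_log
        Log-scale bootstrap standard error per taxon (None before
        bootstrapping).
    ci_lower, ci_upper
        95% percentile bootstrap interval (2.5 / 97.5), efficiency scale.
    ci50_lower, ci50_upper
        50% percentile interval (25 / 75), efficiency scale.
    n_samples
        Number of samples in the group.
    n_boot
        Number of bootstrap replicates (0 for a plain point estimate).
    dropouts
        Per-taxon count of samples where the taxon was expected but
        observed with zero reads.
    log_replicates
        ``(n_boot, n_taxa)`` array of centered log-efficiency bootstrap
        replicates (NaN where a taxon was absent from a replicate), kept so
        that downstream steps (partitioning, trait models) can propagate
        uncertainty by pairing replicates.
    """

    group: Mapping[str, object]
    efficiency: pd.Series
    n_samples: int
    dropouts: pd.Series
    se_log: pd.Series | None = None
    ci_lower: pd.Series | None = None
    ci_upper: pd.Series | None = None
    ci50_lower: pd.Series | None = None
    ci50_upper: pd.Series | None = None
    n_boot: int = 0
    log_replicates: np.ndarray | None = field(default=None, repr=False)

    @property
    def taxa(self) -> pd.Index:
        return self.efficiency.index

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: taxon, efficiency, se_log, ci_lo, ci_hi, n_dropout."""
        out = pd.DataFrame({"efficiency": self.efficiency})
        out["se_log"] = self.se_log if self.se_log is not None else np.nan
        out["ci_lo"] = self.ci_lower if self.ci_lower is not None else np.nan
        out["ci_hi"] = self.ci_upper if self.ci_upper is not None else np.nan
        out["n_dropout"] = self.dropouts.reindex(self.taxa).fillna(0).astype(int)
        out.index.name = "taxon"
        return out


def select_samples(meta: pd.DataFrame, group: Mapping[str, object]) -> list:
    """Sample identifiers matching every key=value pair of ``group``.

    Comparison is string-based so that e.g. run ``1`` and ``"1"`` select the
    same samples regardless of how the metadata was parsed.
    """
    mask = pd.Series(True, index=meta.index)
    for key, value in group.items():
        if key not in meta.columns:
            raise GroupError(f"unknown metadata column in group selector: {key!r}")
        mask &= meta[key].astype(str) == str(value)
    return list(meta.index[mask])


def _log_error_matrix(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: MockDesign,
    samples: list,
    zero_policy: ZeroPolicy,
    pseudocount: float,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample centered log compositional errors.

    Returns a ``samples x taxa`` DataFrame with NaN where a taxon was not
    expected in the sample's pool (or was dropped under the exclude
    policy), plus the per-taxon dropout counts.
    """
    E = pd.DataFrame(np.nan, index=pd.Index(samples), columns=design.taxa)
    dropouts = pd.Series(0, index=design.taxa, dtype=int)
    for s in samples:
        pool = meta.loc[s, "pool"]
        expected = design.expected_composition(pool)
        obs = counts[s].reindex(expected.index).fillna(0).astype(float)
        zero = obs.index[obs == 0]
        dropouts[zero] += 1
        err = compositional_error(
            obs, expected, zero_policy=zero_policy, pseudocount=pseudocount
        )
        E.loc[s, err.index] = np.log(err.to_numpy())
    return E, dropouts


def _point_from_matrix(E: np.ndarray, taxa: pd.Index) -> tuple[pd.Series, np.ndarray]:
    """Centered point estimate from a log-error matrix; also returns the
    boolean mask of taxa retained (observed in at least one sample)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        logmean = np.nanmean(E, axis=0)
    kept = np.isfinite(logmean)
    if not kept.any():
        raise GroupError("no taxon observed in any sample of the group")
    centered = logmean[kept] - logmean[kept].mean()
    eff = pd.Series(np.exp(centered), index=taxa[kept])
    return eff, kept


def _prepare_group(counts, meta, design, group, zero_policy, pseudocount):
    samples = select_samples(meta, group)
    if not samples:
        raise GroupError(f"no samples match group selector {dict(group)!r}")
    missing = [s for s in samples if s not in counts.columns]
    if missing:
        raise GroupError(f"samples missing from count table: {missing}")
    E, dropouts = _log_error_matrix(
        counts, meta, design, samples, zero_policy, pseudocount
    )
    return samples, E, dropouts


def estimate_bias(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: MockDesign,
    group: Mapping[str, object],
    zero_policy: ZeroPolicy = "exclude",
    pseudocount: float = 0.5,
) -> BiasEstimate:
    """Point estimate of the centered detection-efficiency vector.

    Parameters
    ----------
    counts
        ``taxa x samples`` read-count table.
    meta
        Per-sample metadata with columns ``pool, stage, extraction, primer,
        run``, indexed by sample identifier.
    design
        Mock-community design supplying each pool's expected composition.
    group
        Metadata selector defining the replicate group, e.g. one
        (stage, extraction protocol, primer) combination.
    zero_policy, pseudocount
        Handling of expected-but-unobserved taxa; see
        :func:`mockbias.composition.compositional_error`.

    Notes
    -----
    Taxa observed in no sample of the group are excluded with a warning
    (their efficiency is not identifiable from the group).
    """
    samples, E, dropouts = _prepare_group(
        counts, meta, design, group, zero_policy, pseudocount
    )
    eff, kept = _point_from_matrix(E.to_numpy(), E.columns)
    excluded = [t for t, k in zip(E.columns, kept) if not k and dropouts[t] > 0]
    if excluded:
        warnings.warn(
            f"taxa observed in no sample of group {dict(group)!r}, excluded: {excluded}",
            stacklevel=2,
        )
    return BiasEstimate(
        group=dict(group),
        efficiency=eff,
        n_samples=len(samples),
        dropouts=dropouts[eff.index],
    )


def bootstrap_bias(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: MockDesign,
    group: Mapping[str, object],
    n_boot: int = 1000,
    seed=None,
    zero_policy: ZeroPolicy = "exclude",
    pseudocount: float = 0.5,
) -> BiasEstimate:
    """Bias estimate with bootstrap standard errors and percentile CIs.

    Samples (pool replicates) are resampled with replacement within the
    group; the estimator is re-run on each of ``n_boot`` replicates.  The
    log-scale standard error is the standard deviation of the centered
    log-efficiency across replicates; intervals are expanded percentile
    intervals at nominal 95% and 50% levels (see :func:`expanded_tail` for
    the small-sample tail adjustment).  The same ``seed`` always yields
    identical output.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    samples, E, dropouts = _prepare_group(
        counts, meta, design, group, zero_policy, pseudocount
    )
    Ev = E.to_numpy()
    eff, kept = _point_from_matrix(Ev, E.columns)
    n = len(samples)
    if n == 1:
        warnings.warn(
            "bootstrap over a single sample: standard errors are zero", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        M = np.nanmean(Ev[idx], axis=1)[:, kept]  # (n_boot, n_kept)
        M = M - np.nanmean(M, axis=1, keepdims=True)
        se = np.nanstd(M, axis=0, ddof=1) if n_boot > 1 else np.zeros(M.shape[1])
        a95 = expanded_tail(n, 0.025)
        a50 = expanded_tail(n, 0.25)
        q = np.nanquantile(M, [a95, 1 - a95, a50, 1 - a50], axis=0)
    taxa = eff.index
    return BiasEstimate(
        group=dict(group),
        efficiency=eff,
        n_samples=n,
        dropouts=dropouts[taxa],
        se_log=pd.Series(se, index=taxa),
        ci_lower=pd.Series(np.exp(q[0]), index=taxa),
        ci_upper=pd.Series(np.exp(q[1]), index=taxa),
        ci50_lower=pd.Series(np.exp(q[2]), index=taxa),
        ci50_upper=pd.Series(np.exp(q[3]), index=taxa),
        n_boot=n_boot,
        log_replicates=M,
    )


def expanded_tail(n: int, tail: float) -> float:
    """Small-sample adjusted tail probability for percentile intervals.

    Plain percentile bootstrap intervals are systematically narrow when
    the number of resampled units is small (here: 8-16 samples per
    group).  The expanded percentile interval widens the quantile levels
    by the t/normal ratio, ``tail' = Phi(t_{tail,n-1} * sqrt(n/(n-1)))``,
    restoring close-to-nominal coverage while keeping the percentile
    form.
    """
    if n < 2:
        return tail
    z = stats.t.ppf(tail, n - 1) * np.sqrt(n / (n - 1))
    return float(stats.norm.cdf(z))


def predict_composition(expected: pd.Series, bias: pd.Series) -> pd.Series:
    """Predicted observed composition: ``close(expected * bias)``.

    Applying the estimated efficiencies to a known composition predicts
    what sequencing should report; comparing the prediction with the actual
    reads evaluates the fit of the multiplicative bias model.
    """
    if set(expected.index) != set(bias.index):
        raise CompositionError("predict_composition: taxon sets differ")
    return close(expected * bias.reindex(expected.index))


def observed_expected_pairs(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    design: MockDesign,
    group: Mapping[str, object],
    bias: pd.Series | None = None,
) -> tuple[list[pd.Series], list[pd.Series]]:
    """Paired (observed, expected) compositions for the samples of a group.

    Observed compositions are closed read counts over each sample's
    expected taxa (zeros retained — no logs are taken here).  If ``bias``
    is given, the expected compositions are bias-corrected predictions
    instead, restricted to taxa present in the bias vector.  The pairs feed
    :func:`mockbias.composition.rmse`.
    """
    samples = select_samples(meta, group)
    if not samples:
        raise GroupError(f"no samples match group selector {dict(group)!r}")
    observed, expected = [], []
    for s in samples:
        pool = meta.loc[s, "pool"]
        exp = design.expected_composition(pool)
        if bias is not None:
            common = exp.index.intersection(bias.index)
            exp = predict_composition(close(exp[common]), bias[common])
        obs = counts[s].reindex(exp.index).fillna(0).astype(float)
        if obs.sum() == 0:
            warnings.warn(f"sample {s!r} has zero reads over expected taxa; skipped")
            continue
        observed.append(close(obs))
        expected.append(exp)
    return observed, expected
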