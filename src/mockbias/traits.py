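"""Trait regression: which insect traits drive detection bias.

Log detection efficiency is regressed on morphological traits (body
volume, exoskeleton hardness) and molecular traits (primer-template
mismatch, amplicon GC fraction) by ordinary least squares.  Because
efficiencies are multiplicative, coefficients are estimated on the log
scale and reported exponentiated: exp(beta) is the factor by which a
unit change of the trait multiplies detection efficiency.

Two encodings of the categorical hardness trait are available:

* ``"full_dummy"`` (default): indicator columns for all three hardness
  levels and no intercept.  The column space still contains the constant
  (the indicators sum to one), so the customary centered R-squared and
  overall F test against the intercept-only model apply, with numerator
  degrees of freedom one less than the number of columns.
* ``"reference"``: an explicit intercept with soft hardness as the
  reference level.

Also here: small sequence utilities to regenerate the molecular traits —
primer-template mismatch proportion under IUPAC degeneracy, and amplicon
length from barcode coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "TraitTable",
    "TraitModelFit",
    "build_design_matrix",
    "fit_trait_model",
    "bootstrap_trait_cis",
    "mismatch_proportion",
    "amplicon_length",
    "DESIGN_COLUMNS",
    "MORPHOLOGY_COLUMNS",
]

HARDNESS_LABELS = {1: "soft", 2: "intermediate", 3: "hard"}
DESIGN_COLUMNS = ("soft", "intermediate", "hard", "log_volume", "mismatch", "gc")
#: primer-independent columns (used for the extraction step in simulations)
MORPHOLOGY_COLUMNS = ("soft", "intermediate", "hard", "log_volume")

Encoding = Literal["full_dummy", "reference"]


@dataclass(frozen=True)
class TraitTable:
    """Per-taxon, per-primer molecular and morphological covariates.

    ``data`` is indexed by (taxon, primer) and has columns
    ``fwd_mismatch``, ``rev_mismatch``, ``gc`` (all fractions in [0, 1]),
    ``volume_mm3`` (> 0) and ``hardness`` (1 = soft, 2 = intermediate,
    3 = hard).  Volume and hardness are primer-independent and repeated
    per primer row.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"fwd_mismatch", "rev_mismatch", "gc", "volume_mm3", "hardness"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"TraitTable: missing columns {sorted(missing)}")
        if self.data.index.nlevels != 2:
            raise ValueError("TraitTable: index must be (taxon, primer)")
        if self.data.index.has_duplicates:
            raise ValueError("TraitTable: duplicate (taxon, primer) rows")
        d = self.data
        for col in ("fwd_mismatch", "rev_mismatch", "gc"):
            if ((d[col] < 0) | (d[col] > 1)).any():
                raise ValueError(f"TraitTable: {col} outside [0, 1]")
        if (d["volume_mm3"] <= 0).any():
            raise ValueError("TraitTable: volume_mm3 must be positive")
        if not d["hardness"].isin([1, 2, 3]).all():
            raise ValueError("TraitTable: hardness must be in {1, 2, 3}")

    @property
    def taxa(self) -> pd.Index:
        return self.data.index.get_level_values(0).unique()

    @property
    def primers(self) -> pd.Index:
        return self.data.index.get_level_values(1).unique()

    def for_primer(self, primer: str) -> pd.DataFrame:
        if primer not in set(self.primers):
            raise KeyError(f"unknown primer set: {primer!r}")
        return self.data.xs(primer, level=1)


def build_design_matrix(
    traits: TraitTable,
    taxa: Sequence[str],
    primer: str,
    encoding: Encoding = "full_dummy",
    log_volume: bool = True,
) -> pd.DataFrame:
    """Design matrix for the trait regression, row order = ``taxa``.

    Columns (full-dummy encoding): ``soft``, ``intermediate``, ``hard``
    hardness indicators, ``log_volume`` (natural log of body volume in
    mm^3; raw volume if ``log_volume=False``), ``mismatch`` (forward +
    reverse primer mismatch proportions) and ``gc`` (amplicon GC
    fraction).  The reference encoding replaces the three indicators by an
    intercept plus ``intermediate`` and ``hard``.
    """
    table = traits.for_primer(primer)
    missing = [t for t in taxa if t not in table.index]
    if missing:
        raise KeyError(f"taxa missing from trait table for {primer!r}: {missing}")
    sub = table.loc[list(taxa)]
    X = pd.DataFrame(index=pd.Index(taxa, name="taxon"))
    hardness = sub["hardness"].to_numpy()
    if encoding == "full_dummy":
        for level, label in HARDNESS_LABELS.items():
            X[label] = (hardness == level).astype(float)
    elif encoding == "reference":
        X["intercept"] = 1.0
        for level in (2, 3):
            X[HARDNESS_LABELS[level]] = (hardness == level).astype(float)
    else:
        raise ValueError(f"unknown encoding: {encoding!r}")
    vol = sub["volume_mm3"].to_numpy(dtype=float)
    X["log_volume" if log_volume else "volume"] = np.log(vol) if log_volume else vol
    X["mismatch"] = (sub["fwd_mismatch"] + sub["rev_mismatch"]).to_numpy(dtype=float)
    X["gc"] = sub["gc"].to_numpy(dtype=float)
    return X


@dataclass
class TraitModelFit:
    """OLS fit of log detection efficiency on traits.

    ``coefficients`` has one row per term with the log-scale estimate, the
    exponentiated estimate, and (after bootstrapping) percentile interval
    bounds on the exponentiated scale.
    """

    response: str
    coefficients: pd.DataFrame
    r2_adj: float
    f_stat: float
    df_num: int
    df_den: int
    n_obs: int

    def to_frame(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out.insert(0, "response", self.response)
        return out


def _spans_constant(X: np.ndarray) -> bool:
    ones = np.ones(X.shape[0])
    beta, *_ = np.linalg.lstsq(X, ones, rcond=None)
    return bool(np.allclose(X @ beta, ones, atol=1e-8))


def _check_rank(X: pd.DataFrame) -> None:
    vals = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(vals)
    if rank < X.shape[1]:
        # name the offending columns via the QR diagonal
        _, r = np.linalg.qr(vals)
        diag = np.abs(np.diag(r))
        bad = [c for c, d in zip(X.columns, diag) if d < 1e-10 * max(diag.max(), 1.0)]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_trait_model(
    response,
    X: pd.DataFrame,
    response_label: str = "total",
) -> TraitModelFit:
    """Ordinary least squares of log efficiency on the trait design matrix.

    ``response`` may be a :class:`pandas.Series` of log efficiencies (its
    index must equal ``X``'s row index) or a
    :class:`~mockbias.bias.BiasEstimate`, whose centered efficiencies are
    logged.  The overall F statistic is tested against the intercept-only
    model whenever the design's column space contains the constant.
    """
    from .bias import BiasEstimate  # local import to avoid a cycle

    if isinstance(response, BiasEstimate):
        response = np.log(response.efficiency)
    y = pd.Series(response).astype(float)
    if not y.index.equals(X.index):
        raise ValueError("response index must equal design-matrix index")
    _check_rank(X)
    has_const = _spans_constant(X.to_numpy(dtype=float))
    model = sm.OLS(y.to_numpy(), X.to_numpy(dtype=float), hasconst=has_const).fit()
    coeffs = pd.DataFrame(
        {
            "term": list(X.columns),
            "estimate_log": model.params,
            "estimate": np.exp(model.params),
            "ci_lo": np.nan,
            "ci_hi": np.nan,
        }
    ).set_index("term")
    return TraitModelFit(
        response=response_label,
        coefficients=coeffs,
        r2_adj=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        df_num=int(model.df_model),
        df_den=int(model.df_resid),
        n_obs=int(model.nobs),
    )


def bootstrap_trait_cis(
    response,
    X: pd.DataFrame,
    log_replicates: np.ndarray,
    response_label: str = "total",
    ci: tuple[float, float] = (0.025, 0.975),
) -> TraitModelFit:
    """Percentile coefficient intervals from bias bootstrap replicates.

    The trait model is refit to each bootstrap replicate of the log
    efficiency vector and percentile intervals of the exponentiated
    coefficients are taken.  Replicate rows containing NaN (taxa absent
    from a resample) are refit on their finite subset; the procedure is
    deterministic given the replicates, so identical inputs always yield
    identical intervals.

    Parameters
    ----------
    response
        Point-estimate log efficiencies (or a BiasEstimate), as in
        :func:`fit_trait_model`.
    X
        Design matrix aligned with the replicate columns.
    log_replicates
        ``(n_replicates, n_obs)`` array of log-efficiency bootstrap
        replicates; at least two replicates are required.
    """
    fit = fit_trait_model(response, X, response_label=response_label)
    R = np.asarray(log_replicates, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if R.shape[1] != X.shape[0]:
        raise ValueError("replicate columns must match design-matrix rows")
    Xv = X.to_numpy(dtype=float)
    p = Xv.shape[1]
    coefs = np.full((R.shape[0], p), np.nan)
    finite = np.isfinite(R)
    patterns: dict[bytes, list[int]] = {}
    for b in range(R.shape[0]):
        patterns.setdefault(finite[b].tobytes(), []).append(b)
    for key, rows in patterns.items():
        mask = finite[rows[0]]
        if mask.sum() < p:
            continue  # too few observations to identify the model
        pinv = np.linalg.pinv(Xv[mask])
        coefs[rows] = (pinv @ R[np.ix_(rows, np.flatnonzero(mask))].T).T
    lo, hi = np.nanquantile(np.exp(coefs), ci, axis=0)
    fit.coefficients["ci_lo"] = lo
    fit.coefficients["ci_hi"] = hi
    return fit


def _iupac_set(base: str) -> frozenset[str]:
    try:
        return frozenset(ambiguous_dna_values[base.upper()])
    except KeyError:
        raise ValueError(f"non-IUPAC nucleotide code: {base!r}") from None


def mismatch_proportion(primer: str, template: str) -> float:
    """Fraction of primer positions incompatible with the template.

    A position matches when the primer's IUPAC degenerate set contains the
    template base (itself possibly degenerate: compatible when the sets
    intersect).  Rounded to two decimals, matching the granularity of the
    packaged trait table.
    """
    if len(primer) != len(template):
        raise ValueError(
            f"primer ({len(primer)} nt) and template ({len(template)} nt) "
            "must be aligned to equal length"
        )
    if len(primer) == 0:
        raise ValueError("empty primer")
    mismatches = sum(
        1
        for p, t in zip(primer, template)
        if not (_iupac_set(p) & _iupac_set(t))
    )
    return round(mismatches / len(primer), 2)


def amplicon_length(start: int, end: int) -> int:
    """Amplicon length (bp, excluding primers) from barcode coordinates.

    Computed as ``end - start``, the coordinate convention under which the
    two packaged primer pairs span 205 bp (346-551) and 214 bp (346-560).
    """
    if end < start:
        raise ValueError("end coordinate must be >= start coordinate")
    return int(end) - int(start)
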