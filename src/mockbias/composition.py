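"""Compositional primitives for mock-community bias analysis.

Metabarcoding read counts are compositional: the total number of reads a
sample receives is an arbitrary consequence of library pooling and sequencer
loading, so only the *relative* abundances of taxa within a sample carry
information.  All quantities in this package therefore live either on the
simplex (compositions, entries summing to one) or in the multiplicative
group of positive vectors considered up to a scalar (detection-efficiency
vectors, reported relative to the geometric-mean taxon).

This module provides the small set of primitives everything else is built
from:

* :func:`close` — project a non-negative vector onto the simplex,
* :func:`center` — divide a positive vector by its geometric mean so that
  the "average" taxon has efficiency one,
* :func:`compositional_error` — the centered observed/expected ratio for a
  single sample,
* :func:`expected_composition` — the known composition of a mock pool from
  its design table of individual counts,
* :func:`rmse` — root-mean-square error between observed and expected
  relative abundances, in percentage points.

Vectors are represented as :class:`pandas.Series` indexed by taxon name;
the mock-community design is the :class:`MockDesign` container.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompositionError",
    "MockDesign",
    "close",
    "center",
    "geometric_mean",
    "is_centered",
    "compositional_error",
    "expected_composition",
    "rmse",
]

#: absolute tolerance for the simplex / centering invariants
TOL = 1e-9

ZeroPolicy = Literal["exclude", "pseudocount"]


class CompositionError(ValueError):
    """Raised when a vector violates a compositional precondition."""


def _as_series(v, what: str) -> pd.Series:
    if isinstance(v, pd.Series):
        s = v.astype(float)
    else:
        s = pd.Series(np.asarray(v, dtype=float))
    if s.size == 0:
        raise CompositionError(f"{what}: empty vector")
    if not np.all(np.isfinite(s.to_numpy())):
        raise CompositionError(f"{what}: non-finite entries")
    return s


def close(v) -> pd.Series:
    """Normalise a non-negative vector to proportions summing to one.

    Parameters
    ----------
    v
        Sequence or :class:`pandas.Series` of non-negative values (read
        counts, individual counts, concentrations ...).

    Returns
    -------
    pandas.Series
        ``v / sum(v)``, preserving order and index.

    Raises
    ------
    CompositionError
        If the vector is empty, contains a negative entry, or sums to zero.
    """
    s = _as_series(v, "close")
    vals = s.to_numpy()
    if np.any(vals < 0):
        raise CompositionError("close: negative entries are not allowed")
    total = vals.sum()
    if not total > 0:
        raise CompositionError("close: vector sum must be positive")
    return s / total


def geometric_mean(v) -> float:
    """Geometric mean of a strictly positive vector."""
    s = _as_series(v, "geometric_mean")
    vals = s.to_numpy()
    if np.any(vals <= 0):
        raise CompositionError("geometric_mean: entries must be strictly positive")
    return float(np.exp(np.mean(np.log(vals))))


def center(e) -> pd.Series:
    """Divide a positive vector by its geometric mean.

    The result has geometric mean one, i.e. each entry is the efficiency of
    that taxon relative to the "average" taxon.  Centering is idempotent and
    removes the arbitrary scale of ratio-based quantities.

    Raises
    ------
    CompositionError
        If any entry is zero or negative; callers must apply a zero policy
        (exclude the cell or add a pseudocount) before centering.
    """
    s = _as_series(e, "center")
    vals = s.to_numpy()
    if np.any(vals <= 0):
        raise CompositionError("center: entries must be strictly positive")
    return s / np.exp(np.mean(np.log(vals)))


def is_centered(e, tol: float = TOL) -> bool:
    """True if the log-entries of ``e`` sum to zero within ``tol``."""
    s = _as_series(e, "is_centered")
    vals = s.to_numpy()
    if np.any(vals <= 0):
        return False
    return bool(abs(np.log(vals).mean()) <= tol)


def compositional_error(
    observed,
    expected,
    zero_policy: ZeroPolicy = "exclude",
    pseudocount: float = 0.5,
) -> pd.Series:
    """Centered per-taxon ratio of observed to expected relative abundance.

    This is the single-sample "compositional error": the multiplicative
    factor by which each taxon is over- or under-represented relative to the
    geometric-mean taxon of the sample.

    Parameters
    ----------
    observed, expected
        :class:`pandas.Series` over the same taxon set.  Neither needs to be
        closed beforehand; both are (re-)closed over the taxa actually used.
        ``expected`` must be strictly positive.
    zero_policy
        How to treat taxa expected but observed with zero reads.
        ``"exclude"`` (default) drops those cells from the vector — the
        caller can detect the dropout from the shorter index.
        ``"pseudocount"`` adds ``pseudocount`` to every observed entry
        before closure, retaining all taxa.
    pseudocount
        Pseudo-reads added under the ``"pseudocount"`` policy (default 0.5).

    Returns
    -------
    pandas.Series
        Centered efficiency vector over the retained taxa.
    """
    obs = _as_series(observed, "compositional_error")
    exp = _as_series(expected, "compositional_error")
    if set(obs.index) != set(exp.index):
        raise CompositionError("compositional_error: taxon sets differ")
    exp = exp.reindex(obs.index)
    if np.any(exp.to_numpy() <= 0):
        raise CompositionError("compositional_error: expected entries must be > 0")
    if zero_policy == "pseudocount":
        obs = obs + float(pseudocount)
    elif zero_policy == "exclude":
        keep = obs > 0
        if not keep.any():
            raise CompositionError("compositional_error: all observed entries are zero")
        obs = obs[keep]
        exp = exp[keep]
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown zero_policy: {zero_policy!r}")
    ratio = close(obs) / close(exp)
    return center(ratio)


@dataclass(frozen=True)
class MockDesign:
    """Individuals per taxon per mock pool.

    Parameters
    ----------
    counts
        ``taxa x pools`` DataFrame of non-negative integer individual
        counts; the index holds taxon names, columns hold pool identifiers.
    orders
        Optional taxonomic order label per taxon, aligned with ``counts``.
    """

    counts: pd.DataFrame
    orders: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise CompositionError("MockDesign: empty design table")
        if self.counts.index.has_duplicates:
            raise CompositionError("MockDesign: duplicate taxon names")
        if self.counts.columns.has_duplicates:
            raise CompositionError("MockDesign: duplicate pool identifiers")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise CompositionError("MockDesign: negative individual counts")
        if not np.allclose(vals, np.round(vals)):
            raise CompositionError("MockDesign: individual counts must be integers")
        if self.orders is not None and not self.orders.index.equals(self.counts.index):
            raise CompositionError("MockDesign: orders index must match counts index")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def pools(self) -> list:
        return list(self.counts.columns)

    def pool_totals(self) -> pd.Series:
        """Total number of individuals per pool."""
        return self.counts.sum(axis=0)

    def taxa_in_pool(self, pool) -> pd.Index:
        """Taxa with a nonzero individual count in ``pool``."""
        col = self._pool_column(pool)
        return col.index[col > 0]

    def _pool_column(self, pool) -> pd.Series:
        if pool not in self.counts.columns:
            raise KeyError(f"unknown pool: {pool!r}")
        return self.counts[pool]

    def expected_composition(self, pool) -> pd.Series:
        """Known composition of ``pool``: closed individual counts over the
        taxa actually present in that pool."""
        col = self._pool_column(pool)
        col = col[col > 0]
        return close(col.astype(float))


def expected_composition(design: MockDesign, pool) -> pd.Series:
    """Functional alias for :meth:`MockDesign.expected_composition`."""
    return design.expected_composition(pool)


def rmse(
    observed,
    expected,
    mode: Literal["pooled", "per_sample"] = "pooled",
) -> float:
    """Root-mean-square error between observed and expected compositions.

    Accepts a single pair of composition vectors or two paired lists of
    them.  Each pair is aligned on its taxon index (the sets must match).
    The result is expressed in percentage points: an RMSE of 10.0 means the
    observed relative abundances deviate from the expected ones by 10
    percentage points root-mean-square.

    ``mode="pooled"`` (default) takes one RMS over all sample-taxon cells;
    ``mode="per_sample"`` averages the per-sample RMS values.
    """
    if isinstance(observed, pd.Series):
        observed = [observed]
    if isinstance(expected, pd.Series):
        expected = [expected]
    observed = list(observed)
    expected = list(expected)
    if len(observed) == 0 or len(observed) != len(expected):
        raise CompositionError("rmse: need equal-length, non-empty paired lists")
    per_sample = []
    cells: list[np.ndarray] = []
    for obs, exp in zip(observed, expected):
        obs = _as_series(obs, "rmse")
        exp = _as_series(exp, "rmse")
        if set(obs.index) != set(exp.index):
            raise CompositionError("rmse: taxon sets differ within a pair")
        diff = obs.to_numpy() - exp.reindex(obs.index).to_numpy()
        cells.append(diff**2)
        per_sample.append(math.sqrt(float(np.mean(diff**2))))
    if mode == "pooled":
        return float(np.sqrt(np.mean(np.concatenate(cells))) * 100.0)
    if mode == "per_sample":
        return float(np.mean(per_sample) * 100.0)
    raise ValueError(f"unknown rmse mode: {mode!r}")
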