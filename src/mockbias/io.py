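"""TSV readers and writers for the pipeline's tabular interchange formats.

All tables are tab-separated UTF-8 with a header row and '.' as the
decimal mark:

* design table — ``taxon`` (+ optional ``order``) and ``pool_<id>``
  columns of integer individual counts;
* trait table — ``taxon, primer, fwd_mismatch, rev_mismatch, gc,
  volume_mm3, hardness``;
* count table — ``taxon`` column followed by one integer column per
  sample;
* sample metadata — ``sample, pool, stage, extraction, primer, run``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .composition import MockDesign
from .traits import TraitTable

__all__ = [
    "ParseError",
    "read_design",
    "write_design",
    "read_traits",
    "write_traits",
    "read_count_table",
    "write_count_table",
    "read_meta",
    "write_meta",
]

STAGES = ("insect", "dna", "pcr")
EXTRACTIONS = ("quickextract", "dneasy", "none")

#: float format used by every writer, so that reruns are byte-identical
FLOAT_FORMAT = "%.12g"


class ParseError(ValueError):
    """Raised when an input file does not conform to its documented dialect."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    return df


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")


def _to_int(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    for c in columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {c!r}: {exc}") from None
        vals = df[c].to_numpy(dtype=float)
        if np.any(vals < 0):
            bad = df.index[vals < 0][0]
            raise ParseError(f"{path}: negative count at row {bad!r}, column {c!r}")
        if not np.allclose(vals, np.round(vals)):
            raise ParseError(f"{path}: non-integer count in column {c!r}")
        df[c] = df[c].astype(np.int64)
    return df


def read_design(path) -> MockDesign:
    """Read a mock-community design table (taxa x pools)."""
    df = _read_tsv(path)
    _require(df, ["taxon"], path)
    pool_cols = [c for c in df.columns if c.startswith("pool_")]
    if not pool_cols:
        raise ParseError(f"{path}: no pool_<id> columns found")
    if df["taxon"].duplicated().any():
        dup = df["taxon"][df["taxon"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate taxon {dup!r}")
    df = df.set_index("taxon")
    df = _to_int(df, pool_cols, path)
    counts = df[pool_cols]
    counts.columns = [int(c.removeprefix("pool_")) for c in pool_cols]
    orders = df["order"] if "order" in df.columns else None
    return MockDesign(counts=counts, orders=orders)


def write_design(design: MockDesign, path) -> None:
    out = design.counts.copy()
    out.columns = [f"pool_{c}" for c in out.columns]
    if design.orders is not None:
        out.insert(0, "order", design.orders)
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_traits(path) -> TraitTable:
    """Read a per-taxon, per-primer trait table."""
    df = _read_tsv(path)
    cols = ["taxon", "primer", "fwd_mismatch", "rev_mismatch", "gc", "volume_mm3", "hardness"]
    _require(df, cols, path)
    for c in ("fwd_mismatch", "rev_mismatch", "gc", "volume_mm3"):
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric value in column {c!r}: {exc}") from None
    df = _to_int(df, ["hardness"], path)
    df = df.set_index(["taxon", "primer"])
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate (taxon, primer) rows")
    try:
        return TraitTable(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_traits(traits: TraitTable, path) -> None:
    traits.data.reset_index().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_count_table(path) -> pd.DataFrame:
    """Read a taxa x samples read-count table."""
    df = _read_tsv(path)
    _require(df, ["taxon"], path)
    if df["taxon"].duplicated().any():
        dup = df["taxon"][df["taxon"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate taxon {dup!r}")
    df = df.set_index("taxon")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample identifiers")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns")
    return _to_int(df, list(df.columns), path)


def write_count_table(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")


def read_meta(path) -> pd.DataFrame:
    """Read per-sample metadata keyed by sample identifier."""
    df = _read_tsv(path)
    cols = ["sample", "pool", "stage", "extraction", "primer", "run"]
    _require(df, cols, path)
    if df["sample"].duplicated().any():
        dup = df["sample"][df["sample"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample {dup!r}")
    df = df.set_index("sample")
    df = _to_int(df, ["pool", "run"], path)
    for col, allowed in (("stage", STAGES), ("extraction", EXTRACTIONS)):
        bad = df.index[~df[col].isin(allowed)]
        if len(bad):
            raise ParseError(
                f"{path}: unknown {col} {df.loc[bad[0], col]!r} at sample {bad[0]!r} "
                f"(allowed: {list(allowed)})"
            )
    return df[["pool", "stage", "extraction", "primer", "run"]]


def write_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")
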