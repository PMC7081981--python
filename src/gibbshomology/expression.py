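"""Expression tables and per-sample rescaling to concentrations in [0, 1].

Transcript abundance is used as a surrogate for protein concentration.
Each sample is min-max rescaled independently across its genes, so a
single patient's energy landscape is computable without the rest of the
cohort.  A per-gene (across-cohort) mode is available for sensitivity
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ExpressionFormatError(ValueError):
    """Raised when an expression TSV cannot be parsed or is invalid."""


@dataclass
class ExpressionTable:
    """Genes x samples matrix of non-negative expression values.

    ``values`` is a DataFrame indexed by uppercased gene symbol with one
    column per sample ID; duplicates have already been collapsed.
    """

    values: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ExpressionProfile:
    """One sample's rescaled concentrations c_i in [0, 1], keyed by symbol."""

    sample_id: str
    conc: dict[str, float]


def read_expression(path: str | Path, collapse: str = "mean") -> ExpressionTable:
    """Read a TSV expression matrix (symbols in first column, sample header).

    Duplicate symbols are collapsed by ``collapse`` ("mean", the default, or
    "max"); the number collapsed is logged.  Non-numeric cells and negative
    values are rejected with the offending row and column named.
    """
    path = Path(path)
    # keep_default_na=False: "NA" cells must be reported, not silently NaN'd
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", dtype=str, keep_default_na=False
    )
    if df.empty:
        raise ExpressionFormatError(f"{path}: empty expression table")
    df.index = df.index.astype(str).str.strip().str.upper()

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise ExpressionFormatError(
            f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}: "
            f"{df.loc[gene, col]!r}"
        )
    if numeric.isna().any().any():
        gene = numeric.isna().any(axis=1).idxmax()
        raise ExpressionFormatError(f"{path}: missing value at gene {gene!r}")
    if (numeric < 0).any().any():
        gene = (numeric < 0).any(axis=1).idxmax()
        col = numeric.loc[gene][numeric.loc[gene] < 0].index[0]
        raise ExpressionFormatError(
            f"{path}: negative value at gene {gene!r}, sample {col!r}"
        )

    if numeric.index.has_duplicates:
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene row(s) by %s", n_dup, collapse)
        grouped = numeric.groupby(level=0, sort=False)
        numeric = grouped.mean() if collapse == "mean" else grouped.max()
    return ExpressionTable(values=numeric.astype(float))


def from_frame(df: pd.DataFrame) -> ExpressionTable:
    """Wrap an in-memory genes x samples DataFrame (symbols uppercased)."""
    out = df.copy()
    out.index = out.index.astype(str).str.upper()
    if out.index.has_duplicates:
        out = out.groupby(level=0, sort=False).mean()
    return ExpressionTable(values=out.astype(float))


def rescale_sample(
    table: ExpressionTable,
    sample_id: str,
    restrict_to: Iterable[str] | None = None,
    mode: str = "per_sample",
) -> ExpressionProfile:
    """Min-max rescale one sample's values to [0, 1].

    With ``restrict_to`` (normally the network node set) only genes in the
    intersection are retained before rescaling, so the transform is taken
    over the genes that will actually sit on the network.  A constant
    sample maps to all 0.5 — documented degenerate convention avoiding
    division by zero.

    ``mode="per_gene"`` instead rescales each gene across the cohort and
    then reads off this sample's column (sensitivity-analysis switch).
    """
    if sample_id not in table.values.columns:
        raise KeyError(f"unknown sample: {sample_id!r}")
    values = table.values
    if restrict_to is not None:
        keep = [g for g in values.index if g in set(restrict_to)]
        n_dropped = len(values.index) - len(keep)
        if not keep:
            raise ValueError("empty intersection between table genes and restrict_to")
        if n_dropped:
            logger.info("dropped %d gene(s) absent from restriction set", n_dropped)
        values = values.loc[keep]

    if mode == "per_sample":
        col = values[sample_id].to_numpy(dtype=float)
        conc = _minmax(col)
    elif mode == "per_gene":
        lo = values.min(axis=1).to_numpy(dtype=float)
        hi = values.max(axis=1).to_numpy(dtype=float)
        col = values[sample_id].to_numpy(dtype=float)
        span = hi - lo
        conc = np.where(span > 0, (col - lo) / np.where(span > 0, span, 1.0), 0.5)
    else:
        raise ValueError(f"unknown rescale mode: {mode!r}")
    return ExpressionProfile(
        sample_id=sample_id, conc=dict(zip(values.index, conc.tolist()))
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.full_like(x, 0.5, dtype=float)
    return (x - lo) / (hi - lo)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.values.to_csv(path, sep="\t", index_label="gene")
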