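"""Readers and writers for the plain-text formats the pipeline touches.

Expression matrices travel as TSV (gene rows, sample columns), gene sets as
GMT (Broad dialect), clinical annotations as TSV keyed by sample ID.  All
output tables are CSV with a header row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table.

    ``data`` holds the values with gene IDs as the row index and sample IDs
    as columns.  ``normalized`` records whether log10 + per-gene z-scoring
    has been applied; ``constant_genes`` flags rows that had zero variance
    at normalization time (they are set to all-zeros rather than NaN).
    """

    data: pd.DataFrame
    normalized: bool = False
    constant_genes: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(genes)], self.normalized,
                                [g for g in self.constant_genes if g in set(genes)])


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {kind} ID {i!r}")
        seen.add(i)


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample IDs, first column = gene IDs).

    Rejects duplicate gene/sample IDs, non-numeric cells, missing values and
    an empty body.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no genes (empty body)")
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    try:
        numeric = df.astype(float)
    except ValueError:
        # locate the offending cell for the error message
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric value {cell!r} at gene {gene!r}, "
                        f"sample {sample!r}") from None
        raise
    if numeric.isna().any().any():
        gene = numeric.index[numeric.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in gene {gene!r}")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV at full precision so read/write round-trips."""
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into an ordered mapping set-name -> unique members.

    Duplicate members within a line are dropped with a warning; a repeated
    set name or a line with fewer than three fields is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            unique = list(dict.fromkeys(m for m in members if m))
            if len(unique) < len([m for m in members if m]):
                logger.warning("gene set %s: duplicate members deduplicated", name)
            sets[name] = unique
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical annotation TSV (first column = sample ID, categorical columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index, "sample")
    return df


def read_ranked_cv(path) -> pd.Series:
    """Read a cv.csv (gene, cv) output back into a gene-indexed series."""
    df = pd.read_csv(path, index_col=0)
    return df.iloc[:, 0].astype(float)
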