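"""Expression preprocessing: low-expression filtering, log10 + z-score
normalization, random gene partitioning, and seed-based correlation screening.

The search operates on a normalized matrix in which every retained gene has
all raw values at or above a detection floor (default 1), so the log10 step
is always defined.  Gene screening keeps, within each random gene block,
the genes whose absolute correlation to a large fraction of the block is
high when evaluated over that block's seed samples — concentrating the
matrix on genes that participate in some massive correlating module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    removed: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.removed, "rule": "min_expression"})


def filter_low_expression(raw: ExpressionMatrix, min_expression: float = 1.0
                          ) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop every gene with any sample value below ``min_expression``.

    Returns the filtered matrix plus a report of what was removed.  Raises
    if nothing survives.
    """
    if raw.normalized:
        raise ValueError("filter_low_expression expects a raw (un-normalized) matrix")
    keep = (raw.data >= min_expression).all(axis=1)
    if not keep.any():
        raise ValueError("empty matrix after filter")
    removed = list(raw.data.index[~keep])
    report = FilterReport(n_input=raw.shape[0], n_kept=int(keep.sum()), removed=removed)
    logger.info("filter_low_expression: kept %d of %d genes", report.n_kept, report.n_input)
    return ExpressionMatrix(raw.data.loc[keep]), report


def normalize(filtered: ExpressionMatrix) -> ExpressionMatrix:
    """log10-transform then z-score each gene across samples (sample sd, n-1).

    A gene whose log values are constant cannot be standardized; it is set
    to all-zeros and flagged in ``constant_genes`` instead of producing NaN.
    Normalizing twice is refused.
    """
    if filtered.normalized:
        raise ValueError("matrix is already normalized; refusing to normalize twice")
    values = filtered.data.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("normalize requires strictly positive values (run the filter first)")
    logged = np.log10(values)
    means = logged.mean(axis=1, keepdims=True)
    sds = logged.std(axis=1, ddof=1, keepdims=True)
    constant = (sds[:, 0] == 0) | ~np.isfinite(sds[:, 0])
    sds[constant, 0] = 1.0
    z = (logged - means) / sds
    z[constant, :] = 0.0
    flagged = [g for g, c in zip(filtered.data.index, constant) if c]
    if flagged:
        logger.warning("normalize: %d constant gene(s) set to zero: %s",
                       len(flagged), flagged[:5])
    out = pd.DataFrame(z, index=filtered.data.index, columns=filtered.data.columns)
    return ExpressionMatrix(out, normalized=True, constant_genes=flagged)


def partition_genes(X: ExpressionMatrix, max_block: int = 1000,
                    rng: np.random.Generator | None = None) -> list[ExpressionMatrix]:
    """Randomly permute genes and split into ceil(n/max_block) balanced blocks.

    Block sizes differ by at most one, so no block exceeds ``max_block`` and
    no tiny remainder block is created.  The blocks form a true partition of
    the input gene set.
    """
    if max_block < 1:
        raise ValueError("max_block must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    n = X.shape[0]
    order = rng.permutation(n)
    n_blocks = -(-n // max_block)  # ceil
    splits = np.array_split(order, n_blocks)
    return [ExpressionMatrix(X.data.iloc[idx], X.normalized) for idx in splits]


def screen_correlated_genes(blocks, block_seeds, rho: float = 0.9,
                            q: float = 0.6) -> list[str]:
    """Union over blocks of genes strongly correlated with much of their block.

    Within block ``b`` restricted to its seed's sample subset, gene ``g`` is
    retained iff the fraction of *other* genes ``k`` with ``|C(g,k)| >= rho``
    is at least ``q``.  A gene with no partners (singleton block) has
    fraction 0 by convention and is retained only when ``q <= 0``.
    """
    from .search import correlation_matrix

    if len(blocks) != len(block_seeds):
        raise ValueError("one seed per block required")
    kept: list[str] = []
    for bi, (block, seed) in enumerate(zip(blocks, block_seeds)):
        if seed is None:
            raise ValueError(f"block {bi} has no seed")
        genes = block.gene_ids
        if len(genes) == 1:
            if q <= 0:
                kept.extend(genes)
            continue
        C = correlation_matrix(block, genes, seed.sample_subset)
        hits = np.abs(C.values) >= rho
        np.fill_diagonal(hits, False)
        frac = hits.sum(axis=1) / (len(genes) - 1)
        kept.extend(g for g, f in zip(genes, frac) if f >= q)
    return kept
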