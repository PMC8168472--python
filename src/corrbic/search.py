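"""Stochastic seed search.

The objective is the alpha score: the mean absolute pairwise Pearson
correlation among a gene set I evaluated over a sample subset J,

    alpha(I, J) = (1/|I|^2) * sum_i sum_k |C_ik(J)|,

diagonal included, so alpha lies in (0, 1] and equals 1 when every pair of
genes is perfectly (anti-)correlated over J.  A high-alpha small sample
subset (the "seed") marks samples in which the gene set behaves as one
strongly coregulated module; the search is a greedy hill-climb over
single-sample swaps starting from a uniform random subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    values: np.ndarray          # |I| x |I|, symmetric, unit diagonal
    gene_ids: list[str]
    computed_on: list[str]      # the sample subset J


@dataclass
class SeedState:
    gene_subset: list[str]
    sample_subset: list[str]
    alpha: float                 # Eq-style gene-gene mean |correlation| of the seed
    score: float = 0.0           # search objective: sample-coherence score
    trajectory: list[tuple[int, float, bool]] = field(default_factory=list)
    # trajectory rows: (iteration, best objective so far, proposal accepted?)


def _standardized_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows standardized to mean 0, sd 1 (ddof=1); constant rows zeroed and flagged."""
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sds[:, 0] == 0) | ~np.isfinite(sds[:, 0])
    sds[constant, 0] = 1.0
    z = (values - means) / sds
    z[constant, :] = 0.0
    return z, constant


def correlation_values(values: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the rows of ``values`` (columns = samples).

    Zero-variance rows get correlation 0 to every other gene but keep a unit
    diagonal, so downstream scores stay defined.
    """
    n = values.shape[1]
    if n < 3:
        raise ValueError("degenerate sample subset: correlation needs >= 3 samples")
    z, constant = _standardized_rows(values)
    C = (z @ z.T) / (n - 1)
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    if constant.any():
        logger.debug("correlation: %d zero-variance row(s) set to r=0", constant.sum())
    return C


def correlation_matrix(X: ExpressionMatrix, I, J) -> CorrelationMatrix:
    """Gene-gene Pearson correlation of gene subset I over sample subset J."""
    I = list(I)
    J = list(J)
    sub = X.data.loc[I, J].to_numpy(dtype=float)
    return CorrelationMatrix(correlation_values(sub), I, J)


def alpha_score(C: CorrelationMatrix | np.ndarray) -> float:
    """Mean absolute entry of the correlation matrix (diagonal included)."""
    values = C.values if isinstance(C, CorrelationMatrix) else C
    return float(np.abs(values).mean())


def _alpha_of(values: np.ndarray, cols: np.ndarray) -> float:
    return alpha_score(correlation_values(values[:, cols]))


def coherence_score(values: np.ndarray, cols: np.ndarray) -> float:
    """Mean absolute correlation *between the chosen samples*, across genes.

    This is the same restricted correlation matrix as the alpha score read
    along the other axis.  Averaging over the (many) genes instead of the
    (few) seed samples gives the score a near-zero noise floor, so a greedy
    hill-climb actually discriminates coherent sample subsets instead of
    overfitting the sampling noise of gene-gene correlations at small seed
    sizes; see the methods note.
    """
    return alpha_score(correlation_values(values[:, cols].T))


def expected_null_abs_corr(n: int) -> float:
    """Mean |Pearson r| of independent normals over n observations (~ sqrt(2/pi(n-1)))."""
    return float(np.sqrt(2.0 / (np.pi * max(n - 1, 1))))


def find_seed(X: ExpressionMatrix, seed_size: int, iterations: int,
              rng: np.random.Generator, gene_subset=None) -> SeedState:
    """Greedy stochastic search for a maximally coherent sample subset.

    Each iteration proposes replacing one uniformly chosen seed member with
    one uniformly chosen non-member and accepts iff the coherence score
    strictly increases, so the score trajectory is monotone non-decreasing
    and the final state is the best seen.  With ``iterations=0`` the random
    initial subset is returned as-is.  The returned state carries both the
    final search score and the gene-gene alpha of the found seed.
    """
    if seed_size < 3:
        raise ValueError("seed_size must be >= 3")
    genes = list(gene_subset) if gene_subset is not None else X.gene_ids
    values = X.data.loc[genes].to_numpy(dtype=float)
    n_samples = values.shape[1]
    if n_samples < seed_size:
        raise ValueError("seed_size exceeds the number of samples")
    if n_samples == seed_size:
        # no non-member to swap in: degenerates to a single evaluation
        members = np.arange(n_samples)
        score = coherence_score(values, members)
        logger.info("find_seed: seed covers all samples; nothing to search")
        return SeedState(gene_subset=genes, sample_subset=list(X.sample_ids),
                         alpha=_alpha_of(values, members), score=score,
                         trajectory=[(0, score, True)])

    members = rng.choice(n_samples, size=seed_size, replace=False)
    in_seed = np.zeros(n_samples, dtype=bool)
    in_seed[members] = True
    score = coherence_score(values, members)
    trajectory = [(0, score, True)]
    if iterations == 0:
        logger.info("find_seed: 0 iterations, returning random initial subset")

    for it in range(1, iterations + 1):
        swap_pos = rng.integers(seed_size)
        outside = np.flatnonzero(~in_seed)
        candidate = outside[rng.integers(outside.size)]
        proposal = members.copy()
        proposal[swap_pos] = candidate
        new_score = coherence_score(values, proposal)
        accepted = new_score > score
        if accepted:
            in_seed[members[swap_pos]] = False
            in_seed[candidate] = True
            members = proposal
            score = new_score
        trajectory.append((it, score, accepted))

    sample_ids = [X.sample_ids[j] for j in members]
    return SeedState(gene_subset=genes, sample_subset=sample_ids,
                     alpha=_alpha_of(values, members), score=score,
                     trajectory=trajectory)
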