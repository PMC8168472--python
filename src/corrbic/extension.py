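"""Extending a seed to a full bicluster.

Given a high-alpha seed, the extension step (i) purifies the gene set by
average-linkage clustering on 1 - |correlation| and keeping the cluster with
the highest internal alpha, (ii) fits PC1 on the purified genes over the
seed samples and projects *every* sample onto it, (iii) sorts samples by
|PC1| and takes the bottom background fraction as definitely-outside
samples whose maximum |PC1| sets the membership threshold, (iv) computes the
correlation vector CV — each gene's Pearson correlation with the PC1 score
over member samples — and (v) aligns signs so the strongest-|CV| gene is
positively correlated, then labels each sample's fork: upper for positive
PC1, lower otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .search import CorrelationMatrix, SeedState, alpha_score, correlation_matrix

logger = logging.getLogger(__name__)


@dataclass
class BiclusterResult:
    gene_set: list[str]                # purified genes the PC1 model is fit on
    cv: pd.Series                      # per-gene correlation with PC1, all genes
    pc1_loadings: pd.Series            # per-gene-in-gene_set, unit norm
    pc1_scores: pd.Series              # per-sample projection, all samples
    sample_order: list[str]            # decreasing |pc1_score|
    threshold: float
    in_bicluster: pd.Series            # bool per sample
    fork: pd.Series                    # "upper" / "lower" per sample
    alpha: float                       # seed alpha this run reached
    seed_samples: list[str]

    def samples_frame(self) -> pd.DataFrame:
        rank = pd.Series({s: r for r, s in enumerate(self.sample_order)}, name="rank")
        return pd.DataFrame({
            "pc1": self.pc1_scores,
            "rank": rank,
            "in_bicluster": self.in_bicluster,
            "fork": self.fork,
        })


def correlated_gene_set(C: CorrelationMatrix, min_size: int = 10) -> list[str]:
    """The gene cluster carrying the most mutual |correlation| above chance.

    Average-linkage clustering on distance 1 - |C|; every clade of the
    dendrogram (including the full set at the root) is a candidate.  Among
    candidates of size >= ``min_size`` (when any exist) the winner maximizes
    size * (internal alpha - null |r| level), which favors a large genuinely
    coherent module over a tiny cluster of genes correlated by chance at the
    small seed sample size.  If the winner's internal alpha falls below the
    full set's, the full set is returned instead, so the result's alpha
    never drops below the input's.
    """
    from .search import expected_null_abs_corr

    n = len(C.gene_ids)
    if n < 2:
        raise ValueError("correlated_gene_set needs >= 2 genes")
    A = np.abs(C.values)
    D = 1.0 - A
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2  # enforce exact symmetry for squareform
    Z = average(squareform(D, checks=False))

    # enumerate every clade, carrying member lists and the |C| mass
    # incrementally: mass(parent) = mass(a) + mass(b) + 2 * cross(a, b)
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    mass = [1.0] * n                       # diagonal |C| = 1 per singleton
    colsum = [A[:, i].copy() for i in range(n)]
    candidates: list[tuple[np.ndarray, float]] = []
    for a, b in Z[:, :2].astype(int):
        idx = np.concatenate([members[a], members[b]])
        cross = float(colsum[a][members[b]].sum())
        m = mass[a] + mass[b] + 2.0 * cross
        members.append(idx)
        mass.append(m)
        colsum.append(colsum[a] + colsum[b])
        candidates.append((idx, m / idx.size**2))

    null_level = expected_null_abs_corr(len(C.computed_on))
    pool = [c for c in candidates if c[0].size >= min(min_size, n)]
    if not pool:
        pool = candidates
    best_idx, best_alpha = max(
        pool, key=lambda c: (c[0].size * (c[1] - null_level), c[0].size))
    full_alpha = alpha_score(A)
    if best_alpha < full_alpha:
        best_idx = np.arange(n)
    return [C.gene_ids[i] for i in sorted(best_idx)]


def compute_pc1(X: ExpressionMatrix, genes, J) -> tuple[pd.Series, pd.Series]:
    """First principal component of the gene subset fit over sample subset J.

    Loadings are the unit-norm leading eigenvector of the gene x gene
    covariance over J (genes centered on their seed-sample means); scores
    are the projections of the seed samples.  Use :func:`project_scores`
    to score every sample with the same centering.
    """
    genes = list(genes)
    J = list(J)
    if len(genes) < 2:
        raise ValueError("compute_pc1 needs >= 2 genes")
    if len(J) < 3:
        raise ValueError("compute_pc1 needs >= 3 samples")
    sub = X.data.loc[genes, J].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    centered = sub - mu
    if not np.any(centered):
        raise ValueError("no variance in the selected submatrix")
    U, S, _ = np.linalg.svd(centered, full_matrices=False)
    loadings = U[:, 0]
    # deterministic sign: largest-|loading| gene points positive
    pivot = int(np.argmax(np.abs(loadings)))
    if loadings[pivot] < 0:
        loadings = -loadings
    scores = loadings @ centered
    return (pd.Series(loadings, index=genes, name="loading"),
            pd.Series(scores, index=J, name="pc1"))


def project_scores(X: ExpressionMatrix, loadings: pd.Series) -> pd.Series:
    """Project every sample onto the seed-derived loadings.

    Genes are centered on their full-cohort mean (zero for a normalized
    matrix), so a score of zero means "at the cohort average" and the
    upper/lower fork boundary is anchored to the cohort rather than to the
    seed's latent-factor mean.
    """
    genes = list(loadings.index)
    vals = X.data.loc[genes].to_numpy(dtype=float)
    centered = vals - vals.mean(axis=1, keepdims=True)
    scores = loadings.to_numpy() @ centered
    return pd.Series(scores, index=X.sample_ids, name="pc1")


def order_and_threshold(scores_all: pd.Series, background_fraction: float
                        ) -> tuple[list[str], float, pd.Series]:
    """Sort samples by decreasing |PC1|; the trailing fraction is background.

    The membership threshold is the largest |score| inside the background,
    so a sample is in the bicluster iff its |score| strictly exceeds every
    background score.  |score| ties are broken by input sample order.
    """
    n = len(scores_all)
    abs_scores = scores_all.abs().to_numpy()
    order_idx = np.lexsort((np.arange(n), -abs_scores))  # stable on ties
    sample_order = [scores_all.index[i] for i in order_idx]
    n_bg = ceil(background_fraction * n)
    if n_bg < 1:
        n_bg = 1
        logger.info("order_and_threshold: background rounded up to 1 sample")
    background = order_idx[n - n_bg:]
    threshold = float(abs_scores[background].max())
    in_bic = pd.Series(abs_scores > threshold, index=scores_all.index,
                       name="in_bicluster")
    if not in_bic.any():
        logger.warning("order_and_threshold: empty bicluster (no |score| above "
                       "background threshold %.4g)", threshold)
    return sample_order, threshold, in_bic


def compute_cv(X: ExpressionMatrix, pc1_scores: pd.Series, members) -> pd.Series:
    """Correlation vector: each gene's Pearson r with the PC1 score over members.

    Computed for every gene in the matrix, not just the bicluster's gene
    set; constant genes get cv = 0.
    """
    members = list(members)
    if len(members) < 3:
        raise ValueError("compute_cv needs >= 3 member samples")
    vals = X.data.loc[:, members].to_numpy(dtype=float)
    s = pc1_scores.loc[members].to_numpy(dtype=float)
    s_sd = s.std(ddof=1)
    if s_sd == 0:
        raise ValueError("PC1 scores constant over members")
    zs = (s - s.mean()) / s_sd
    means = vals.mean(axis=1, keepdims=True)
    sds = vals.std(axis=1, ddof=1, keepdims=True)
    constant = (sds[:, 0] == 0) | ~np.isfinite(sds[:, 0])
    sds[constant, 0] = 1.0
    zg = (vals - means) / sds
    cv = (zg @ zs) / (len(members) - 1)
    cv[constant] = 0.0
    if constant.any():
        logger.debug("compute_cv: %d constant gene(s) set to cv=0", constant.sum())
    np.clip(cv, -1.0, 1.0, out=cv)
    return pd.Series(cv, index=X.gene_ids, name="cv")


def fork_classify(scores: pd.Series) -> pd.Series:
    """Upper fork for positive PC1, lower for negative (exact zero -> lower)."""
    return pd.Series(np.where(scores.to_numpy() > 0, "upper", "lower"),
                     index=scores.index, name="fork")


def align_signs(result: BiclusterResult) -> BiclusterResult:
    """Flip all signs if the strongest-|CV| gene is negatively correlated.

    Sign of PC1 is arbitrary; this fixes a convention so that runs on
    sign-flipped data produce identical CV vectors.  Idempotent; fork
    labels are recomputed from the (possibly flipped) scores.
    """
    pivot = result.cv.abs().idxmax()
    flip = result.cv.loc[pivot] < 0
    sign = -1.0 if flip else 1.0
    scores = result.pc1_scores * sign
    return BiclusterResult(
        gene_set=result.gene_set,
        cv=result.cv * sign,
        pc1_loadings=result.pc1_loadings * sign,
        pc1_scores=scores,
        sample_order=result.sample_order,
        threshold=result.threshold,
        in_bicluster=result.in_bicluster,
        fork=fork_classify(scores),
        alpha=result.alpha,
        seed_samples=result.seed_samples,
    )


def extend_seed(X: ExpressionMatrix, seed: SeedState,
                background_fraction: float = 0.10) -> BiclusterResult:
    """Run the full seed-to-bicluster extension and return the aligned result."""
    C = correlation_matrix(X, seed.gene_subset, seed.sample_subset)
    gene_set = correlated_gene_set(C)
    loadings, _ = compute_pc1(X, gene_set, seed.sample_subset)
    scores = project_scores(X, loadings)
    sample_order, threshold, in_bic = order_and_threshold(scores, background_fraction)
    members = list(in_bic.index[in_bic])
    if len(members) < 3:
        logger.warning("extend_seed: only %d member sample(s); computing CV over "
                       "the seed samples instead", len(members))
        members = seed.sample_subset
    cv = compute_cv(X, scores, members)
    result = BiclusterResult(
        gene_set=gene_set, cv=cv, pc1_loadings=loadings, pc1_scores=scores,
        sample_order=sample_order, threshold=threshold, in_bicluster=in_bic,
        fork=fork_classify(scores), alpha=seed.alpha,
        seed_samples=seed.sample_subset,
    )
    return align_signs(result)
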