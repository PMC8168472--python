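"""Consensus over many search cycles.

Each cycle's bicluster is summarized by its CV vector; runs are compared by
the absolute Pearson correlation of their CV vectors (a bicluster and its
sign flip are the same object), clustered by average linkage on
1 - |correlation|, and the number of distinct biclusters K is chosen to
maximize the mean silhouette width over K = 2..max_k, smallest K on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .extension import BiclusterResult
from .search import _standardized_rows

logger = logging.getLogger(__name__)


@dataclass
class RunCollection:
    runs: list[BiclusterResult]
    cv_matrix: pd.DataFrame        # runs x genes

    @classmethod
    def from_runs(cls, runs: list[BiclusterResult]) -> "RunCollection":
        if not runs:
            raise ValueError("no runs")
        genes = runs[0].cv.index
        for r in runs[1:]:
            if not r.cv.index.equals(genes):
                raise ValueError("runs do not share one gene universe")
        cv = pd.DataFrame([r.cv.to_numpy() for r in runs], columns=genes)
        cv.index.name = "run"
        return cls(runs=runs, cv_matrix=cv)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([r.alpha for r in self.runs])


@dataclass
class ConsensusResult:
    similarity: pd.DataFrame               # runs x runs, in [0, 1]
    assignments: dict[int, np.ndarray]     # k -> label per run (1-based labels)
    silhouette_per_k: pd.Series            # mean width per k
    chosen_k: int
    representatives: list[int]             # run index per final cluster

    @property
    def assignment(self) -> np.ndarray:
        return self.assignments[self.chosen_k]

    def per_k_frame(self) -> pd.DataFrame:
        return self.silhouette_per_k.rename("mean_width").rename_axis("k").reset_index()


def run_similarity(runs: RunCollection | pd.DataFrame) -> pd.DataFrame:
    """|Pearson correlation| between the CV vectors of every pair of runs."""
    cv = runs.cv_matrix if isinstance(runs, RunCollection) else runs
    if cv.shape[0] < 2:
        raise ValueError("run_similarity needs >= 2 runs")
    z, constant = _standardized_rows(cv.to_numpy(dtype=float))
    S = np.abs(z @ z.T) / (cv.shape[1] - 1)
    np.clip(S, 0.0, 1.0, out=S)
    np.fill_diagonal(S, 1.0)
    if constant.any():
        logger.warning("run_similarity: %d run(s) with constant CV get similarity 0",
                       constant.sum())
    return pd.DataFrame(S, index=cv.index, columns=cv.index)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_runs(similarity: pd.DataFrame, k: int) -> np.ndarray:
    """Average-linkage clustering on distance 1 - similarity, cut into k groups."""
    n = similarity.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    D = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = average(squareform(D, checks=False))
    return _canonical_labels(fcluster(Z, t=k, criterion="maxclust"))


def silhouette_width(distance: np.ndarray, assignment: np.ndarray
                     ) -> tuple[np.ndarray, float]:
    """Silhouette widths s(i) = (b - a)/max(a, b) and their mean.

    a(i) is the mean distance to the other members of i's cluster, b(i) the
    smallest mean distance to any other cluster.  A member of a singleton
    cluster gets s = 0 by convention.
    """
    distance = np.asarray(distance, dtype=float)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    if labels.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = distance.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = assignment == assignment[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = distance[i, own].sum() / (n_own - 1)  # exclude self (distance 0)
        b = min(distance[i, assignment == lab].mean()
                for lab in labels if lab != assignment[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths, float(widths.mean())


def choose_k(similarity: pd.DataFrame, max_k: int = 20,
             alphas=None) -> ConsensusResult:
    """Pick the number of biclusters maximizing mean silhouette over k=2..max_k.

    Ties go to the smallest k.  One representative run per final cluster is
    the member with the highest alpha (first on ties).
    """
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    n = similarity.shape[0]
    D = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    ks = range(2, min(max_k, n) + 1)
    assignments: dict[int, np.ndarray] = {}
    means: dict[int, float] = {}
    for k in ks:
        labels = cluster_runs(similarity, k)
        assignments[k] = labels
        _, means[k] = silhouette_width(D, labels)
    per_k = pd.Series(means).sort_index()
    chosen_k = int(per_k.index[np.argmax(per_k.to_numpy())])  # smallest on ties
    final = assignments[chosen_k]
    if alphas is None:
        alphas = np.zeros(n)
    alphas = np.asarray(alphas, dtype=float)
    reps = []
    for lab in range(1, chosen_k + 1):
        idx = np.flatnonzero(final == lab)
        reps.append(int(idx[np.argmax(alphas[idx])]))
    return ConsensusResult(similarity=similarity, assignments=assignments,
                           silhouette_per_k=per_k, chosen_k=chosen_k,
                           representatives=reps)


def cv_correlation(cv_a: pd.Series, cv_b: pd.Series) -> float:
    """Pearson correlation between two CV vectors over their shared genes.

    Used to compare a de novo bicluster with one derived from a reference
    gene list (e.g. known androgen-regulated genes).
    """
    shared = cv_a.index.intersection(cv_b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    a = cv_a.loc[shared].to_numpy(dtype=float)
    b = cv_b.loc[shared].to_numpy(dtype=float)
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
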