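"""Gene-set statistics on a bicluster's correlation vector.

Two complementary views: over-representation of a gene set among the
bicluster's high-|CV| genes (one-sided hypergeometric, Bonferroni across
terms, with each term's average CV recording the direction of regulation),
and the weighted Kolmogorov-Smirnov running-sum enrichment score on the
full CV-ranked gene list with gene-label permutation significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRecord:
    term_id: str
    term_size: int
    overlap: int
    p_raw: float
    p_adj: float
    avg_cv: float

    @property
    def direction(self) -> str:
        return "negative" if self.avg_cv < 0 else "positive"


@dataclass
class GseaRecord:
    term_id: str
    es: float
    nes: float
    p_perm: float
    fdr_q: float


def hypergeom_enrich(selected, term_genes, universe) -> float:
    """Upper-tail hypergeometric p of observing >= overlap term genes in the selection."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    term = set(term_genes) & universe
    sel = set(selected) & universe
    overlap = len(term & sel)
    return float(hypergeom.sf(overlap - 1, len(universe), len(term), len(sel)))


def term_avg_cv(term_genes, cv: pd.Series) -> float:
    """Mean CV over the term genes present in the CV universe."""
    present = [g for g in term_genes if g in cv.index]
    if not present:
        raise ValueError("no term gene present in the CV universe")
    missing = len(set(term_genes)) - len(present)
    if missing:
        logger.debug("term_avg_cv: %d absent gene(s) ignored", missing)
    return float(cv.loc[present].mean())


def enrich_table(cv: pd.Series, gene_sets: dict[str, list[str]],
                 cv_threshold: float = 0.5) -> pd.DataFrame:
    """Over-representation of each gene set among genes with |CV| >= threshold.

    Bonferroni-adjusts over the terms actually tested (those with at least
    one gene in the universe); terms with no mapped gene are skipped with a
    log line.  Rows are sorted by adjusted then raw p.
    """
    universe = list(cv.index)
    selected = list(cv.index[cv.abs() >= cv_threshold])
    records: list[EnrichmentRecord] = []
    for name, members in gene_sets.items():
        present = [g for g in members if g in cv.index]
        if not present:
            logger.warning("enrich_table: term %s has no gene in the universe; skipped",
                           name)
            continue
        p = hypergeom_enrich(selected, present, universe)
        records.append(EnrichmentRecord(
            term_id=name, term_size=len(present),
            overlap=len(set(present) & set(selected)),
            p_raw=p, p_adj=p, avg_cv=term_avg_cv(present, cv)))
    m = len(records)
    rows = []
    for rec in records:
        rec.p_adj = min(1.0, m * rec.p_raw)
        rows.append({"term": rec.term_id, "size": rec.term_size,
                     "overlap": rec.overlap, "p_raw": rec.p_raw,
                     "p_adj": rec.p_adj, "avg_cv": rec.avg_cv,
                     "direction": rec.direction})
    df = pd.DataFrame(rows, columns=["term", "size", "overlap", "p_raw",
                                     "p_adj", "avg_cv", "direction"])
    return df.sort_values(["p_adj", "p_raw", "term"], kind="stable").reset_index(drop=True)


def _running_es(weights: np.ndarray, hit: np.ndarray) -> float:
    """Signed maximum deviation of the weighted hit/miss running sum."""
    n = hit.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("empty gene set after mapping")
    if n_hit == n:
        return 1.0
    hit_w = np.where(hit, weights, 0.0)
    total_w = hit_w.sum()
    if total_w == 0:
        hit_w = hit.astype(float)   # all-zero weights: fall back to equal steps
        total_w = float(n_hit)
    running = np.cumsum(hit_w / total_w - (~hit) / (n - n_hit))
    peak = int(np.argmax(np.abs(running)))
    return float(np.clip(running[peak], -1.0, 1.0))


def gsea_es(ranked_genes, weights, term_genes) -> float:
    """Enrichment score of a term on a CV-ranked gene list.

    ``ranked_genes`` must be sorted by CV descending; ``weights`` are the
    per-gene |CV| values in the same order (weight exponent 1).  Hits step
    the running sum up by weight/sum(term weights); misses step it down by
    1/(N - term size); the ES is the running-sum value at the maximum
    absolute deviation, signed.
    """
    ranked = list(ranked_genes)
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(ranked),):
        raise ValueError("weights must align with ranked_genes")
    term = set(term_genes)
    hit = np.fromiter((g in term for g in ranked), dtype=bool, count=len(ranked))
    return _running_es(np.abs(w), hit)


def gsea_significance(ranked_genes, weights, term_genes, n_perm: int,
                      rng: np.random.Generator) -> GseaRecord:
    """Permutation significance of an ES by random same-size gene-label sets.

    p is the same-sign tail fraction of the null; NES divides the ES by the
    mean |null ES| of that sign; the FDR q for a single term reduces to the
    tail fraction on the NES scale, clipped to [0, 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = list(ranked_genes)
    w = np.abs(np.asarray(weights, dtype=float))
    term = set(term_genes) & set(ranked)
    if not term:
        raise ValueError("empty gene set after mapping")
    es = gsea_es(ranked, w, term)
    n = len(ranked)
    size = len(term)
    null = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        hit[:] = False
        hit[rng.choice(n, size=size, replace=False)] = True
        null[b] = _running_es(w, hit)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    floor = 1.0 / (n_perm + 1)
    if same_sign.size == 0:
        logger.warning("gsea_significance: no same-sign null ES; p floored")
        return GseaRecord(term_id="", es=es, nes=np.sign(es) * np.inf,
                          p_perm=floor, fdr_q=floor)
    p = max(float(np.mean(np.abs(same_sign) >= abs(es))), floor)
    mean_null = float(np.abs(same_sign).mean())
    nes = es / mean_null if mean_null > 0 else 0.0
    null_nes = same_sign / mean_null
    q = float(np.mean(np.abs(null_nes) >= abs(nes)))
    return GseaRecord(term_id="", es=es, nes=nes, p_perm=p,
                      fdr_q=min(1.0, max(q, 0.0)))


def gsea_table(cv: pd.Series, gene_sets: dict[str, list[str]], n_perm: int,
               rng: np.random.Generator) -> pd.DataFrame:
    """Run GSEA for every term against the CV-ranked gene list."""
    order = cv.sort_values(ascending=False, kind="stable")
    ranked = list(order.index)
    weights = order.abs().to_numpy()
    rows = []
    for name, members in gene_sets.items():
        present = set(members) & set(ranked)
        if not present:
            logger.warning("gsea_table: term %s has no mapped gene; skipped", name)
            continue
        rec = gsea_significance(ranked, weights, present, n_perm, rng)
        rows.append({"term": name, "es": rec.es, "nes": rec.nes,
                     "p": rec.p_perm, "q": rec.fdr_q})
    return pd.DataFrame(rows, columns=["term", "es", "nes", "p", "q"])
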