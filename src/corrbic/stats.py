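"""Differential and clinical-association statistics.

Mann-Whitney U with midrank ties (exact when both groups are small and
tie-free, normal approximation with tie and continuity correction
otherwise), fork x clinical-category contingency summaries, and the
cross-cohort replication filter used to call robust differential genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 8


def mwu_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p).

    Exact enumeration when both groups have at most 8 observations and no
    value is shared between or within groups; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= _EXACT_MAX_N and b.size <= _EXACT_MAX_N
                         and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ContingencyTable:
    counts: pd.DataFrame        # fork rows x category columns
    proportions: pd.DataFrame   # per-row fractions
    percentages: pd.DataFrame   # proportions * 100, rounded to 1 dp
    n_dropped: int              # samples excluded for missing annotation

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fork in self.counts.index:
            for cat in self.counts.columns:
                rows.append({"fork": fork, "category": cat,
                             "count": int(self.counts.loc[fork, cat]),
                             "pct": self.percentages.loc[fork, cat]})
        return pd.DataFrame(rows)


def fork_contingency(fork: pd.Series, annotation: pd.Series) -> ContingencyTable:
    """Cross-tabulate fork labels against one clinical category.

    Samples missing either value are dropped (and counted); per-fork
    proportions are reported, with percentages rounded to one decimal.
    """
    df = pd.concat([fork.rename("fork"), annotation.rename("category")],
                   axis=1, join="inner")
    n_joined = len(df)
    df = df.replace("", np.nan).dropna()
    n_dropped = n_joined - len(df)
    if df.empty:
        raise ValueError("no overlapping annotated samples")
    if df["category"].nunique() < 2:
        raise ValueError("need >= 2 annotation categories after dropping missing values")
    if n_dropped:
        logger.info("fork_contingency: %d sample(s) dropped for missing annotation",
                    n_dropped)
    counts = pd.crosstab(df["fork"], df["category"])
    totals = counts.sum(axis=1)
    proportions = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    percentages = (proportions * 100).round(1)
    return ContingencyTable(counts=counts, proportions=proportions,
                            percentages=percentages, n_dropped=n_dropped)


def multi_cohort_filter(p_values: pd.DataFrame, alpha: float = 0.05,
                        min_cohorts: int = 2) -> list[str]:
    """Genes significant (p <= alpha) in at least ``min_cohorts`` cohorts.

    ``p_values`` is genes x cohorts; NaN means the gene was not tested in
    that cohort and never counts as significant.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if min_cohorts < 1:
        raise ValueError("min_cohorts must be >= 1")
    hits = (p_values <= alpha).sum(axis=1)
    return list(p_values.index[hits >= min_cohorts])


def differential_table(cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
                       ) -> pd.DataFrame:
    """Per-gene U test in each cohort.

    Each cohort maps to a (group_a, group_b) pair of genes x samples
    frames sharing a gene index.  Returns long-format (gene, cohort, U, p).
    """
    rows = []
    for cohort, (a_df, b_df) in cohorts.items():
        shared = a_df.index.intersection(b_df.index)
        for gene in shared:
            U, p = mwu_test(a_df.loc[gene].to_numpy(), b_df.loc[gene].to_numpy())
            rows.append({"gene": gene, "cohort": cohort, "U": U, "p": p})
    return pd.DataFrame(rows, columns=["gene", "cohort", "U", "p"])
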