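"""End-to-end orchestration: preprocessing, multi-cycle search, consensus.

Each consensus cycle runs an independent seed search (sub-seeded
deterministically as rng_seed + cycle index, so any cycle can be reproduced
in isolation) followed by the bicluster extension, and contributes one CV
vector to the run collection.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import PipelineConfig
from .consensus import ConsensusResult, RunCollection, choose_k, run_similarity
from .extension import BiclusterResult, extend_seed
from .io import ExpressionMatrix
from .preprocess import filter_low_expression, normalize
from .search import SeedState, find_seed

logger = logging.getLogger(__name__)

_SEED_MOD = 2**31


def cycle_seed(rng_seed: int, cycle: int) -> int:
    """Deterministic per-cycle sub-seed (kept below 2^31)."""
    return (int(rng_seed) + int(cycle)) % _SEED_MOD


def preprocess_matrix(raw: ExpressionMatrix, config: PipelineConfig
                      ) -> ExpressionMatrix:
    filtered, report = filter_low_expression(raw, config.min_expression)
    logger.info("preprocess: %d/%d genes pass the expression filter",
                report.n_kept, report.n_input)
    return normalize(filtered)


def run_cycle(X: ExpressionMatrix, config: PipelineConfig, cycle: int
              ) -> tuple[SeedState, BiclusterResult]:
    rng = np.random.default_rng(cycle_seed(config.rng_seed, cycle))
    seed = find_seed(X, config.seed_size, config.iterations, rng)
    return seed, extend_seed(X, seed, config.background_fraction)


def run_cycles(X: ExpressionMatrix, config: PipelineConfig) -> RunCollection:
    """Run ``config.cycles`` independent search+extension cycles."""
    if not X.normalized:
        raise ValueError("run_cycles expects a normalized matrix")
    results = []
    for c in range(config.cycles):
        _, result = run_cycle(X, config, c)
        results.append(result)
        logger.info("cycle %d/%d: alpha=%.4f, |gene_set|=%d, members=%d",
                    c + 1, config.cycles, result.alpha, len(result.gene_set),
                    int(result.in_bicluster.sum()))
    return RunCollection.from_runs(results)


def consensus_from_runs(runs: RunCollection, max_k: int) -> ConsensusResult:
    similarity = run_similarity(runs)
    return choose_k(similarity, max_k=max_k, alphas=runs.alphas)
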