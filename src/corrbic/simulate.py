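"""Synthetic expression data with planted rank-1 biclusters.

The generative model works on the normalized scale: background entries are
Normal(0, sigma^2) noise; inside a planted block the model adds
lambda * w_g * f_j, a latent factor f per block sample times signed gene
loadings w, which is the minimal structure producing the massive
high-|correlation| gene blocks the alpha score targets (anticorrelated
sub-blocks arise from loadings of opposite sign).  The normalized-scale
matrix is then mapped to a raw abundance scale, x_raw = base * 10^(x/c),
so the low-expression filter and log10/z-score normalization are genuinely
exercised and round-trip back to the model up to a per-gene affine map
(which leaves every correlation-based statistic unchanged).

Ground truth (memberships, loadings, factors) is retained in a flat record
serializable to JSON, so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class PlantedBicluster:
    """Specification of one planted block: which genes/samples, how strong."""
    n_genes: int
    n_samples: int
    strength: float = 3.0           # lambda, in noise-sd units
    neg_fraction: float = 0.5       # fraction of genes given negative loadings
    gene_ids: list[str] = field(default_factory=list)    # filled at simulation
    sample_ids: list[str] = field(default_factory=list)
    loadings: list[float] = field(default_factory=list)
    factor: list[float] = field(default_factory=list)


@dataclass
class SimulationTruth:
    n_genes: int
    n_samples: int
    noise_sd: float
    blocks: list[PlantedBicluster]
    low_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "n_genes": self.n_genes, "n_samples": self.n_samples,
            "noise_sd": self.noise_sd, "low_genes": self.low_genes,
            "blocks": [{
                "gene_ids": b.gene_ids, "sample_ids": b.sample_ids,
                "strength": b.strength, "loadings": b.loadings,
                "factor": b.factor,
            } for b in self.blocks],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        blocks = [PlantedBicluster(
            n_genes=len(b["gene_ids"]), n_samples=len(b["sample_ids"]),
            strength=b["strength"], gene_ids=b["gene_ids"],
            sample_ids=b["sample_ids"], loadings=b["loadings"],
            factor=b["factor"]) for b in payload["blocks"]]
        return cls(n_genes=payload["n_genes"], n_samples=payload["n_samples"],
                   noise_sd=payload["noise_sd"], blocks=blocks,
                   low_genes=payload["low_genes"])


def simulate_matrix(n_genes: int, n_samples: int,
                    biclusters: list[PlantedBicluster],
                    rng: np.random.Generator,
                    noise_sd: float = 1.0,
                    n_low_genes: int = 0,
                    min_expression: float = 1.0,
                    log_scale: float = 6.0,
                    base_log10: float = 4.0,
                    allow_overlap: bool = False,
                    ) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate a raw-scale expression matrix with planted biclusters.

    Planted gene (and sample) sets are drawn disjointly unless
    ``allow_overlap``; ``n_low_genes`` background genes get one sample value
    below ``min_expression`` so the preprocessing filter has work to do.
    """
    for b in biclusters:
        if b.n_genes > n_genes or b.n_samples > n_samples:
            raise ValueError("planted block larger than matrix")
    total_genes = sum(b.n_genes for b in biclusters)
    total_samples = sum(b.n_samples for b in biclusters)
    if not allow_overlap and (total_genes > n_genes or total_samples > n_samples):
        raise ValueError("disjoint planted blocks exceed matrix size")

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    Z = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    gene_pool = list(rng.permutation(n_genes))
    sample_pool = list(rng.permutation(n_samples))
    for b in biclusters:
        if allow_overlap:
            g_idx = rng.choice(n_genes, size=b.n_genes, replace=False)
            s_idx = rng.choice(n_samples, size=b.n_samples, replace=False)
        else:
            g_idx = np.array([gene_pool.pop() for _ in range(b.n_genes)])
            s_idx = np.array([sample_pool.pop() for _ in range(b.n_samples)])
        n_neg = int(round(b.neg_fraction * b.n_genes))
        signs = np.ones(b.n_genes)
        signs[:n_neg] = -1.0
        rng.shuffle(signs)
        factor = rng.normal(0.0, 1.0, size=b.n_samples)
        Z[np.ix_(g_idx, s_idx)] += b.strength * np.outer(signs, factor)
        b.gene_ids = [gene_ids[i] for i in g_idx]
        b.sample_ids = [sample_ids[j] for j in s_idx]
        b.loadings = signs.tolist()
        b.factor = factor.tolist()

    raw = 10.0 ** (Z / log_scale + base_log10)
    low_genes: list[str] = []
    if n_low_genes:
        planted = {g for b in biclusters for g in b.gene_ids}
        candidates = [i for i, g in enumerate(gene_ids) if g not in planted]
        pick = rng.choice(len(candidates), size=min(n_low_genes, len(candidates)),
                         replace=False)
        for i in pick:
            gi = candidates[i]
            raw[gi, rng.integers(n_samples)] = min_expression / 2.0
            low_genes.append(gene_ids[gi])

    data = pd.DataFrame(raw, index=gene_ids, columns=sample_ids)
    truth = SimulationTruth(n_genes=n_genes, n_samples=n_samples,
                            noise_sd=noise_sd, blocks=biclusters,
                            low_genes=sorted(low_genes))
    return ExpressionMatrix(data), truth


def simulate_clinical(truth: SimulationTruth, assoc_prob: float,
                      rng: np.random.Generator,
                      column: str = "group",
                      labels: tuple[str, str] = ("pos", "neg"),
                      block: int = 0) -> pd.DataFrame:
    """Binary clinical label associated with the sign of a block's factor.

    Samples in the chosen planted block get the label matching their factor
    sign with probability ``assoc_prob`` (flipped otherwise); background
    samples are labeled uniformly at random.
    """
    if not 0.5 <= assoc_prob <= 1.0:
        raise ValueError("assoc_prob must lie in [0.5, 1]")
    b = truth.blocks[block]
    factor_sign = dict(zip(b.sample_ids, np.sign(b.factor)))
    sample_ids = [f"S{j:04d}" for j in range(truth.n_samples)]
    out = []
    for s in sample_ids:
        if s in factor_sign:
            match = factor_sign[s] > 0
            if rng.random() >= assoc_prob:
                match = not match
            out.append(labels[0] if match else labels[1])
        else:
            out.append(labels[int(rng.random() < 0.5)])
    df = pd.DataFrame({column: out}, index=pd.Index(sample_ids, name="sample"))
    return df


def simulate_genesets(truth: SimulationTruth, n_decoy: int, set_size: int,
                      rng: np.random.Generator,
                      block: int = 0) -> dict[str, list[str]]:
    """Gene sets with known relation to a planted block, plus random decoys.

    ``planted_negative`` / ``planted_positive`` collect the block's genes
    with negative / positive loadings (emulating e.g. mitochondrial terms
    anticorrelated with the module); decoys are uniform draws from all genes.
    """
    if set_size > truth.n_genes:
        raise ValueError("set_size exceeds the gene universe")
    b = truth.blocks[block]
    negative = [g for g, w in zip(b.gene_ids, b.loadings) if w < 0]
    positive = [g for g, w in zip(b.gene_ids, b.loadings) if w > 0]
    gene_ids = [f"G{i:05d}" for i in range(truth.n_genes)]
    sets = {"planted_negative": negative, "planted_positive": positive}
    for d in range(n_decoy):
        idx = rng.choice(truth.n_genes, size=set_size, replace=False)
        sets[f"decoy_{d:03d}"] = [gene_ids[i] for i in sorted(idx)]
    return sets
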