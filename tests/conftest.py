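import numpy as np
import pandas as pd
import pytest

from corrbic import ExpressionMatrix, PlantedBicluster, simulate_matrix
from corrbic.preprocess import filter_low_expression, normalize


def make_matrix(values, gene_ids=None, sample_ids=None, normalized=False):
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            normalized=normalized)


@pytest.fixture
def planted_instance():
    """One 60-gene x 30-sample block at lambda=3 in a 200 x 100 matrix, normalized."""
    rng = np.random.default_rng(20)
    block = PlantedBicluster(n_genes=60, n_samples=30, strength=3.0)
    raw, truth = simulate_matrix(200, 100, [block], rng)
    filtered, _ = filter_low_expression(raw)
    return normalize(filtered), truth


from hypothesis import settings as _hsettings

_hsettings.register_profile("ci", derandomize=True, deadline=None)
_hsettings.load_profile("ci")
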