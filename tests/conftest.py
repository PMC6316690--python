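import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ricenet.expression import CountMatrix
from ricenet.network_build import SignedWeightedGraph
from ricenet.pipeline import run_all
from ricenet.synthetic_data import SyntheticConfig, generate_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_graph(adj, weights, tau=0.1, nodes=None):
    """SignedWeightedGraph whose binary view reproduces a planted adjacency."""
    n = adj.shape[0]
    nodes = nodes or [f"n{i}" for i in range(n)]
    return SignedWeightedGraph(nodes=nodes, weights=np.where(adj, weights, 0.0), tau=tau)


def toy_count_matrix(counts, conditions=None, stages=None):
    """Small CountMatrix with an auto-generated sample sheet."""
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    conditions = conditions or ["normal", "stress"] * (n_samples // 2 + 1)
    stages = stages or ["seedling"] * n_samples
    samples = pd.DataFrame(
        {
            "condition": conditions[:n_samples],
            "stage": stages[:n_samples],
            "replicate": range(1, n_samples + 1),
        },
        index=pd.Index([f"s{j}" for j in range(n_samples)], name="sample"),
    )
    frame = pd.DataFrame(
        counts,
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene"),
        columns=samples.index,
    )
    return CountMatrix(counts=frame, samples=samples)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the standard regime, shared across the suite."""
    config = SyntheticConfig(seed=1)
    cm, samples, truth = generate_dataset(config)
    return config, cm, samples, truth


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the standard regime (seed 1)."""
    return run_all(seed=1)
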