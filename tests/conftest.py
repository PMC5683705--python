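import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from netmod.io import ExpressionMatrix, PPINetwork, PhenotypeLabels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """4 genes x 6 samples with one clear tumor-up gene."""
    genes = ("GA", "GB", "GC", "GD")
    samples = tuple(f"S{i}" for i in range(6))
    values = np.array([
        [5.0, 6.0, 5.5, 1.0, 1.2, 0.9],   # GA: up in tumors
        [1.0, 1.1, 0.9, 1.0, 1.2, 0.8],   # GB: flat
        [0.05, 0.04, 0.06, 0.05, 0.03, 0.02],  # GC: low everywhere
        [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],   # GD: constant
    ])
    return ExpressionMatrix(genes, samples, values)


@pytest.fixture
def small_labels(small_expr):
    return PhenotypeLabels(small_expr.sample_ids, np.array([1, 1, 1, 0, 0, 0]))


@pytest.fixture
def path_network():
    """Path graph A-B-C-D-E-F."""
    nodes = ["A", "B", "C", "D", "E", "F"]
    return PPINetwork.from_edges(zip(nodes[:-1], nodes[1:]))


def make_labels(n_tumor: int, n_normal: int) -> PhenotypeLabels:
    samples = tuple(f"T{i}" for i in range(n_tumor)) + \
        tuple(f"N{i}" for i in range(n_normal))
    return PhenotypeLabels(samples, np.array([1] * n_tumor + [0] * n_normal))


def make_expr(genes, values, labels: PhenotypeLabels) -> ExpressionMatrix:
    return ExpressionMatrix(tuple(genes), labels.sample_ids, np.asarray(values))
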