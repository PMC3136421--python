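import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from grnilab import (
    ACTIVATOR,
    REPRESSOR,
    DirectedNetwork,
    InferredNetwork,
    MIMatrix,
)


@pytest.fixture
def chain_net() -> DirectedNetwork:
    """A -> B -> C with one activator and one repressor edge."""
    return DirectedNetwork(
        ["A", "B", "C"],
        {("A", "B"), ("B", "C")},
        {("A", "B"): ACTIVATOR, ("B", "C"): REPRESSOR},
    )


@pytest.fixture
def star_net() -> DirectedNetwork:
    """Hub B regulating A, C, D."""
    return DirectedNetwork(
        ["A", "B", "C", "D"],
        {("B", "A"), ("B", "C"), ("B", "D")},
        {("B", "A"): ACTIVATOR, ("B", "C"): ACTIVATOR, ("B", "D"): REPRESSOR},
    )


def random_mi_matrix(n: int, rng: np.random.Generator) -> MIMatrix:
    """Symmetric matrix of distinct positive MI-like values."""
    vals = rng.random((n, n))
    vals = np.triu(vals, k=1)
    vals = vals + vals.T
    return MIMatrix([f"G{i + 1}" for i in range(n)], vals)


def inferred_from_pairs(gene_ids, idx_pairs) -> InferredNetwork:
    genes = list(gene_ids)
    edges = {(genes[a], genes[b]) for a, b in idx_pairs}
    return InferredNetwork(genes, edges, {}, "toy", {})
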