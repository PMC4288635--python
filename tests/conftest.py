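import numpy as np
import pytest

from tsocd.io import ExpressionMatrix, StaticNetwork


@pytest.fixture
def two_cliques():
    """Two disjoint 4-cliques on 8 nodes (binary adjacency, zero diagonal)."""
    A = np.zeros((8, 8))
    A[np.ix_(range(4), range(4))] = 1
    A[np.ix_(range(4, 8), range(4, 8))] = 1
    np.fill_diagonal(A, 0)
    return A


@pytest.fixture
def toy_net():
    return StaticNetwork(
        nodes=["A", "B", "C", "D"],
        edges={("A", "B"), ("B", "C"), ("C", "D"), ("A", "D")},
    )


@pytest.fixture
def toy_expr():
    values = np.array(
        [
            [1.0, 2.0, 3.0, 4.0],
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
            [1.0, 3.0, 2.0, 4.0],
        ]
    )
    return ExpressionMatrix(gene_ids=["A", "B", "C", "D"], values=values)


def random_instances(n_instances, N=10, T=3, r=3, seed=0, density=0.4):
    """Seeded random (H_list, A_list, S) triples for optimizer tests."""
    root = np.random.SeedSequence(seed)
    out = []
    for child in root.spawn(n_instances):
        rng = np.random.default_rng(child)
        A_list = []
        for _ in range(T):
            A = (rng.random((N, N)) < density).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            A_list.append(A)
        S = np.triu((rng.random((N, N)) < 0.3).astype(float), 1)
        S = S + S.T
        H_list = [rng.uniform(0.1, 1.0, size=(N, r)) for _ in range(T)]
        out.append((H_list, A_list, S))
    return out
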