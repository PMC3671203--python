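import numpy as np
import pandas as pd
import pytest

from netact.network import (
    ModuleEdge,
    NetworkModule,
    SignalingNetwork,
    fixture_network,
)


@pytest.fixture(scope="session")
def net():
    """The bundled reduced demonstration network."""
    return fixture_network()


@pytest.fixture
def toy_net():
    """Two modules sharing one gene, one edge: stats by hand are (3, 2, 1)."""
    return SignalingNetwork(
        modules={
            "M1": NetworkModule("M1", "P", "Ligand", frozenset({"A", "B"})),
            "M2": NetworkModule("M2", "P", "Receptor", frozenset({"B", "C"})),
        },
        edges=[ModuleEdge("M1", "M2", "activation")],
    )


@pytest.fixture
def expr_small():
    """3 genes x 4 samples positive matrix with easy medians."""
    return pd.DataFrame(
        [[1.0, 2.0, 10.0, 4.0], [2.0, 4.0, 20.0, 8.0], [3.0, 8.0, 30.0, 6.0]],
        index=["A", "B", "C"],
        columns=["s1", "s2", "s3", "s4"],
    )


def random_distance_matrix(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Symmetric zero-diagonal distance matrix with continuous entries."""
    m = rng.uniform(0.01, 2.0, size=(n, n))
    d = np.triu(m, 1)
    d = d + d.T
    return pd.DataFrame(d, index=[f"o{i}" for i in range(n)],
                        columns=[f"o{i}" for i in range(n)])


def brute_force_complete_linkage(d: pd.DataFrame):
    """O(n^3) reference agglomeration: repeatedly merge the closest pair under
    the maximum inter-cluster distance; returns (heights, partitions), where
    partitions[i] is the set of frozensets after merge i."""
    ids = list(d.columns)
    clusters: list[frozenset] = [frozenset([i]) for i in ids]
    dist = {
        frozenset([a, b]): float(d.loc[a, b])
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
    }

    def cdist(c1, c2):
        return max(float(d.loc[a, b]) for a in c1 for b in c2)

    heights, partitions = [], []
    while len(clusters) > 1:
        best = min(
            (
                (cdist(c1, c2), i, j)
                for i, c1 in enumerate(clusters)
                for j, c2 in enumerate(clusters)
                if i < j
            ),
            key=lambda t: t[0],
        )
        h, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        heights.append(h)
        partitions.append(frozenset(clusters))
    return heights, partitions
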