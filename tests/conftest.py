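"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cotype.io import EdgeTable, Skeleton


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_tree_skeleton(rng, n: int = 20, scale: float = 10.0) -> Skeleton:
    """Random rooted tree with uniform random parents and coordinates."""
    node_id = np.arange(1, n + 1)
    parent = np.array([-1] + [int(rng.integers(1, i + 1)) for i in range(1, n)])
    xyz = rng.uniform(-scale, scale, size=(n, 3))
    return Skeleton(
        pd.DataFrame(
            {
                "node_id": node_id,
                "parent_id": parent,
                "x": xyz[:, 0],
                "y": xyz[:, 1],
                "z": xyz[:, 2],
                "radius": np.full(n, 0.5),
            }
        )
    )


def random_edge_table(rng, n_edges: int = 50, n_neurons: int = 12, neuropils=("", "npA")) -> EdgeTable:
    ids = [f"n{i}" for i in range(n_neurons)]
    rows = []
    for _ in range(n_edges):
        rows.append(
            (
                ids[int(rng.integers(n_neurons))],
                ids[int(rng.integers(n_neurons))],
                int(rng.integers(1, 20)),
                neuropils[int(rng.integers(len(neuropils)))],
            )
        )
    return EdgeTable.from_records(rows)


def linear_skeleton(points: np.ndarray) -> Skeleton:
    """Unbranched chain through the given (n, 3) points."""
    n = len(points)
    return Skeleton(
        pd.DataFrame(
            {
                "node_id": np.arange(1, n + 1),
                "parent_id": np.concatenate([[-1], np.arange(1, n)]),
                "x": points[:, 0],
                "y": points[:, 1],
                "z": points[:, 2],
                "radius": np.full(n, 1.0),
            }
        )
    )
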