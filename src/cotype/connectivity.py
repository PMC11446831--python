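"""Cross-dataset connectivity profiles and distances.

The profile matrix has one row per query neuron (pooled across datasets)
and one (direction, cell type) column per shared type — a type counts as
shared only if it is cross-identified in *every* dataset.  Values are raw
synapse counts by default; cosine distance is invariant to per-row scaling,
so completion-rate differences that scale a neuron's whole profile do not
move it.

Connectivity clustering depends absolutely on a corpus of shared labels
between the datasets (initially from morphological matching); with no
shared types the profile is undefined and an error is raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import EdgeTable

__all__ = [
    "ConnectivityProfile",
    "DistanceMatrix",
    "build_profiles",
    "cosine_distances",
    "combined_distances",
]


@dataclass
class ConnectivityProfile:
    """Neurons × (direction, shared type) synapse-weight matrix.

    ``matrix`` rows are indexed by (dataset, neuron_id); columns by
    (direction in {'in', 'out'}, type).
    """

    matrix: pd.DataFrame
    shared_types: tuple[str, ...]
    unassigned_partners: int = 0

    def normalized(self) -> "ConnectivityProfile":
        """Per-row normalization to fractions (for reporting; cosine
        distances are unchanged by it)."""
        m = self.matrix.to_numpy(dtype=float)
        s = m.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return ConnectivityProfile(
            pd.DataFrame(m / s, index=self.matrix.index, columns=self.matrix.columns),
            self.shared_types,
            self.unassigned_partners,
        )

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


@dataclass
class DistanceMatrix:
    """Square symmetric pairwise distance matrix over pooled neurons."""

    values: np.ndarray
    ids: tuple
    metric: str
    zero_rows: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.ids)
        return pd.DataFrame(self.values, index=idx, columns=idx)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def build_profiles(
    edge_tables: dict[str, EdgeTable],
    assignments: dict[str, dict[str, str]],
    queries: dict[str, list[str]],
    directions: tuple[str, ...] = ("in", "out"),
    normalize: bool = False,
) -> ConnectivityProfile:
    """Stack per-dataset adjacency-to-shared-type matrices row-wise.

    For every query neuron, in-column(T) holds synapses received from
    members of type T and out-column(T) synapses sent to members of T,
    within the neuron's own dataset.  Only types assigned in *all* datasets
    become columns.  Partners without a shared-type assignment contribute
    nothing (counted in ``unassigned_partners``).
    """
    shared = None
    for ds, asg in assignments.items():
        types = set(asg.values())
        shared = types if shared is None else shared & types
    shared = sorted(shared or ())
    if not shared:
        raise ValueError("no cross-identified types shared by all datasets")
    col_index = pd.MultiIndex.from_product(
        [list(directions), shared], names=["direction", "type"]
    )
    blocks = []
    row_index = []
    unassigned = 0
    for ds, qids in queries.items():
        edges = edge_tables[ds].df
        asg = assignments[ds]
        qset = set(qids)
        mat = pd.DataFrame(0.0, index=pd.Index(qids, name="neuron_id"), columns=col_index)
        shared_set = set(shared)
        for direction in directions:
            own, partner = ("pre_id", "post_id") if direction == "out" else ("post_id", "pre_id")
            sub = edges[edges[own].isin(qset)]
            ptype = sub[partner].map(asg)
            unassigned += int(ptype.isna().sum())
            keep = ptype.isin(shared_set)
            grp = (
                sub[keep]
                .groupby([sub.loc[keep, own], ptype[keep]])["weight"]
                .sum()
                .unstack(fill_value=0)
            )
            grp = grp.reindex(index=qids, columns=shared, fill_value=0)
            mat.loc[:, (direction, slice(None))] = grp.to_numpy(dtype=float)
        blocks.append(mat)
        row_index.extend((ds, q) for q in qids)
    matrix = pd.concat(blocks)
    matrix.index = pd.MultiIndex.from_tuples(row_index, names=["dataset", "neuron_id"])
    prof = ConnectivityProfile(matrix, tuple(shared), unassigned)
    return prof.normalized() if normalize else prof


def cosine_distances(profile: ConnectivityProfile) -> DistanceMatrix:
    """Pairwise cosine distance d(u, v) = 1 - u·v / (|u| |v|).

    Rows that are all zero have no defined angle; they are assigned
    distance 1 to everything and flagged in ``zero_rows``.
    """
    m = profile.matrix.to_numpy(dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 profile rows")
    norms = np.linalg.norm(m, axis=1)
    zero = norms == 0
    d = squareform(pdist(np.where(zero[:, None], 1.0, m), metric="cosine"))
    if zero.any():
        d[zero, :] = 1.0
        d[:, zero] = 1.0
        warnings.warn(f"{int(zero.sum())} zero profile rows assigned distance 1")
    np.fill_diagonal(d, 0.0)
    d = np.clip(0.5 * (d + d.T), 0.0, None)
    ids = tuple(profile.matrix.index)
    flagged = tuple(i for i, z in zip(ids, zero) if z)
    return DistanceMatrix(d, ids, "cosine", zero_rows=flagged)


def combined_distances(
    conn: DistanceMatrix,
    morph: DistanceMatrix,
    weights: tuple[float, float] = (1.0, 1.0),
) -> DistanceMatrix:
    """Weighted elementwise sum of connectivity and morphology distances
    (default 1:1), over the same row ordering."""
    if conn.values.shape != morph.values.shape:
        raise ValueError("distance matrices have mismatched shapes")
    if tuple(conn.ids) != tuple(morph.ids):
        raise ValueError("distance matrices have mismatched row orderings")
    vals = weights[0] * conn.values + weights[1] * morph.values
    return DistanceMatrix(vals, conn.ids, "combined")
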