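"""Across-dataset cell typing by balanced co-clustering.

A *cell type* is operationalized here as a group of neurons each more
similar to a group in another brain than to any neuron in the same brain.
Concretely: pool neurons from all datasets, build a Ward dendrogram over a
(connectivity, morphology or combined) distance matrix, and extract the
smallest clusters that (1) contain neurons from all datasets and (2) hold
approximately equal numbers from each — "balanced" clusters.

"Approximately equal" is formalized as max_count <= max_ratio * min_count
+ abs_slack with defaults (2.0, 1); the tolerance is a first-class
parameter recorded in the output metadata.

The model-style entry point is :class:`MultiConnectomeTyping`, whose
``fit()`` returns a :class:`TypingResults` with the assignment, per-type
per-dataset counts and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .connectivity import DistanceMatrix

__all__ = [
    "Dendrogram",
    "BalanceParams",
    "TypeAssignment",
    "TypeMapping",
    "ward_linkage",
    "extract_balanced_clusters",
    "classify_mapping",
    "persistent_groups",
    "apply_overrides",
    "MultiConnectomeTyping",
    "TypingResults",
]


@dataclass
class Dendrogram:
    """Binary merge tree over pooled neurons (wraps a scipy linkage)."""

    linkage_matrix: np.ndarray
    leaf_ids: tuple

    def __post_init__(self):
        Z = np.asarray(self.linkage_matrix, dtype=float)
        n = len(self.leaf_ids)
        if Z.shape != (n - 1, 4):
            raise ValueError("linkage shape inconsistent with leaf count")
        heights = Z[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")
        self.linkage_matrix = Z

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def root(self):
        return to_tree(self.linkage_matrix)

    def members(self) -> dict[int, tuple]:
        """node index -> tuple of leaf ids (leaves are 0..n-1)."""
        n = self.n_leaves
        out: dict[int, tuple] = {i: (self.leaf_ids[i],) for i in range(n)}
        for i, (a, b, _, _) in enumerate(self.linkage_matrix):
            out[n + i] = out[int(a)] + out[int(b)]
        return out


def ward_linkage(dist: DistanceMatrix | np.ndarray, ids=None) -> Dendrogram:
    """Agglomerative Ward merge tree on the given (possibly non-Euclidean)
    distances, via the Lance–Williams update."""
    if isinstance(dist, DistanceMatrix):
        values, ids = dist.values, dist.ids
    else:
        values = np.asarray(dist, dtype=float)
        ids = tuple(range(len(values))) if ids is None else tuple(ids)
    if np.isnan(values).any():
        raise ValueError("NaN in distance matrix")
    Z = linkage(squareform(values, checks=False), method="ward")
    return Dendrogram(Z, tuple(ids))


@dataclass
class BalanceParams:
    """Parameters of the balance predicate for cluster extraction."""

    require_all_datasets: bool = True
    max_ratio: float = 2.0
    abs_slack: int = 1
    min_cluster_size: int | None = None  # defaults to the number of datasets

    def __post_init__(self):
        if self.max_ratio < 1:
            raise ValueError("max_ratio must be >= 1")
        if self.abs_slack < 0:
            raise ValueError("abs_slack must be >= 0")


def _is_balanced(counts: dict[str, int], datasets: tuple, params: BalanceParams) -> bool:
    vals = [counts.get(ds, 0) for ds in datasets]
    if params.require_all_datasets and any(v == 0 for v in vals):
        return False
    present = [v for v in vals if v > 0]
    if not present:
        return False
    min_size = params.min_cluster_size or len(datasets)
    if sum(present) < min_size:
        return False
    return max(present) <= params.max_ratio * min(present) + params.abs_slack


@dataclass
class TypeAssignment:
    """neuron -> type partition plus per-type per-dataset counts."""

    labels: dict  # neuron id -> type label (neurons absent = unassigned)
    unassigned: tuple = ()
    params: BalanceParams | None = None

    def counts(self, dataset_of: dict) -> pd.DataFrame:
        rows = [
            {"neuron": n, "type": t, "dataset": dataset_of[n]}
            for n, t in self.labels.items()
        ]
        if not rows:
            return pd.DataFrame()
        df = pd.DataFrame(rows)
        return df.pivot_table(
            index="type", columns="dataset", values="neuron", aggfunc="count", fill_value=0
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.labels.items()), columns=["neuron_id", "cell_type"]
        )
        un = pd.DataFrame({"neuron_id": sorted(self.unassigned), "cell_type": ""})
        return pd.concat([df, un], ignore_index=True)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def extract_balanced_clusters(
    dend: Dendrogram,
    dataset_of: dict,
    params: BalanceParams | None = None,
    label_prefix: str = "CT",
) -> TypeAssignment:
    """Extract the minimal antichain of balanced dendrogram nodes.

    Descending from the root: at a balanced node, descend only if *every*
    child subtree is itself balanced, otherwise emit the node as one
    cluster; at an unbalanced node, keep searching its children for
    balanced subtrees.  Leaves under subtrees that are never balanced are
    reported unassigned rather than forced into a cluster.  The descent
    rule makes the output a unique, pairwise-disjoint partition of the
    balanced region.
    """
    params = params or BalanceParams()
    datasets = tuple(sorted(set(dataset_of.values())))
    members = dend.members()
    n = dend.n_leaves
    Z = dend.linkage_matrix

    counts: dict[int, dict[str, int]] = {}
    for node, leaf_ids in members.items():
        c: dict[str, int] = {}
        for lid in leaf_ids:
            ds = dataset_of[lid]
            c[ds] = c.get(ds, 0) + 1
        counts[node] = c
    balanced = {node: _is_balanced(counts[node], datasets, params) for node in members}

    def children(node: int) -> tuple[int, int] | None:
        if node < n:
            return None
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        return a, b

    emitted: list[int] = []
    unassigned: list = []
    stack = [2 * n - 2] if n > 1 else [0]
    while stack:
        node = stack.pop()
        ch = children(node)
        if balanced[node]:
            if ch is not None and balanced[ch[0]] and balanced[ch[1]]:
                stack.extend(ch)
            else:
                emitted.append(node)
        else:
            if ch is None:
                unassigned.append(members[node][0])
            else:
                stack.extend(ch)

    # deterministic labels: order clusters by smallest lexicographic member id
    emitted.sort(key=lambda node: min(str(m) for m in members[node]))
    labels: dict = {}
    for i, node in enumerate(emitted, start=1):
        lab = f"{label_prefix}{i:04d}"
        for m in members[node]:
            labels[m] = lab
    return TypeAssignment(labels, tuple(unassigned), params)


def apply_overrides(assignment: TypeAssignment, overrides: dict) -> TypeAssignment:
    """Apply manual neuron -> type overrides after extraction."""
    labels = dict(assignment.labels)
    labels.update(overrides)
    unassigned = tuple(u for u in assignment.unassigned if u not in overrides)
    return TypeAssignment(labels, unassigned, assignment.params)


# ---------------------------------------------------------------------------
# Mapping classification
# ---------------------------------------------------------------------------


@dataclass
class TypeMapping:
    """Classification of how one typing maps onto another.

    Each connected component of the bipartite reference-type <-> new-type
    overlap graph is classed by its (ref, new) type counts: (1,1) 1:1,
    (1,>1) split, (>1,1) merge, (>1,>1) recombination.
    """

    components: list  # list of (ref_types, new_types, overlap counts dict)
    classes: dict  # ref type -> class string

    def class_fractions(self) -> pd.Series:
        s = pd.Series(self.classes)
        return s.value_counts(normalize=True).sort_index()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ref_types, new_types, overlaps in self.components:
            cls = _component_class(len(ref_types), len(new_types))
            for (r, t), cnt in sorted(overlaps.items()):
                rows.append(
                    {"ref_type": r, "new_type": t, "shared": cnt, "class": cls}
                )
        return pd.DataFrame(rows)


def _component_class(n_ref: int, n_new: int) -> str:
    if n_ref == 1 and n_new == 1:
        return "1:1"
    if n_ref == 1:
        return "split"
    if n_new == 1:
        return "merge"
    return "recombination"


def classify_mapping(reference: dict, new: dict) -> TypeMapping:
    """Classify the mapping between a reference and a new typing.

    Both arguments map neuron -> type; the comparison is restricted to the
    shared neuron universe.
    """
    universe = set(reference) & set(new)
    if not universe:
        raise ValueError("reference and new typing share no neurons")
    overlaps: dict[tuple, int] = {}
    for nrn in universe:
        key = (reference[nrn], new[nrn])
        overlaps[key] = overlaps.get(key, 0) + 1

    # union-find over ("r", ref type) / ("n", new type) nodes
    parent: dict = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for r, t in overlaps:
        union(("r", r), ("n", t))

    comp_nodes: dict = {}
    for x in list(parent):
        comp_nodes.setdefault(find(x), []).append(x)
    components = []
    classes: dict = {}
    for nodes in comp_nodes.values():
        refs = sorted(v for k, v in nodes if k == "r")
        news = sorted(v for k, v in nodes if k == "n")
        ov = {k: v for k, v in overlaps.items() if k[0] in refs}
        components.append((tuple(refs), tuple(news), ov))
        cls = _component_class(len(refs), len(news))
        for r in refs:
            classes[r] = cls
    components.sort(key=lambda c: c[0])
    return TypeMapping(components, classes)


# ---------------------------------------------------------------------------
# Persistent morphology groups
# ---------------------------------------------------------------------------


def persistent_groups(clusterings: list[dict]) -> dict:
    """Neuron groups that co-cluster consistently across clustering runs.

    ``clusterings`` are neuron -> cluster label maps from runs over
    overlapping neuron sets (e.g. one-, two- and three-hemisphere runs of
    an adaptive density clustering).  A neuron keeps a group label only if
    the member set of its cluster — restricted to the neurons shared by all
    runs — is identical in every run; the group is that member set.
    Neurons failing consistency get no label.
    """
    if len(clusterings) < 2:
        raise ValueError("need at least 2 clusterings")
    universe = set(clusterings[0])
    for c in clusterings[1:]:
        universe &= set(c)

    def coset(c: dict, nrn) -> frozenset:
        lab = c[nrn]
        return frozenset(m for m in universe if c[m] == lab)

    groups: dict = {}
    group_label: dict[frozenset, str] = {}
    for nrn in universe:
        sets = [coset(c, nrn) for c in clusterings]
        if all(s == sets[0] for s in sets[1:]):
            g = sets[0]
            if g not in group_label:
                group_label[g] = f"MG{len(group_label) + 1:04d}"
            groups[nrn] = group_label[g]
    # relabel deterministically by smallest member id
    order = sorted(group_label, key=lambda g: min(str(m) for m in g))
    remap = {group_label[g]: f"MG{i:04d}" for i, g in enumerate(order, start=1)}
    return {n: remap[lab] for n, lab in groups.items()}


# ---------------------------------------------------------------------------
# Model-style wrapper
# ---------------------------------------------------------------------------


class MultiConnectomeTyping:
    """Across-dataset typing model over a pooled distance matrix.

    Parameters
    ----------
    distance
        Pooled pairwise distances (connectivity, morphology or combined).
    dataset_of
        Leaf id -> dataset label.
    params
        Balance tolerance; defaults to max_ratio 2.0, abs_slack 1.
    """

    def __init__(
        self,
        distance: DistanceMatrix,
        dataset_of: dict,
        params: BalanceParams | None = None,
    ):
        self.distance = distance
        self.dataset_of = dict(dataset_of)
        self.params = params or BalanceParams()
        missing = [i for i in distance.ids if i not in self.dataset_of]
        if missing:
            raise ValueError(f"{len(missing)} neurons lack a dataset label")

    def fit(self, overrides: dict | None = None) -> "TypingResults":
        dend = ward_linkage(self.distance)
        assignment = extract_balanced_clusters(dend, self.dataset_of, self.params)
        if overrides:
            assignment = apply_overrides(assignment, overrides)
        return TypingResults(self, dend, assignment)


@dataclass
class TypingResults:
    """Fitted typing: dendrogram, assignment and diagnostics."""

    model: MultiConnectomeTyping
    dendrogram: Dendrogram
    assignment: TypeAssignment

    @property
    def n_types(self) -> int:
        return len(set(self.assignment.labels.values()))

    @property
    def n_unassigned(self) -> int:
        return len(self.assignment.unassigned)

    def counts(self) -> pd.DataFrame:
        return self.assignment.counts(self.model.dataset_of)

    def compare_to(self, reference: dict) -> TypeMapping:
        return classify_mapping(reference, self.assignment.labels)

    def summary(self) -> str:
        counts = self.counts()
        p = self.model.params
        lines = [
            "Multi-connectome typing",
            "=" * 46,
            f"neurons clustered     {len(self.assignment.labels):>8d}",
            f"neurons unassigned    {self.n_unassigned:>8d}",
            f"cell types            {self.n_types:>8d}",
            f"datasets              {counts.shape[1] if len(counts) else 0:>8d}",
            f"distance metric       {self.model.distance.metric:>8s}",
            f"balance max_ratio     {p.max_ratio:>8.2f}",
            f"balance abs_slack     {p.abs_slack:>8d}",
        ]
        if len(counts):
            sizes = counts.sum(axis=1)
            lines.append(f"median type size      {float(sizes.median()):>8.1f}")
        return "\n".join(lines)
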