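"""Core data types, file I/O and connectivity normalization.

The containers here are deliberately thin wrappers over pandas DataFrames:
an annotation table of :class:`NeuronRecord` rows, a directed synapse
:class:`EdgeTable`, and an SWC-backed :class:`Skeleton`.  All readers
validate on load and all writers emit deterministic row order so that
artifacts diff cleanly across runs.

Coordinates are micrometres throughout; the SWC reader accepts a scale
factor for nanometre-native files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SIDES",
    "FLOWS",
    "SUPERCLASSES",
    "DEFAULT_FLOW_OF_SUPERCLASS",
    "STATUS_FLAGS",
    "NeuronRecord",
    "AnnotationError",
    "EdgeTable",
    "Skeleton",
    "read_annotations",
    "write_annotations",
    "read_edges",
    "write_edges",
    "read_swc",
    "write_swc",
    "input_fraction",
    "budget_fraction",
    "type_edge_table",
]

SIDES = frozenset({"left", "right", "center", "na"})
FLOWS = frozenset({"afferent", "efferent", "intrinsic"})

#: The nine hierarchical superclasses plus the non-neuronal bucket.
SUPERCLASSES = frozenset(
    {
        "sensory",
        "motor",
        "endocrine",
        "ascending",
        "descending",
        "visual_projection",
        "visual_centrifugal",
        "optic_lobe_intrinsic",
        "central",
        "not_a_neuron",
    }
)

#: superclass -> set of admissible flows.  Overridable in read_annotations so
#: non-default taxonomies can be loaded.
DEFAULT_FLOW_OF_SUPERCLASS: dict[str, frozenset[str]] = {
    "sensory": frozenset({"afferent"}),
    "ascending": frozenset({"afferent"}),
    "motor": frozenset({"efferent"}),
    "descending": frozenset({"efferent"}),
    "endocrine": frozenset({"efferent"}),
    "visual_projection": frozenset({"intrinsic"}),
    "visual_centrifugal": frozenset({"intrinsic"}),
    "optic_lobe_intrinsic": frozenset({"intrinsic"}),
    "central": frozenset({"intrinsic"}),
    "not_a_neuron": FLOWS,
}

STATUS_FLAGS = frozenset({"outlier_bio", "outlier_seg"})

REQUIRED_ANNOTATION_COLUMNS = ("neuron_id", "dataset", "side", "flow", "superclass")
OPTIONAL_ANNOTATION_COLUMNS = (
    "class",
    "hemilineage",
    "morph_group",
    "cell_type",
    "hemibrain_type",
    "status",
)


class AnnotationError(ValueError):
    """Schema or row-level validation failure in an annotation table."""


@dataclass
class NeuronRecord:
    """One neuron's hierarchical annotations and dataset membership.

    The annotation hierarchy runs flow > superclass > class > cell type,
    with hemilineage as an orthogonal developmental grouping.  ``status``
    carries quality flags (``outlier_bio``, ``outlier_seg``) that downstream
    stereotypy analyses use to exclude neurons affected by sample or
    imaging artefacts.
    """

    neuron_id: str
    dataset: str
    side: str
    flow: str
    superclass: str
    cell_class: str | None = None
    hemilineage: str | None = None
    morph_group: str | None = None
    cell_type: str | None = None
    hemibrain_type: str | None = None
    status: frozenset[str] = frozenset()
    extra: dict[str, str] = field(default_factory=dict)

    def validate(self, flow_lookup: dict[str, frozenset[str]] | None = None) -> None:
        lookup = DEFAULT_FLOW_OF_SUPERCLASS if flow_lookup is None else flow_lookup
        if self.side not in SIDES:
            raise AnnotationError(f"invalid side {self.side!r} for {self.neuron_id}")
        if self.flow not in FLOWS:
            raise AnnotationError(f"invalid flow {self.flow!r} for {self.neuron_id}")
        if self.superclass not in SUPERCLASSES:
            raise AnnotationError(
                f"invalid superclass {self.superclass!r} for {self.neuron_id}"
            )
        allowed = lookup.get(self.superclass)
        if allowed is not None and self.flow not in allowed:
            raise AnnotationError(
                f"superclass {self.superclass!r} incompatible with flow "
                f"{self.flow!r} for {self.neuron_id}"
            )
        if self.side == "na" and self.flow != "afferent":
            raise AnnotationError(
                f"side 'na' only permitted for afferents ({self.neuron_id})"
            )
        unknown = self.status - STATUS_FLAGS
        if unknown:
            raise AnnotationError(
                f"unknown status flags {sorted(unknown)} for {self.neuron_id}"
            )


def read_annotations(
    path, flow_lookup: dict[str, frozenset[str]] | None = None
) -> list[NeuronRecord]:
    """Read a tab-separated annotation table into validated records.

    Unknown columns are preserved verbatim in ``record.extra``.  Raises
    :class:`AnnotationError` naming the column (schema) or the 1-based data
    row (value) on failure.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise AnnotationError(f"missing required column {col!r}")
    known = set(REQUIRED_ANNOTATION_COLUMNS) | set(OPTIONAL_ANNOTATION_COLUMNS)
    extra_cols = [c for c in df.columns if c not in known]

    records: list[NeuronRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        rowd = row.to_dict()
        status = frozenset(s for s in str(rowd.get("status", "")).split(",") if s)
        rec = NeuronRecord(
            neuron_id=rowd["neuron_id"],
            dataset=rowd["dataset"],
            side=rowd["side"],
            flow=rowd["flow"],
            superclass=rowd["superclass"],
            cell_class=rowd.get("class") or None,
            hemilineage=rowd.get("hemilineage") or None,
            morph_group=rowd.get("morph_group") or None,
            cell_type=rowd.get("cell_type") or None,
            hemibrain_type=rowd.get("hemibrain_type") or None,
            status=status,
            extra={c: rowd[c] for c in extra_cols},
        )
        try:
            rec.validate(flow_lookup)
        except AnnotationError as err:
            raise AnnotationError(f"row {i}: {err}") from None
        key = (rec.neuron_id, rec.dataset)
        if key in seen:
            raise AnnotationError(f"row {i}: duplicate (neuron_id, dataset) {key}")
        seen.add(key)
        records.append(rec)
    return records


def write_annotations(records: list[NeuronRecord], path) -> None:
    """Write records as a TSV, sorted by (dataset, neuron_id) for diffability."""
    extra_cols = sorted({k for r in records for k in r.extra})
    rows = []
    for r in sorted(records, key=lambda r: (r.dataset, r.neuron_id)):
        rows.append(
            {
                "neuron_id": r.neuron_id,
                "dataset": r.dataset,
                "side": r.side,
                "flow": r.flow,
                "superclass": r.superclass,
                "class": r.cell_class or "",
                "hemilineage": r.hemilineage or "",
                "morph_group": r.morph_group or "",
                "cell_type": r.cell_type or "",
                "hemibrain_type": r.hemibrain_type or "",
                "status": ",".join(sorted(r.status)),
                **{c: r.extra.get(c, "") for c in extra_cols},
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Edge tables
# ---------------------------------------------------------------------------


class EdgeTable:
    """Directed synapse-count edges, optionally tagged with a neuropil.

    An *edge* is the set of synaptic connections between two cells (or two
    cell types); its weight is the summed unitary synapse count with no
    threshold (>= 1).  Duplicate (pre, post, neuropil) rows are summed on
    construction, which conserves total synapse counts.
    """

    COLUMNS = ("pre_id", "post_id", "weight", "neuropil")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "neuropil" not in df.columns:
            df["neuropil"] = ""
        df["neuropil"] = df["neuropil"].fillna("").astype(str)
        missing = {"pre_id", "post_id", "weight"} - set(df.columns)
        if missing:
            raise ValueError(f"edge table missing columns {sorted(missing)}")
        if len(df):
            w = pd.to_numeric(df["weight"])
            if (w < 1).any():
                bad = df.loc[w < 1].iloc[0]
                raise ValueError(
                    f"edge weights must be >= 1 (got {bad['weight']!r} for "
                    f"{bad['pre_id']}->{bad['post_id']})"
                )
            if df["pre_id"].isna().any() or df["post_id"].isna().any():
                raise ValueError("null pre_id/post_id not allowed")
            df["weight"] = w.astype(np.int64)
        else:
            df["weight"] = df.get("weight", pd.Series(dtype=np.int64)).astype(np.int64)
        df["pre_id"] = df["pre_id"].astype(str)
        df["post_id"] = df["post_id"].astype(str)
        df = (
            df.groupby(["pre_id", "post_id", "neuropil"], as_index=False)["weight"]
            .sum()
            .sort_values(["pre_id", "post_id", "neuropil"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.df = df[list(self.COLUMNS)]

    @classmethod
    def from_records(cls, records) -> "EdgeTable":
        cols = ["pre_id", "post_id", "weight", "neuropil"]
        ncol = len(records[0]) if records else 4
        return cls(pd.DataFrame(records, columns=cols[:ncol]))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, EdgeTable) and self.df.equals(other.df)

    @property
    def total_weight(self) -> int:
        return int(self.df["weight"].sum())

    def neurons(self) -> set[str]:
        return set(self.df["pre_id"]) | set(self.df["post_id"])

    def collapse_neuropils(self) -> "EdgeTable":
        """Sum weights over neuropils, keeping one row per (pre, post)."""
        df = self.df.groupby(["pre_id", "post_id"], as_index=False)["weight"].sum()
        return EdgeTable(df)


def read_edges(path, on_dangling: str = "ignore", known_ids=None) -> EdgeTable:
    """Read an edge-list CSV (pre_id, post_id, weight[, neuropil]).

    ``on_dangling`` controls the policy for ids outside ``known_ids``
    ("ignore", "warn" or "error"); it is a no-op when ``known_ids`` is None.
    """
    df = pd.read_csv(path, dtype={"pre_id": str, "post_id": str})
    table = EdgeTable(df)
    if known_ids is not None and on_dangling != "ignore":
        dangling = table.neurons() - set(known_ids)
        if dangling:
            msg = f"{len(dangling)} edge endpoint ids not in annotation set"
            if on_dangling == "error":
                raise ValueError(msg)
            warnings.warn(msg)
    return table


def write_edges(table: EdgeTable, path) -> None:
    """Write an edge table as CSV in deterministic (pre, post, neuropil) order."""
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------


@dataclass
class Skeleton:
    """A neuron skeleton: an acyclic node/parent tree with µm coordinates.

    ``nodes`` has columns node_id, parent_id (-1 marks a root), x, y, z,
    radius.  Each connected component has exactly one root.
    """

    nodes: pd.DataFrame

    def __post_init__(self):
        df = self.nodes
        ids = df["node_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate node ids in skeleton")
        if not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise ValueError("non-finite coordinates in skeleton")
        idset = set(ids.tolist())
        parents = df["parent_id"].to_numpy()
        for nid, pid in zip(ids, parents):
            if pid == nid:
                raise ValueError(f"node {nid} is its own parent")
            if pid != -1 and pid not in idset:
                raise ValueError(f"node {nid} has dangling parent {pid}")
        # cycle check by walking to root from every node
        parent_of = dict(zip(ids.tolist(), parents.tolist()))
        state: dict[int, int] = {}
        for start in ids.tolist():
            path = []
            n = start
            while n != -1 and state.get(n, 0) == 0:
                state[n] = 1
                path.append(n)
                n = parent_of[n]
            if n != -1 and state.get(n) == 1:
                raise ValueError("cycle detected in skeleton")
            for p in path:
                state[p] = 2

    @property
    def roots(self) -> np.ndarray:
        return self.nodes.loc[self.nodes["parent_id"] == -1, "node_id"].to_numpy()

    @property
    def coords(self) -> np.ndarray:
        return self.nodes[["x", "y", "z"]].to_numpy(dtype=float)

    def cable_length(self) -> float:
        """Total cable length in µm (sum of parent-child segment lengths)."""
        df = self.nodes
        pos = df.set_index("node_id")[["x", "y", "z"]]
        child = df[df["parent_id"] != -1]
        if not len(child):
            return 0.0
        a = pos.loc[child["node_id"]].to_numpy()
        b = pos.loc[child["parent_id"]].to_numpy()
        return float(np.linalg.norm(a - b, axis=1).sum())

    def children_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {int(n): [] for n in self.nodes["node_id"]}
        for nid, pid in zip(self.nodes["node_id"], self.nodes["parent_id"]):
            if pid != -1:
                out[int(pid)].append(int(nid))
        return out


def read_swc(path, scale: float = 1.0) -> Skeleton:
    """Read an SWC v1 skeleton.  ``scale`` multiplies coordinates and radii
    (use 1e-3 for nm-native files to obtain µm)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["node_id", "struct", "x", "y", "z", "radius", "parent_id"],
    )
    if df.shape[1] != 7:
        raise ValueError("SWC file must have 7 columns")
    nodes = pd.DataFrame(
        {
            "node_id": df["node_id"].astype(np.int64),
            "parent_id": df["parent_id"].astype(np.int64),
            "x": df["x"] * scale,
            "y": df["y"] * scale,
            "z": df["z"] * scale,
            "radius": df["radius"] * scale,
        }
    )
    return Skeleton(nodes)


def write_swc(skel: Skeleton, path) -> None:
    df = skel.nodes.sort_values("node_id")
    with open(path, "w") as fh:
        fh.write("# node_id type x y z radius parent_id\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{int(row.node_id)} 0 {row.x:.6f} {row.y:.6f} {row.z:.6f} "
                f"{row.radius:.6f} {int(row.parent_id)}\n"
            )


# ---------------------------------------------------------------------------
# Connectivity normalization
# ---------------------------------------------------------------------------


def input_fraction(edges: EdgeTable, target) -> pd.Series:
    """Connection strength normalized to the target's total inputs.

    ``target`` is a neuron id or an iterable of ids treated as one unit
    (e.g. the members of a cell type).  Returns a Series indexed by pre_id
    with fractional weights in [0, 1] summing to 1.  A target with zero
    inputs yields an empty Series with a warning.

    Ten synapses onto a target receiving 200 inputs in total give 0.05.
    """
    targets = {target} if isinstance(target, str) else set(target)
    sub = edges.df[edges.df["post_id"].isin(targets)]
    total = sub["weight"].sum()
    if total == 0:
        warnings.warn(f"target {sorted(targets)} has no inputs; fractions undefined")
        return pd.Series(dtype=float)
    frac = sub.groupby("pre_id")["weight"].sum() / float(total)
    return frac.sort_index()


def budget_fraction(
    edges: EdgeTable,
    source,
    partition: dict[str, str],
    direction: str = "out",
    other_label: str = "other",
) -> pd.Series:
    """Fraction of a source's total synaptic budget spent per partner group.

    ``partition`` maps partner neuron ids to group labels; partners without
    a group are collected under ``other_label``.  ``direction`` selects the
    output budget ("out": source as presynaptic) or the input budget ("in").
    Fractions sum to 1.
    """
    if direction not in {"in", "out"}:
        raise ValueError("direction must be 'in' or 'out'")
    sources = {source} if isinstance(source, str) else set(source)
    df = edges.df
    if direction == "out":
        sub = df[df["pre_id"].isin(sources)]
        partner = sub["post_id"]
    else:
        sub = df[df["post_id"].isin(sources)]
        partner = sub["pre_id"]
    total = sub["weight"].sum()
    if total == 0:
        warnings.warn("empty synaptic budget; returning empty result")
        return pd.Series(dtype=float)
    groups = partner.map(lambda p: partition.get(p, other_label))
    frac = sub.groupby(groups.values)["weight"].sum() / float(total)
    frac.index.name = "group"
    return frac.sort_index()


def type_edge_table(
    edges: EdgeTable, assignment: dict[str, str]
) -> tuple[EdgeTable, dict]:
    """Aggregate a neuron-level edge table to the cell-type level.

    weight(A -> B) is the summed weight over all member pairs.  Edges
    touching untyped neurons are dropped, never silently: the returned
    report counts dropped edges and synapses.  Total synapses among typed
    neurons are conserved.
    """
    df = edges.df
    pre_t = df["pre_id"].map(assignment)
    post_t = df["post_id"].map(assignment)
    keep = pre_t.notna() & post_t.notna()
    dropped = df[~keep]
    typed = pd.DataFrame(
        {
            "pre_id": pre_t[keep],
            "post_id": post_t[keep],
            "weight": df.loc[keep, "weight"],
            "neuropil": df.loc[keep, "neuropil"],
        }
    )
    report = {
        "dropped_edges": int(len(dropped)),
        "dropped_synapses": int(dropped["weight"].sum()),
        "untyped_neurons": sorted(
            (set(df.loc[~keep, "pre_id"]) | set(df.loc[~keep, "post_id"]))
            - set(assignment)
        ),
    }
    if not len(typed):
        typed = pd.DataFrame(columns=["pre_id", "post_id", "weight", "neuropil"])
    return EdgeTable(typed), report
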