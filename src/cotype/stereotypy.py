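"""Edge-weight stereotypy statistics across hemispheres.

Given type-level edge tables from two or more hemispheres the functions
here match edges across datasets (outer join on the (pre type, post type)
pair), compute persistence curves — the probability that an edge seen at a
given weight in one dataset is present (weight >= 1) in the others —
weight-agreement correlations with quantile envelopes, per-type cell-count
stereotypy, and Cohen's d effect sizes for within- versus across-brain
similarity contrasts.

Normalized weight means the edge's input fraction of the postsynaptic
type's total inputs in its own dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EdgeTable

__all__ = [
    "EdgeComparison",
    "PersistenceCurve",
    "match_edges",
    "persistence_curve",
    "weight_agreement",
    "count_stereotypy",
    "cohens_d",
    "default_weight_bins",
]


@dataclass
class EdgeComparison:
    """Union of type-level edges across datasets with per-dataset weights.

    ``table`` is indexed by (pre_type, post_type) and has columns
    ``weight_<ds>`` (0 where absent) and ``norm_<ds>`` (input fraction of
    the postsynaptic type).
    """

    table: pd.DataFrame
    datasets: tuple[str, ...]

    def weights(self, ds: str) -> pd.Series:
        return self.table[f"weight_{ds}"]

    def norms(self, ds: str) -> pd.Series:
        return self.table[f"norm_{ds}"]


def match_edges(
    tables: dict[str, EdgeTable],
    exclude_types=None,
) -> EdgeComparison:
    """Outer-join type-level edge tables across datasets.

    ``exclude_types`` is a collection of type names or a predicate called
    on each type; edges touching an excluded type (e.g. types flagged
    'outlier_seg', or classes known to be truncated) are removed from every
    dataset before joining.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 datasets")
    if exclude_types is None:
        excluded = lambda t: False  # noqa: E731
    elif callable(exclude_types):
        excluded = exclude_types
    else:
        excl = set(exclude_types)
        excluded = lambda t: t in excl  # noqa: E731

    datasets = tuple(tables)
    namespaces = [
        set(t.df["pre_id"]) | set(t.df["post_id"]) for t in tables.values()
    ]
    if not set.intersection(*namespaces):
        raise ValueError("type namespaces of the datasets do not intersect")

    cols = {}
    for ds, table in tables.items():
        df = table.collapse_neuropils().df
        keep = ~(df["pre_id"].map(excluded) | df["post_id"].map(excluded))
        df = df[keep]
        w = df.set_index(["pre_id", "post_id"])["weight"]
        total_in = df.groupby("post_id")["weight"].sum()
        norm = w / w.index.get_level_values("post_id").map(total_in)
        cols[f"weight_{ds}"] = w
        cols[f"norm_{ds}"] = norm
    out = pd.DataFrame(cols).fillna(0.0)
    out.index.names = ["pre_type", "post_type"]
    for ds in datasets:
        out[f"weight_{ds}"] = out[f"weight_{ds}"].astype(np.int64)
    return EdgeComparison(out.sort_index(), datasets)


def default_weight_bins(max_int: int = 30, max_weight: float = 1e5) -> np.ndarray:
    """Integer bins for weights 1..max_int, logarithmic above."""
    log_edges = np.geomspace(max_int + 1, max_weight, 12)
    return np.concatenate([np.arange(1, max_int + 2), log_edges[1:]])


@dataclass
class PersistenceCurve:
    """Per-weight-bin probability that an edge is found in another dataset."""

    table: pd.DataFrame  # columns: bin_left, bin_right, probability, n
    measure: str
    mode: str

    def threshold_for(self, level: float):
        """Smallest bin lower edge at which persistence first reaches and
        then stays at or above ``level``; None if never reached."""
        t = self.table.dropna(subset=["probability"])
        ok = t["probability"].to_numpy() >= level
        # require all subsequent bins to also satisfy the level
        for i in range(len(ok)):
            if ok[i:].all():
                return float(t["bin_left"].iloc[i])
        return None


def persistence_curve(
    cmp: EdgeComparison,
    source: str,
    others: tuple[str, ...] | None = None,
    measure: str = "absolute",
    mode: str = "pairwise",
    bins: np.ndarray | None = None,
) -> PersistenceCurve:
    """P(edge present elsewhere) as a function of its weight in ``source``.

    ``mode='pairwise'`` requires presence in at least one other dataset;
    ``mode='all'`` in every other dataset.  Bins with no edges report a
    null probability, not 0.
    """
    others = tuple(d for d in cmp.datasets if d != source) if others is None else others
    if not others:
        raise ValueError("need at least one comparison dataset")
    if measure == "absolute":
        w = cmp.weights(source).to_numpy(dtype=float)
        edges = default_weight_bins() if bins is None else np.asarray(bins, dtype=float)
    elif measure == "normalized":
        w = cmp.norms(source).to_numpy(dtype=float)
        edges = (
            np.geomspace(1e-5, 1.0, 26) if bins is None else np.asarray(bins, dtype=float)
        )
    else:
        raise ValueError("measure must be 'absolute' or 'normalized'")

    present_other = np.column_stack(
        [cmp.weights(d).to_numpy() >= 1 for d in others]
    )
    hit = present_other.all(axis=1) if mode == "all" else present_other.any(axis=1)
    in_source = w > 0

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = in_source & (w >= lo) & (w < hi)
        n = int(sel.sum())
        prob = float(hit[sel].mean()) if n else np.nan
        rows.append({"bin_left": lo, "bin_right": hi, "probability": prob, "n": n})
    return PersistenceCurve(pd.DataFrame(rows), measure, mode)


def weight_agreement(
    cmp: EdgeComparison,
    a: str,
    b: str,
    quantiles: tuple[float, ...] = (0.05, 0.25, 0.75, 0.95),
    bins: np.ndarray | None = None,
) -> dict:
    """Correlation and per-weight envelopes of paired edge weights.

    Pearson R is computed on log10(w + 1) over edges present in both
    datasets.  Per source-weight bin, the mean and the requested quantiles
    of the partner weight are returned.
    """
    wa = cmp.weights(a).to_numpy(dtype=float)
    wb = cmp.weights(b).to_numpy(dtype=float)
    both = (wa > 0) & (wb > 0)
    if both.sum() < 10:
        raise ValueError("need at least 10 shared edges")
    la, lb = np.log10(wa[both] + 1), np.log10(wb[both] + 1)
    if la.std() == 0 or lb.std() == 0:
        warnings.warn("degenerate weight variance; correlation undefined")
        r = np.nan
    else:
        r = float(np.corrcoef(la, lb)[0, 1])

    edges = default_weight_bins() if bins is None else np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = both & (wa >= lo) & (wa < hi)
        n = int(sel.sum())
        row = {"bin_left": lo, "bin_right": hi, "n": n}
        if n:
            row["mean"] = float(wb[sel].mean())
            for q in quantiles:
                row[f"q{int(round(q * 100)):02d}"] = float(np.quantile(wb[sel], q))
        else:
            row["mean"] = np.nan
            for q in quantiles:
                row[f"q{int(round(q * 100)):02d}"] = np.nan
        rows.append(row)
    return {"pearson_r": r, "n_shared": int(both.sum()), "envelope": pd.DataFrame(rows)}


def count_stereotypy(counts: dict[str, dict[str, int]]) -> dict:
    """Per-type cell-count differences between datasets.

    ``counts`` maps dataset -> {type: n cells}.  Returns per-type signed
    and absolute differences for every dataset pair plus summary mean ± sd
    of the absolute differences and the share of singleton types.
    """
    datasets = sorted(counts)
    all_types = sorted(set().union(*[set(c) for c in counts.values()]))
    df = pd.DataFrame(
        {ds: [counts[ds].get(t, 0) for t in all_types] for ds in datasets},
        index=pd.Index(all_types, name="type"),
    )
    pairs = {}
    for i, a in enumerate(datasets):
        for b in datasets[i + 1:]:
            pairs[(a, b)] = df[b] - df[a]
    abs_all = np.concatenate([np.abs(v.to_numpy()) for v in pairs.values()])
    singleton_share = float((df.max(axis=1) == 1).mean())
    return {
        "per_type_counts": df,
        "signed_differences": pairs,
        "mean_abs_difference": float(abs_all.mean()),
        "sd_abs_difference": float(abs_all.std(ddof=1)) if len(abs_all) > 1 else 0.0,
        "singleton_share": singleton_share,
    }


def cohens_d(sample1, sample2) -> float:
    """Cohen's d with the pooled standard deviation:

        d = (mean1 - mean2) / s,
        s = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2))

    with s1^2, s2^2 the unbiased sample variances.  Undefined (NaN, with a
    warning) when the pooled variance is zero.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    s1, s2 = x1.var(ddof=1), x2.var(ddof=1)
    pooled = np.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        warnings.warn("zero pooled variance; Cohen's d undefined")
        return float("nan")
    return float((x1.mean() - x2.mean()) / pooled)
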