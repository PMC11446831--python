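"""Synthetic multi-hemisphere connectomes with planted cell types.

The generator emulates the study design the rest of the package is built
for: 2-3 hemispheres (two from one brain plus one from a second brain)
sharing a catalogue of planted cell types.  Each type has a morphology
prototype (a smoothed random-walk polyline; left-side neurons are exact
mirror images of the right prototype before jitter) and participates in a
heavy-tailed type-level connectivity backbone shared by all hemispheres.

Noise structure, applied per hemisphere:

1. cell-count jitter (per brain and per hemisphere, floored at 1 cell, so
   singleton types survive);
2. brain-level biological edge jitter (multiplicative lognormal with
   coefficient of variation ``bio_cv``) — hemispheres of the same brain
   share a biological realization, different brains do not;
3. multinomial splitting of each type-level weight across member neuron
   pairs;
4. technical noise: binomial thinning at the per-(hemisphere, neuropil)
   synaptic completion rate, false negatives at 1 - recall, and false
   positives added to hold the expected precision (allocated mostly
   proportionally to edge weight, with a small configurable share on
   random untrue pairs);
5. a per-hemisphere rigid registration offset on morphology (residual
   template-registration error shared by all neurons of one dataset);
6. optional axis-aligned truncation of morphology.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EdgeTable, NeuronRecord, Skeleton, write_annotations, write_edges, write_swc
from .morphology import to_dotprops
from ._seed import derive_seed

__all__ = ["SyntheticConfig", "GroundTruth", "generate", "make_kc_scenario"]

DEFAULT_DATASETS = (("a_left", "left"), ("a_right", "right"), ("b_right", "right"))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic connectome.

    Defaults model three hemispheres (one full brain plus a second brain's
    right side), 50 planted types with 2-8 cells each, lognormal type-level
    edge weights, per-hemisphere completion rates in 0.5-0.9 and synapse
    detection at precision 0.72 / recall 0.77.
    """

    datasets: tuple = DEFAULT_DATASETS
    n_types: int = 50
    cells_per_type: tuple = ("uniform", 2, 8)  # or ("geometric", p, minimum)
    count_jitter_within: float = 0.3  # sd, hemispheres of one brain
    count_jitter_across: float = 0.6  # sd, across brains
    n_neuropils: int = 5
    completion: dict | None = None  # dataset -> {neuropil: rate}; sampled if None
    completion_range: tuple[float, float] = (0.5, 0.9)
    precision: float = 0.72
    recall: float = 0.77
    edge_density: float = 0.15
    weight_mu: float = 3.5  # lognormal log-mean of type-level weights
    weight_sigma: float = 1.2
    bio_cv: float = 0.2
    point_jitter: float = 1.0  # µm, i.i.d. per neuron
    registration_sd: float = 1.0  # µm, shared rigid offset per dataset
    prototype_points: tuple[int, int] = (40, 80)
    prototype_step: float = 2.0  # µm per random-walk step
    mirror_plane: float = 0.0
    truncation_box: dict | None = None  # dataset -> ((lo, hi) per axis)
    fp_uniform_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.datasets) < 2:
            raise ValueError("need at least 2 datasets")
        for name, v in (("precision", self.precision), ("recall", self.recall)):
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.completion is not None:
            for ds, rates in self.completion.items():
                for npil, c in rates.items():
                    if not (0 < c <= 1):
                        raise ValueError(f"completion[{ds}][{npil}] must be in (0, 1]")
        if not (0 <= self.edge_density <= 1):
            raise ValueError("edge_density must be in [0, 1]")

    @property
    def neuropils(self) -> tuple[str, ...]:
        return tuple(f"np{i}" for i in range(self.n_neuropils))

    def brain_of(self, dataset: str) -> str:
        return dataset.split("_")[0]


@dataclass
class GroundTruth:
    """The generated connectome plus everything needed to score recovery."""

    config: SyntheticConfig
    type_of: dict  # dataset -> {neuron_id: type}
    annotations: list
    prototypes: dict  # type -> (n, 3) right-side polyline
    points: dict  # dataset -> {neuron_id: (n, 3) array}
    true_edges: EdgeTable  # type-level, neuropil-tagged, pre-noise
    brain_edges: dict  # brain -> type-level EdgeTable after biological jitter
    realized: dict  # dataset -> neuron-level EdgeTable after all noise
    completion: dict  # dataset -> {neuropil: rate}

    def dotprops(self, dataset: str, k: int = 5) -> dict:
        side = dict(self.config.datasets)[dataset]
        return {
            nid: to_dotprops(pts, k=k, neuron_id=nid, side=side)
            for nid, pts in self.points[dataset].items()
        }

    def type_labels(self) -> dict:
        """Pooled neuron -> planted type over all datasets (ids are unique)."""
        out = {}
        for mapping in self.type_of.values():
            out.update(mapping)
        return out

    def write(self, outdir) -> list[str]:
        """Emit annotation TSV, per-dataset edge CSVs, SWC skeletons and a
        ground-truth JSON.  Returns the relative paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        write_annotations(self.annotations, outdir / "annotations.tsv")
        written.append("annotations.tsv")
        for ds, table in sorted(self.realized.items()):
            path = outdir / f"edges_{ds}.csv"
            write_edges(table, path)
            written.append(path.name)
        skel_dir = outdir / "skeletons"
        skel_dir.mkdir(exist_ok=True)
        for ds in sorted(self.points):
            for nid, pts in sorted(self.points[ds].items()):
                n = len(pts)
                nodes = pd.DataFrame(
                    {
                        "node_id": np.arange(1, n + 1),
                        "parent_id": np.concatenate([[-1], np.arange(1, n)]),
                        "x": pts[:, 0],
                        "y": pts[:, 1],
                        "z": pts[:, 2],
                        "radius": np.full(n, 0.5),
                    }
                )
                write_swc(Skeleton(nodes), skel_dir / f"{nid}.swc")
        written.append("skeletons/")
        gt = {
            "type_of": self.type_of,
            "true_edges": self.true_edges.df.to_dict(orient="list"),
            "completion": self.completion,
            "seed": self.config.seed,
        }
        (outdir / "ground_truth.json").write_text(json.dumps(gt, sort_keys=True, indent=1))
        written.append("ground_truth.json")
        return written


def _base_counts(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.cells_per_type[0]
    if kind == "uniform":
        lo, hi = cfg.cells_per_type[1], cfg.cells_per_type[2]
        return rng.integers(lo, hi + 1, size=cfg.n_types)
    if kind == "geometric":
        p, minimum = cfg.cells_per_type[1], cfg.cells_per_type[2]
        return minimum - 1 + rng.geometric(p, size=cfg.n_types)
    raise ValueError(f"unknown cells_per_type spec {cfg.cells_per_type!r}")


def _prototype(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Smoothed random-walk polyline on the right side of the midline."""
    n = int(rng.integers(cfg.prototype_points[0], cfg.prototype_points[1] + 1))
    steps = rng.normal(scale=cfg.prototype_step, size=(n, 3))
    pts = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    for axis in range(3):
        pts[:, axis] = np.convolve(pts[:, axis], kernel, mode="same")
    origin = rng.uniform([20.0, -50.0, -50.0], [80.0, 50.0, 50.0])
    pts = pts - pts.mean(axis=0) + origin
    pts[:, 0] = np.abs(pts[:, 0] - cfg.mirror_plane) + cfg.mirror_plane + 1.0
    return pts


def _lognormal_factor(cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative lognormal jitter with mean exactly 1."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate(config: SyntheticConfig) -> GroundTruth:
    """Generate a multi-hemisphere connectome with planted ground truth."""
    cfg = config
    seed = cfg.seed
    types = [f"T{i:03d}" for i in range(cfg.n_types)]
    rng_types = np.random.default_rng(derive_seed(seed, "types"))

    base_counts = _base_counts(cfg, rng_types)
    prototypes = {t: _prototype(cfg, rng_types) for t in types}

    # type-level connectivity backbone shared by every hemisphere
    rng_edges = np.random.default_rng(derive_seed(seed, "true_edges"))
    rows = []
    for i, a in enumerate(types):
        for j, b in enumerate(types):
            if i == j or rng_edges.random() >= cfg.edge_density:
                continue
            w = max(1, int(round(rng_edges.lognormal(cfg.weight_mu, cfg.weight_sigma))))
            npil = cfg.neuropils[int(rng_edges.integers(cfg.n_neuropils))]
            rows.append((a, b, w, npil))
    if not rows:
        raise ValueError("edge_density too low: empty true edge table")
    true_edges = EdgeTable.from_records(rows)

    # completion rates
    if cfg.completion is not None:
        completion = {ds: dict(cfg.completion[ds]) for ds, _ in cfg.datasets}
    else:
        completion = {}
        for ds, _ in cfg.datasets:
            r = np.random.default_rng(derive_seed(seed, f"completion:{ds}"))
            completion[ds] = {
                npil: float(r.uniform(*cfg.completion_range)) for npil in cfg.neuropils
            }

    # brain-level biological jitter: hemispheres of one brain share it
    brains = sorted({cfg.brain_of(ds) for ds, _ in cfg.datasets})
    brain_edges = {}
    brain_counts = {}
    for brain in brains:
        r = np.random.default_rng(derive_seed(seed, f"bio:{brain}"))
        factors = _lognormal_factor(cfg.bio_cv, len(true_edges.df), r)
        w = np.maximum(
            1, np.round(true_edges.df["weight"].to_numpy() * factors)
        ).astype(np.int64)
        df = true_edges.df.copy()
        df["weight"] = w
        brain_edges[brain] = EdgeTable(df)
        jitter = r.normal(scale=cfg.count_jitter_across, size=cfg.n_types)
        brain_counts[brain] = np.maximum(1, np.round(base_counts + jitter)).astype(int)

    type_of: dict = {}
    points: dict = {}
    realized: dict = {}
    annotations: list[NeuronRecord] = []

    for ds, side in cfg.datasets:
        brain = cfg.brain_of(ds)
        r = np.random.default_rng(derive_seed(seed, f"dataset:{ds}"))
        # residual template-registration error: one rigid offset per dataset,
        # shared by all of its neurons (cross-dataset comparisons see it,
        # within-dataset ones do not)
        reg_offset = r.normal(scale=cfg.registration_sd, size=3)
        jitter = r.normal(scale=cfg.count_jitter_within, size=cfg.n_types)
        counts = np.maximum(1, np.round(brain_counts[brain] + jitter)).astype(int)

        members: dict[str, list[str]] = {}
        ds_types: dict[str, str] = {}
        ds_points: dict[str, np.ndarray] = {}
        serial = 0
        for t, c in zip(types, counts):
            members[t] = []
            proto = prototypes[t]
            if side == "left":
                proto = proto.copy()
                proto[:, 0] = 2.0 * cfg.mirror_plane - proto[:, 0]
            for _ in range(int(c)):
                nid = f"{ds}_n{serial:05d}"
                serial += 1
                members[t].append(nid)
                ds_types[nid] = t
                pts = proto + reg_offset + r.normal(scale=cfg.point_jitter, size=proto.shape)
                box = (cfg.truncation_box or {}).get(ds)
                if box is not None:
                    (x0, x1), (y0, y1), (z0, z1) = box
                    keep = (
                        (pts[:, 0] >= x0) & (pts[:, 0] <= x1)
                        & (pts[:, 1] >= y0) & (pts[:, 1] <= y1)
                        & (pts[:, 2] >= z0) & (pts[:, 2] <= z1)
                    )
                    if keep.sum() >= 2:
                        pts = pts[keep]
                ds_points[nid] = pts
                annotations.append(
                    NeuronRecord(
                        neuron_id=nid,
                        dataset=ds,
                        side=side,
                        flow="intrinsic",
                        superclass="central",
                        cell_type=t,
                    )
                )

        # neuron-level realization of the brain's type-level table
        pre_ids: list[str] = []
        post_ids: list[str] = []
        weights: list[int] = []
        npils: list[str] = []
        for row in brain_edges[brain].df.itertuples(index=False):
            pre_m, post_m = members[row.pre_id], members[row.post_id]
            npairs = len(pre_m) * len(post_m)
            split = r.multinomial(int(row.weight), np.full(npairs, 1.0 / npairs))
            nz = np.nonzero(split)[0]
            for k in nz:
                pre_ids.append(pre_m[k // len(post_m)])
                post_ids.append(post_m[k % len(post_m)])
                weights.append(int(split[k]))
                npils.append(row.neuropil)
        w = np.asarray(weights, dtype=np.int64)
        npil_arr = np.asarray(npils)

        # technical noise: completion thinning, false negatives, false positives
        rates = np.array([completion[ds][p] for p in npil_arr])
        w = r.binomial(w, rates)
        if cfg.recall < 1:
            w = r.binomial(w, cfg.recall)
        if cfg.precision < 1:
            tp = int(w.sum())
            n_fp = r.poisson(tp * (1.0 - cfg.precision) / cfg.precision)
            if n_fp > 0:
                n_rand = r.binomial(n_fp, cfg.fp_uniform_fraction)
                n_prop = n_fp - n_rand
                if n_prop > 0 and w.sum() > 0:
                    p = w / w.sum()
                    w = w + r.multinomial(n_prop, p)
                all_ids = sorted(ds_types)
                for _ in range(int(n_rand)):
                    pre_ids.append(all_ids[int(r.integers(len(all_ids)))])
                    post_ids.append(all_ids[int(r.integers(len(all_ids)))])
                    npil_arr = np.append(npil_arr, cfg.neuropils[int(r.integers(cfg.n_neuropils))])
                    w = np.append(w, 1)

        keep = w >= 1
        df = pd.DataFrame(
            {
                "pre_id": np.asarray(pre_ids)[keep],
                "post_id": np.asarray(post_ids)[keep],
                "weight": w[keep],
                "neuropil": npil_arr[keep],
            }
        )
        realized[ds] = EdgeTable(df) if len(df) else EdgeTable(
            pd.DataFrame(columns=["pre_id", "post_id", "weight", "neuropil"])
        )
        type_of[ds] = ds_types
        points[ds] = ds_points

    return GroundTruth(
        config=cfg,
        type_of=type_of,
        annotations=annotations,
        prototypes=prototypes,
        points=points,
        true_edges=true_edges,
        brain_edges=brain_edges,
        realized=realized,
        completion=completion,
    )


# ---------------------------------------------------------------------------
# Kenyon-cell scenario
# ---------------------------------------------------------------------------


def make_kc_scenario(
    M: int,
    N: int = 58,
    K: int = 6,
    apl_budget: int = 20000,
    seed: int = 0,
    mean_weight: float = 4.0,
    budget_total: int | None = None,
    n_groups: int = 2,
) -> dict:
    """Expansion-layer wiring: M KCs each sampling K of N input channels.

    Every KC receives input from exactly K distinct channels (uniform
    without replacement), each with weight >= 1; one global inhibitory
    source ('apl') spreads ``apl_budget`` synapses over all KCs.  Channel
    output budgets are fixed at ``budget_total / N`` total synapses, so
    calling again with 2M KCs and the same ``budget_total`` yields the
    doubled-population variant in which per-KC input halves while
    population-level budget fractions are conserved.

    Returns a dict with the edge table, the channel map (ALPN id ->
    glomerulus), the KC ids, a round-robin KC group map and the planted K.
    """
    if not (1 <= K <= N):
        raise ValueError("K must satisfy 1 <= K <= N")
    rng = np.random.default_rng(derive_seed(seed, "kc_scenario"))
    alpns = [f"alpn{j:02d}" for j in range(N)]
    channel_map = {a: f"g{j:02d}" for j, a in enumerate(alpns)}
    kcs = [f"kc{i:05d}" for i in range(M)]
    if budget_total is None:
        budget_total = int(M * K * mean_weight)

    picks = np.empty((M, K), dtype=int)
    for i in range(M):
        picks[i] = rng.choice(N, size=K, replace=False)

    rows = []
    per_channel_budget = budget_total // N
    for j, alpn in enumerate(alpns):
        targets = np.nonzero((picks == j).any(axis=1))[0]
        if len(targets) == 0:
            continue
        base = len(targets)  # one synapse per connection guarantees weight >= 1
        extra = max(per_channel_budget - base, 0)
        alloc = rng.multinomial(extra, np.full(len(targets), 1.0 / len(targets)))
        for t, add in zip(targets, alloc):
            rows.append((alpn, kcs[t], 1 + int(add), "MB"))

    apl_alloc = rng.multinomial(max(apl_budget - M, 0), np.full(M, 1.0 / M))
    for i, add in enumerate(apl_alloc):
        rows.append(("apl", kcs[i], 1 + int(add), "MB"))

    groups = {kc: f"kcgrp{i % n_groups}" for i, kc in enumerate(kcs)}
    return {
        "edges": EdgeTable.from_records(rows),
        "channel_map": channel_map,
        "kcs": kcs,
        "groups": groups,
        "K": K,
        "budget_total": budget_total,
    }
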