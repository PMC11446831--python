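"""End-to-end convenience pipeline over a synthetic ground truth.

Glues the stages together the way the CLI and the validation scripts use
them: pool dotprops (mirroring left onto right), compute NBLAST and cosine
connectivity distances, combine them 1:1, co-cluster, extract balanced
clusters and score the recovered typing against the planted one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .celltypes import BalanceParams, MultiConnectomeTyping, TypingResults, classify_mapping
from .connectivity import DistanceMatrix, build_profiles, combined_distances, cosine_distances
from .morphology import ScoreParams, distance_from_scores, mirror, nblast_allbyall
from .synthetic import GroundTruth

__all__ = ["pooled_distances", "recover_types", "RecoveryReport"]


def pooled_distances(
    gt: GroundTruth, score_params: ScoreParams | None = None
) -> dict[str, DistanceMatrix]:
    """Morphology, connectivity and combined distance matrices over the
    pooled neurons of a synthetic ground truth (rows keyed by
    (dataset, neuron_id), identical ordering across the three)."""
    cfg = gt.config
    dps, order = [], []
    for ds, _side in cfg.datasets:
        dd = gt.dotprops(ds)
        for nid in sorted(dd):
            dp = dd[nid]
            if dp.side == "left":
                dp = mirror(dp, cfg.mirror_plane)
            dps.append(dp)
            order.append((ds, nid))
    scores = nblast_allbyall(dps, score_params or ScoreParams())
    morph = DistanceMatrix(
        distance_from_scores(scores).to_numpy(), tuple(order), "nblast"
    )
    prof = build_profiles(
        gt.realized, gt.type_of, {ds: sorted(gt.type_of[ds]) for ds in gt.type_of}
    )
    prof.matrix = prof.matrix.loc[order]
    conn = cosine_distances(prof)
    return {
        "morphology": morph,
        "connectivity": conn,
        "combined": combined_distances(conn, morph),
    }


@dataclass
class RecoveryReport:
    """Recovered typing scored against the planted ground truth."""

    results: TypingResults
    ari: float
    fraction_one_to_one: float
    n_types_recovered: int
    n_unassigned: int


def recover_types(
    gt: GroundTruth,
    distance: str = "combined",
    params: BalanceParams | None = None,
) -> RecoveryReport:
    """Run the full co-clustering pipeline and score planted-type recovery.

    ARI is the Adjusted Rand Index between recovered and planted labels
    over all pooled neurons (unassigned neurons count as singletons);
    ``fraction_one_to_one`` is the share of planted types whose overlap
    component with the recovered typing is 1:1.
    """
    from sklearn.metrics import adjusted_rand_score

    dmats = pooled_distances(gt)
    dm = dmats[distance]
    dataset_of = {key: key[0] for key in dm.ids}
    results = MultiConnectomeTyping(dm, dataset_of, params).fit()
    planted = {key: gt.type_of[key[0]][key[1]] for key in dm.ids}
    labels = dict(results.assignment.labels)
    for i, u in enumerate(results.assignment.unassigned):
        labels[u] = f"__unassigned{i}"
    ari = adjusted_rand_score(
        [planted[k] for k in dm.ids], [labels[k] for k in dm.ids]
    )
    mapping = classify_mapping(planted, labels)
    frac = float(mapping.class_fractions().get("1:1", 0.0))
    return RecoveryReport(
        results=results,
        ari=float(ari),
        fraction_one_to_one=frac,
        n_types_recovered=results.n_types,
        n_unassigned=results.n_unassigned,
    )
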