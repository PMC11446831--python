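"""Ward co-clustering, balanced-cluster extraction, mapping classes and
persistent groups — each backed by an independent brute-force oracle."""

import numpy as np
import pytest

from cotype.celltypes import (
    BalanceParams,
    Dendrogram,
    MultiConnectomeTyping,
    _is_balanced,
    classify_mapping,
    extract_balanced_clusters,
    persistent_groups,
    ward_linkage,
)
from cotype.connectivity import DistanceMatrix


# ---------------------------------------------------------------------------
# Ward linkage
# ---------------------------------------------------------------------------


def _lance_williams_ward(D: np.ndarray) -> np.ndarray:
    """Reference Ward linkage via the explicit Lance-Williams recurrence."""
    n = len(D)
    d = D.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    index = {i: i for i in range(n)}  # cluster id -> row in d
    rows = []
    coords = {i: i for i in range(n)}
    cur = d.copy()
    ids = list(range(n))
    Z = []
    next_id = n
    dist = {frozenset((i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    while len(active) > 1:
        best = min(
            (pair for pair in dist if pair <= active),
            key=lambda p: (dist[p], tuple(sorted(p))),
        )
        i, j = sorted(best)
        h = dist[best]
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in list(active):
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            dij = h
            # Ward update on distances (scipy convention: Euclidean-like)
            val = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            dist[frozenset((new, k))] = val
        active -= {i, j}
        active.add(new)
        sizes[new] = ni + nj
        Z.append([i, j, h, ni + nj])
    return np.array(Z)


class TestWardLinkage:
    def test_coincident_points_merge_first_at_zero(self):
        D = np.array(
            [[0.0, 0.0, 5.0], [0.0, 0.0, 5.0], [5.0, 5.0, 0.0]]
        )
        dend = ward_linkage(DistanceMatrix(D, ("a", "b", "c"), "cosine"))
        assert dend.linkage_matrix[0, 2] == 0.0
        assert set(dend.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_two_leaves_single_merge(self):
        D = np.array([[0.0, 3.7], [3.7, 0.0]])
        dend = ward_linkage(DistanceMatrix(D, ("a", "b"), "cosine"))
        assert dend.linkage_matrix.shape == (1, 4)
        assert dend.linkage_matrix[0, 2] == pytest.approx(3.7)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_lance_williams_reference(self, seed):
        rng = np.random.default_rng(seed)
        v = np.abs(rng.normal(size=(10, 10)))
        D = (v + v.T) / 2
        np.fill_diagonal(D, 0.0)
        dend = ward_linkage(DistanceMatrix(D, tuple(range(10)), "cosine"))
        ref = _lance_williams_ward(D)
        assert np.allclose(dend.linkage_matrix[:, 2], ref[:, 2], atol=1e-8)

    def test_nan_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ward_linkage(D)


# ---------------------------------------------------------------------------
# Balanced extraction
# ---------------------------------------------------------------------------


def _random_dendrogram(rng, n_leaves: int) -> Dendrogram:
    """Random binary merge tree with increasing heights."""
    heights = np.sort(rng.uniform(0.1, 10.0, size=n_leaves - 1))
    active = list(range(n_leaves))
    Z = []
    next_id = n_leaves
    sizes = {i: 1 for i in range(n_leaves)}
    for h in heights:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        Z.append([a, b, h, sizes[a] + sizes[b]])
        sizes[next_id] = sizes[a] + sizes[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(np.array(Z, dtype=float), tuple(f"L{i}" for i in range(n_leaves)))


def _oracle_emitted(dend: Dendrogram, dataset_of, params) -> list[frozenset]:
    """Independent characterization of the extraction output.

    A node v is emitted iff (a) v is balanced; (b) v is a leaf or has an
    unbalanced child; and (c) every strict ancestor a of v is either
    unbalanced (search mode descends) or has all children balanced
    (balanced descent is allowed).
    """
    n = dend.n_leaves
    Z = dend.linkage_matrix
    members = dend.members()
    datasets = tuple(sorted(set(dataset_of.values())))

    def balanced(node):
        c = {}
        for leaf in members[node]:
            c[dataset_of[leaf]] = c.get(dataset_of[leaf], 0) + 1
        return _is_balanced(c, datasets, params)

    parent = {}
    children = {}
    for i, (a, b, _, _) in enumerate(Z):
        children[n + i] = (int(a), int(b))
        parent[int(a)] = n + i
        parent[int(b)] = n + i

    out = []
    for v in members:
        if not balanced(v):
            continue
        ch = children.get(v)
        if ch is not None and balanced(ch[0]) and balanced(ch[1]):
            continue
        ok = True
        a = parent.get(v)
        while a is not None:
            if balanced(a):
                ca, cb = children[a]
                if not (balanced(ca) and balanced(cb)):
                    ok = False
                    break
            a = parent.get(a)
        if ok:
            out.append(frozenset(members[v]))
    return out


class TestBalancedExtraction:
    def _dataset_of(self, labels):
        return {f"L{i}": ds for i, ds in enumerate(labels)}

    def test_two_tight_triples_give_two_types(self):
        # leaves 0-2 = one neuron per dataset, leaves 3-5 likewise
        Z = np.array(
            [
                [0, 1, 0.1, 2], [6, 2, 0.2, 3],
                [3, 4, 0.3, 2], [8, 5, 0.4, 3],
                [7, 9, 5.0, 6],
            ]
        )
        dend = Dendrogram(Z, tuple(f"L{i}" for i in range(6)))
        asg = extract_balanced_clusters(
            dend, self._dataset_of(["d1", "d2", "d3"] * 2)
        )
        groups = {}
        for nrn, t in asg.labels.items():
            groups.setdefault(t, set()).add(nrn)
        assert sorted(map(sorted, groups.values())) == [
            ["L0", "L1", "L2"], ["L3", "L4", "L5"]
        ]

    def test_missing_dataset_merges_upward(self):
        # leaves 0-5: subtree {0,1,2,3} has datasets d1 d1 d2 d2 (no d3);
        # only with leaves 4 (d3) and 5 (d3) does it balance
        Z = np.array(
            [
                [0, 1, 0.1, 2], [2, 3, 0.2, 2], [6, 7, 0.3, 4],
                [4, 5, 0.4, 2], [8, 9, 1.0, 6],
            ]
        )
        dend = Dendrogram(Z, tuple(f"L{i}" for i in range(6)))
        asg = extract_balanced_clusters(
            dend, self._dataset_of(["d1", "d1", "d2", "d2", "d3", "d3"])
        )
        assert len(set(asg.labels.values())) == 1
        assert len(asg.labels) == 6

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_antichain_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        dend = _random_dendrogram(rng, n)
        datasets = ["d1", "d2", "d3"][: int(rng.integers(2, 4))]
        dataset_of = {f"L{i}": datasets[int(rng.integers(len(datasets)))] for i in range(n)}
        params = BalanceParams()
        asg = extract_balanced_clusters(dend, dataset_of, params)
        got = set()
        bylab = {}
        for nrn, lab in asg.labels.items():
            bylab.setdefault(lab, set()).add(nrn)
        got = {frozenset(v) for v in bylab.values()}
        expected = set(_oracle_emitted(dend, dataset_of, params))
        assert got == expected
        # unassigned leaves are exactly those not covered
        covered = set().union(*got) if got else set()
        assert set(asg.unassigned) == set(dataset_of) - covered

    def test_emitted_clusters_satisfy_balance_predicate(self):
        rng = np.random.default_rng(99)
        dend = _random_dendrogram(rng, 14)
        dataset_of = {f"L{i}": ["d1", "d2", "d3"][i % 3] for i in range(14)}
        params = BalanceParams()
        asg = extract_balanced_clusters(dend, dataset_of, params)
        datasets = ("d1", "d2", "d3")
        bylab = {}
        for nrn, lab in asg.labels.items():
            bylab.setdefault(lab, []).append(nrn)
        for membs in bylab.values():
            counts = {}
            for m in membs:
                counts[dataset_of[m]] = counts.get(dataset_of[m], 0) + 1
            assert _is_balanced(counts, datasets, params)


# ---------------------------------------------------------------------------
# Mapping classification
# ---------------------------------------------------------------------------


def _oracle_classes(reference, new):
    """Brute-force component analysis over the bipartite overlap graph."""
    universe = set(reference) & set(new)
    edges = {(reference[n], new[n]) for n in universe}
    refs = {r for r, _ in edges}
    classes = {}
    # BFS over the bipartite graph
    seen_r, seen_n = set(), set()
    for r0 in sorted(refs):
        if r0 in seen_r:
            continue
        comp_r, comp_n = {r0}, set()
        frontier = {("r", r0)}
        while frontier:
            kind, x = frontier.pop()
            if kind == "r":
                for (r, t) in edges:
                    if r == x and t not in comp_n:
                        comp_n.add(t)
                        frontier.add(("n", t))
            else:
                for (r, t) in edges:
                    if t == x and r not in comp_r:
                        comp_r.add(r)
                        frontier.add(("r", r))
        seen_r |= comp_r
        if len(comp_r) == 1 and len(comp_n) == 1:
            cls = "1:1"
        elif len(comp_r) == 1:
            cls = "split"
        elif len(comp_n) == 1:
            cls = "merge"
        else:
            cls = "recombination"
        for r in comp_r:
            classes[r] = cls
    return classes


class TestClassifyMapping:
    def test_split_definition(self):
        ref = {1: "X", 2: "X"}
        new = {1: "Y", 2: "Z"}
        assert classify_mapping(ref, new).classes["X"] == "split"

    def test_merge_definition(self):
        ref = {1: "X", 2: "Y"}
        new = {1: "Z", 2: "Z"}
        m = classify_mapping(ref, new)
        assert m.classes["X"] == "merge" and m.classes["Y"] == "merge"

    def test_disjoint_universes_rejected(self):
        with pytest.raises(ValueError, match="share no neurons"):
            classify_mapping({1: "X"}, {2: "Y"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_component_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        ref = {i: f"R{rng.integers(8)}" for i in range(n)}
        new = {i: f"N{rng.integers(8)}" for i in range(n)}
        assert classify_mapping(ref, new).classes == _oracle_classes(ref, new)


# ---------------------------------------------------------------------------
# Persistent groups
# ---------------------------------------------------------------------------


def _oracle_persistent(clusterings):
    """Meet of partitions, restricted to cells whose cluster member set
    (within the common universe) is identical in every run."""
    universe = set(clusterings[0])
    for c in clusterings[1:]:
        universe &= set(c)
    consistent = {}
    for n in universe:
        sets = []
        for c in clusterings:
            sets.append(frozenset(m for m in universe if c[m] == c[n]))
        if all(s == sets[0] for s in sets):
            consistent[n] = sets[0]
    return consistent


class TestPersistentGroups:
    def test_identical_clusterings_return_clusters(self):
        c = {"a": 1, "b": 1, "c": 2}
        groups = persistent_groups([c, dict(c)])
        assert groups.keys() == c.keys()
        assert groups["a"] == groups["b"] != groups["c"]

    def test_inconsistent_partner_loses_label(self):
        run1 = {"a": 1, "b": 1, "c": 2}
        run2 = {"a": 1, "b": 2, "c": 1}  # a now with c, not b
        groups = persistent_groups([run1, run2])
        assert "a" not in groups and "b" not in groups and "c" not in groups

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_meet_of_partitions_oracle(self, seed):
        rng = np.random.default_rng(seed)
        neurons = [f"n{i}" for i in range(30)]
        runs = []
        for _ in range(3):
            subset = [n for n in neurons if rng.random() > 0.1]
            runs.append({n: int(rng.integers(5)) for n in subset})
        groups = persistent_groups(runs)
        oracle = _oracle_persistent(runs)
        assert set(groups) == set(oracle)
        # same grouping structure: equal labels iff equal member sets
        for a in groups:
            for b in groups:
                assert (groups[a] == groups[b]) == (oracle[a] == oracle[b])


# ---------------------------------------------------------------------------
# Model front end
# ---------------------------------------------------------------------------


class TestMultiConnectomeTyping:
    def test_fit_and_summary(self, rng):
        n = 12
        centers = np.repeat(np.arange(4) * 100.0, 3)
        vals = np.abs(centers[:, None] - centers[None, :]) + rng.uniform(0, 1, (n, n))
        D = (vals + vals.T) / 2
        np.fill_diagonal(D, 0)
        ids = tuple(f"x{i}" for i in range(n))
        dm = DistanceMatrix(D, ids, "cosine")
        dataset_of = {f"x{i}": ["d1", "d2", "d3"][i % 3] for i in range(n)}
        res = MultiConnectomeTyping(dm, dataset_of).fit()
        assert res.n_types == 4
        assert "cell types" in res.summary()
        counts = res.counts()
        assert (counts.to_numpy() == 1).all()

    def test_missing_dataset_label_rejected(self):
        dm = DistanceMatrix(np.zeros((2, 2)), ("a", "b"), "cosine")
        with pytest.raises(ValueError, match="lack a dataset"):
            MultiConnectomeTyping(dm, {"a": "d1"})
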