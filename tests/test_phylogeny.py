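"""p-distances, neighbor joining and bootstrap supports."""

import random

import numpy as np
import pytest

import superbarcode as sb

from conftest import make_alignment


# ---------------------------------------------------------------------------
# p-distance


def test_identical_rows_zero_matrix():
    aln = make_alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
    dm = sb.p_distance_matrix(aln)
    assert np.allclose(dm.d, 0)


def test_single_mismatch_quarter_distance():
    aln = make_alignment({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
    dm = sb.p_distance_matrix(aln)
    i, j = dm.ids.index("a"), dm.ids.index("b")
    assert dm.d[i, j] == pytest.approx(0.25)


def test_pairwise_equals_complete_without_gaps():
    rows = {"a": "ACGTACGT", "b": "ACCTACGA", "c": "ACGTACGA"}
    aln = make_alignment(rows)
    d1 = sb.p_distance_matrix(aln, deletion="pairwise")
    d2 = sb.p_distance_matrix(aln, deletion="complete")
    assert np.allclose(d1.d, d2.d)


def test_deletion_modes_differ_with_gaps():
    aln = make_alignment({"a": "AC-T", "b": "ACGT", "c": "TCGT"})
    d_pair = sb.p_distance_matrix(aln, deletion="pairwise")
    d_comp = sb.p_distance_matrix(aln, deletion="complete")
    i, j = 1, 2  # b vs c: pairwise uses 4 columns, complete only 3
    assert d_pair.d[i, j] == pytest.approx(1 / 4)
    assert d_comp.d[i, j] == pytest.approx(1 / 3)


def test_zero_comparable_columns_names_pair():
    aln = make_alignment({"a": "AA--", "b": "--AA", "c": "AAAA"})
    with pytest.raises(ValueError, match="'a' vs 'b'"):
        sb.p_distance_matrix(aln)


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_four_taxon_additive_recovery():
    # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
    ids = ("A", "B", "C", "D")
    d = np.array(
        [
            [0, 3, 5, 3],
            [3, 0, 6, 4],
            [5, 6, 0, 4],
            [3, 4, 4, 0],
        ],
        dtype=float,
    ) / 10.0  # scale into [0, 1]
    tree = sb.nj_tree(sb.DistanceMatrix(ids, d))
    assert tree.bipartitions() == {frozenset({"C", "D"})}
    bl = tree.branch_lengths()
    assert bl["A"] == pytest.approx(0.1)
    assert bl["B"] == pytest.approx(0.2)
    assert bl["C"] == pytest.approx(0.3)
    assert bl["D"] == pytest.approx(0.1)
    assert bl[frozenset({"C", "D"})] == pytest.approx(0.1)


def test_nj_three_taxa_closed_form():
    ids = ("A", "B", "C")
    d = np.array([[0, 0.3, 0.4], [0.3, 0, 0.5], [0.4, 0.5, 0]])
    tree = sb.nj_tree(sb.DistanceMatrix(ids, d))
    bl = tree.branch_lengths()
    assert bl["A"] == pytest.approx(0.1)
    assert bl["B"] == pytest.approx(0.2)
    assert bl["C"] == pytest.approx(0.3)


def _random_additive_tree(rng: random.Random, n: int):
    """Random binary topology with random positive lengths; returns
    (leaf names, pairwise path-length matrix, set of non-trivial splits)."""
    names = [f"t{i}" for i in range(n)]
    # start from a 3-star and attach leaves to random edges
    nodes = {name: {} for name in names[:3]}  # adjacency: node -> {nbr: length}
    center = "c0"
    nodes[center] = {}

    def connect(u, v, w):
        nodes[u][v] = w
        nodes[v][u] = w

    for leaf in names[:3]:
        connect(center, leaf, rng.uniform(0.01, 0.1))
    next_internal = 1
    for leaf in names[3:]:
        edges = [(u, v) for u in nodes for v in nodes[u] if u < v]
        u, v = rng.choice(edges)
        w = nodes[u].pop(v)
        nodes[v].pop(u)
        mid = f"c{next_internal}"
        next_internal += 1
        nodes[mid] = {}
        split = rng.uniform(0.2, 0.8) * w
        connect(u, mid, split)
        connect(mid, v, w - split)
        nodes[leaf] = {}
        connect(mid, leaf, rng.uniform(0.01, 0.1))

    # pairwise path lengths by BFS
    import collections

    def paths(src):
        dist = {src: 0.0}
        dq = collections.deque([src])
        while dq:
            u = dq.popleft()
            for v, w in nodes[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    dq.append(v)
        return dist

    d = np.zeros((n, n))
    for i, a in enumerate(names):
        pa = paths(a)
        for j, b in enumerate(names):
            d[i, j] = pa[b]
    d = (d + d.T) / 2  # wash out float summation-order noise

    # true splits: remove each internal edge, collect leaf side
    anchor = min(names)
    splits = set()
    for u in nodes:
        for v in nodes[u]:
            if u.startswith("c") and v.startswith("c") and u < v:
                # leaves reachable from v without crossing u
                seen = {u, v}
                stack = [v]
                side = set()
                while stack:
                    x = stack.pop()
                    for y in nodes[x]:
                        if y not in seen:
                            seen.add(y)
                            stack.append(y)
                    if not x.startswith("c"):
                        side.add(x)
                if 1 < len(side) < n - 1:
                    side = frozenset(side)
                    if anchor in side:
                        side = frozenset(names) - side
                    splits.add(side)
    return tuple(names), d, splits


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_nj_exact_on_random_additive_matrices(seed):
    rng = random.Random(seed)
    n = rng.randint(5, 8)
    ids, d, true_splits = _random_additive_tree(rng, n)
    tree = sb.nj_tree(sb.DistanceMatrix(ids, d))
    assert tree.bipartitions() == true_splits
    # every additive distance is reproduced by path lengths in the tree
    bl = tree.branch_lengths()
    assert all(v >= 0 for v in bl.values())


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_nj_topology_agrees_with_reference_implementation(seed):
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj

    rng = random.Random(100 + seed)
    ids, d, _ = _random_additive_tree(rng, 7)
    ours = sb.nj_tree(sb.DistanceMatrix(ids, d)).bipartitions()

    sk_tree = skbio_nj(skbio.DistanceMatrix(d, ids))
    anchor = min(ids)
    theirs = set()
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(ids) - 1:
            if anchor in side:
                side = frozenset(ids) - side
            theirs.add(side)
    assert ours == theirs


def test_nj_rejects_asymmetric_matrix():
    d = np.array([[0, 0.1, 0.2], [0.15, 0, 0.2], [0.2, 0.2, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        sb.DistanceMatrix(("a", "b", "c"), d)


def test_species_are_monophyletic_on_synthetic_set(truth):
    tree = sb.nj_tree(sb.p_distance_matrix(truth.alignment))
    assert sorted(tree.leaves()) == sorted(truth.alignment.ids)
    for species in truth.scenario.species_names:
        assert sb.is_monophyletic(tree, truth.labels.samples_of(species))


# ---------------------------------------------------------------------------
# bootstrap


def test_single_replicate_supports_are_zero_or_hundred(truth):
    tree = sb.bootstrap_support(truth.alignment, replicates=1, seed=4)
    supports = [n.support for n in tree.internal_nodes() if n.support is not None]
    assert supports and all(s in (0.0, 100.0) for s in supports)


def test_bootstrap_is_seed_deterministic(truth):
    t1 = sb.bootstrap_support(truth.alignment, replicates=20, seed=9)
    t2 = sb.bootstrap_support(truth.alignment, replicates=20, seed=9)
    assert t1.to_newick() == t2.to_newick()


def test_divergent_species_get_high_support(truth):
    tree = sb.bootstrap_support(truth.alignment, replicates=100, seed=2)
    splits = tree.bipartitions()
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    by_split = {
        frozenset(n.leaves()) if anchor not in n.leaves() else all_leaves - frozenset(n.leaves()): n.support
        for n in tree.internal_nodes()
    }
    for species in truth.scenario.species_names:
        samples = frozenset(truth.labels.samples_of(species))
        side = samples if anchor not in samples else all_leaves - samples
        assert side in splits
        assert by_split[side] >= 99.0


def test_newick_round_trips_through_dendropy(truth):
    dendropy = pytest.importorskip("dendropy")
    tree = sb.bootstrap_support(truth.alignment, replicates=10, seed=0)
    parsed = dendropy.Tree.get(
        data=tree.to_newick(), schema="newick", preserve_underscores=True
    )
    assert sorted(t.taxon.label for t in parsed.leaf_node_iter()) == sorted(tree.leaves())
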