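import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from organphylo.align_dist import Alignment, DistanceMatrix, p_distance
from organphylo.phylo import (
    ExhaustiveMP,
    Tree,
    bootstrap_support,
    enumerate_topologies,
    fitch_score,
    matrix_euclidean,
    mp_bootstrap,
    mp_search,
    nested_to_tree,
    nj_tree,
    patristic_matrix,
    rf_distance,
    root_with_outgroup,
)

from conftest import random_dna


# -- independent Fitch oracle: exhaustive internal labelings -------------------

def _edges_of_nested(top, n):
    """(edge list, n_internal) for a rooted-at-leaf-0 nested topology."""
    edges = []
    next_id = [n]

    def rec(node):
        if isinstance(node, int):
            return node
        me = next_id[0]
        next_id[0] += 1
        for child in node:
            edges.append((me, rec(child)))
        return me

    top_id = rec(top)
    edges.append((0, top_id))
    return edges, next_id[0] - n


def _brute_min_changes(top, column, n):
    """Minimum substitutions for one column by enumerating all internal (and
    missing-leaf) base assignments."""
    edges, n_internal = _edges_of_nested(top, n)
    free = [n + i for i in range(n_internal)]
    fixed = {}
    for i, ch in enumerate(column):
        if ch in "ACGT":
            fixed[i] = ch
        else:
            free.append(i)  # missing: free to take any base
    best = np.inf
    for combo in itertools.product("ACGT", repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        cost = sum(assign[a] != assign[b] for a, b in edges)
        best = min(best, cost)
    return int(best)


def random_tree(rng, labels):
    """Random binary unrooted topology with random positive branch lengths."""
    tops = enumerate_topologies(len(labels))
    top = tops[int(rng.integers(len(tops)))]
    tree = nested_to_tree(top, labels)

    def set_lengths(node):
        for c in node.children:
            c.length = float(rng.uniform(0.05, 0.5))
            set_lengths(c)

    set_lengths(tree.root)
    return tree


# -- NJ -------------------------------------------------------------------------

def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]))
    t = nj_tree(dm)
    bl = t.branch_lengths()
    assert bl["a"] == pytest.approx(0.1)
    assert bl["b"] == pytest.approx(0.1)
    assert bl["c"] == pytest.approx(0.3)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((a:0.1,b:0.2):0.05,c:0.3,d:0.15) -> additive matrix
    nwk = "((a:0.1,b:0.2):0.05,c:0.3,d:0.15);"
    truth = Tree.from_newick(nwk)
    dm = patristic_matrix(truth)
    t = nj_tree(dm)
    assert rf_distance(t, truth) == 0
    back = patristic_matrix(t)
    order = sorted(dm.labels)
    assert np.allclose(dm.subset(order).d, back.subset(order).d)


def test_nj_additivity_fixed_point(rng):
    for n in (4, 5, 6, 7):
        labels = [f"s{i}" for i in range(n)]
        truth = random_tree(rng, labels)
        pm = patristic_matrix(truth)
        rebuilt = nj_tree(pm)
        pm2 = patristic_matrix(rebuilt)
        order = sorted(labels)
        assert np.allclose(pm.subset(order).d, pm2.subset(order).d, atol=1e-9)
        assert rf_distance(truth, rebuilt) == 0


def test_nj_requires_three_labels():
    dm = DistanceMatrix(["a", "b"], np.array([[0, 0.1], [0.1, 0]]))
    with pytest.raises(ValueError):
        nj_tree(dm)
    t = nj_tree(dm, allow_two=True)
    assert set(t.leaves()) == {"a", "b"}


def test_nj_negative_branch_clamped():
    # a strongly non-additive matrix that forces a negative NJ branch estimate
    d = np.array([
        [0.0, 0.1, 0.1, 0.5],
        [0.1, 0.0, 0.12, 0.5],
        [0.1, 0.12, 0.0, 0.5],
        [0.5, 0.5, 0.5, 0.0],
    ])
    t = nj_tree(DistanceMatrix(list("abcd"), d))
    assert all(v >= 0 for v in t.branch_lengths().values())


# -- Fitch ------------------------------------------------------------------------

def test_fitch_examples():
    labels = ["a", "b", "c", "d"]
    aln = Alignment("x", labels, ["A", "A", "C", "C"])
    # topology ((a,b),(c,d)): nested (1,(2,3)) rooted at leaf 0 gives split {c,d}
    tree = nested_to_tree((1, (2, 3)), labels)
    assert tree.splits() == frozenset({frozenset({"c", "d"})})
    assert fitch_score(tree, aln) == 1
    assert fitch_score(tree, Alignment("x", labels, ["G", "G", "G", "G"])) == 0
    for top in enumerate_topologies(4):
        t = nested_to_tree(top, labels)
        assert fitch_score(t, Alignment("x", labels, ["A", "C", "G", "T"])) == 3


def test_fitch_missing_data_free():
    labels = ["a", "b", "c", "d"]
    tree = nested_to_tree((1, (2, 3)), labels)
    assert fitch_score(tree, Alignment("x", labels, ["A", "N", "C", "-"])) == 1


def test_fitch_matches_labeling_enumeration_oracle(rng):
    for n in (4, 5):
        labels = [f"s{i}" for i in range(n)]
        for top in enumerate_topologies(n):
            tree = nested_to_tree(top, labels)
            cols = ["".join(rng.choice(list("ACGTN-"), size=n)) for _ in range(6)]
            aln = Alignment("x", labels, ["".join(c[i] for c in cols) for i in range(n)])
            expect = sum(_brute_min_changes(top, c, n) for c in cols)
            assert fitch_score(tree, aln) == expect


# -- exhaustive MP -----------------------------------------------------------------

def test_topology_counts():
    assert len(enumerate_topologies(4)) == 3
    assert len(enumerate_topologies(5)) == 15
    assert len(enumerate_topologies(7)) == 945


def test_mp_search_requires_four():
    with pytest.raises(ValueError):
        mp_search(Alignment("x", ["a", "b", "c"], ["A", "A", "C"]))


def test_mp_search_equals_bruteforce_oracle(rng):
    for n in (5, 6):
        labels = [f"s{i}" for i in range(n)]
        L = 30
        rows = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(n)]
        aln = Alignment("x", labels, rows)
        res = mp_search(aln)
        cols = ["".join(r[c] for r in rows) for c in range(L)]
        oracle_scores = [
            sum(_brute_min_changes(top, c, n) for c in cols)
            for top in enumerate_topologies(n)
        ]
        assert res.best_score == min(oracle_scores)
        assert res.n_enumerated == len(oracle_scores)
        assert len(res.optimal_topologies) == oracle_scores.count(min(oracle_scores))


def test_mp_recovers_generating_topology(hotspot_fixture):
    from organphylo.align_dist import progressive_align

    cfg = hotspot_fixture["config"]
    truth_tree = Tree.from_newick(cfg.tree)
    region = next(r for r in hotspot_fixture["region_sets"]
                  if r.region_id == "gene04")  # high-rate: strong signal
    aln = progressive_align(region)
    res = mp_search(aln)
    assert any(rf_distance(t, truth_tree) == 0 for t in res.optimal_topologies)


def test_mp_heuristic_flagged_beyond_nine(rng):
    labels = [f"s{i}" for i in range(10)]
    base = random_dna(rng, 60)
    rows = []
    for i in range(10):
        row = list(base)
        for p in rng.choice(60, size=6, replace=False):
            row[p] = rng.choice(list("ACGT"))
        rows.append("".join(row))
    res = mp_search(Alignment("x", labels, rows))
    assert res.exhaustive is False
    assert len(res.optimal_topologies) == 1


# -- bootstrap ----------------------------------------------------------------------

def _two_clade_alignment():
    return Alignment(
        "x", ["a", "b", "c", "d"],
        ["A" * 20 + "G" * 20, "A" * 20 + "G" * 20, "C" * 20 + "T" * 20, "C" * 20 + "T" * 20],
    )


def test_bootstrap_strong_split_support():
    aln = _two_clade_alignment()
    for seed in (0, 1, 2):
        t = bootstrap_support(aln, lambda a: nj_tree(p_distance(a)), B=100, seed=seed)
        assert t.supports[frozenset({"c", "d"})] >= 99.0


def test_bootstrap_deterministic_under_seed():
    aln = _two_clade_alignment()
    t1 = bootstrap_support(aln, lambda a: nj_tree(p_distance(a)), B=50, seed=7)
    t2 = bootstrap_support(aln, lambda a: nj_tree(p_distance(a)), B=50, seed=7)
    assert t1.supports == t2.supports
    _, s1 = mp_bootstrap(aln, B=50, seed=7)
    _, s2 = mp_bootstrap(aln, B=50, seed=7)
    assert s1 == s2


def test_bootstrap_requires_replicates():
    with pytest.raises(ValueError):
        bootstrap_support(_two_clade_alignment(), lambda a: nj_tree(p_distance(a)), B=0)


def test_mp_bootstrap_row_order_invariant():
    aln = _two_clade_alignment()
    perm = Alignment("x", ["d", "b", "a", "c"],
                     [aln.row("d"), aln.row("b"), aln.row("a"), aln.row("c")])
    _, s1 = mp_bootstrap(aln, B=60, seed=3)
    _, s2 = mp_bootstrap(perm, B=60, seed=3)
    assert s1 == s2


# -- tree comparison -----------------------------------------------------------------

def test_rf_identical_and_different():
    labels = list("abcde")
    t1 = nested_to_tree((1, ((2, 3), 4)), labels)
    t2 = nested_to_tree((1, ((2, 3), 4)), labels)
    assert rf_distance(t1, t2) == 0
    t3 = nested_to_tree((3, ((2, 1), 4)), labels)
    assert rf_distance(t1, t3) > 0


def test_rf_label_mismatch_errors():
    t1 = nested_to_tree((1, (2, 3)), list("abcd"))
    t2 = nested_to_tree((1, (2, 3)), list("abce"))
    with pytest.raises(ValueError, match="d|e"):
        rf_distance(t1, t2)


def test_rf_is_a_metric_on_five_leaf_trees():
    labels = list("abcde")
    trees = [nested_to_tree(t, labels) for t in enumerate_topologies(5)]
    for t1 in trees[:6]:
        assert rf_distance(t1, t1) == 0
        for t2 in trees[:6]:
            assert rf_distance(t1, t2) == rf_distance(t2, t1)
            for t3 in trees[:6]:
                assert rf_distance(t1, t3) <= rf_distance(t1, t2) + rf_distance(t2, t3)


def test_matrix_euclidean_examples(rng):
    labels = list("abcdefg")
    m = rng.uniform(0, 0.5, size=(7, 7))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    m1 = DistanceMatrix(labels, m)
    assert matrix_euclidean(m1, m1) == 0.0
    m2 = m.copy()
    m2[0, 1] = m2[1, 0] = m[0, 1] + 0.1
    assert matrix_euclidean(m1, DistanceMatrix(labels, m2)) == pytest.approx(0.1)
    # flat double-loop oracle on random matrices
    mb = rng.uniform(0, 0.5, size=(7, 7))
    mb = (mb + mb.T) / 2
    np.fill_diagonal(mb, 0)
    ss = 0.0
    for i in range(7):
        for j in range(i + 1, 7):
            ss += (m[i, j] - mb[i, j]) ** 2
    assert matrix_euclidean(m1, DistanceMatrix(labels, mb)) == pytest.approx(np.sqrt(ss))


def test_newick_roundtrip_with_supports():
    t = nested_to_tree((1, (2, 3)), list("abcd"))
    t.supports = {frozenset({"c", "d"}): 87.0}
    nwk = t.to_newick()
    back = Tree.from_newick(nwk)
    assert back.splits() == t.splits()
    assert back.supports == {frozenset({"c", "d"}): 87.0}


def test_outgroup_rooting_preserves_topology():
    t = nested_to_tree((1, (2, 3)), list("abcd"))
    rooted = root_with_outgroup(t, "c")
    assert rooted.splits() == t.splits()
    assert rooted.root.children[0].name == "c"
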