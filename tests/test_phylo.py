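"""Neighbor joining, Newick round-trips, outgroup rooting and monophyly."""
import dendropy
import numpy as np
import pytest

from cpaai_delimit.phylo import PhyloTree, nj_tree


def random_binary_tree(n_leaves, rng):
    """Independent generator: random topology, branch lengths in [0.1, 1]."""
    labels = [f"t{i}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    active = []
    for lbl in labels:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lbl)
        node.edge.length = rng.uniform(0.1, 1.0)
        active.append(node)
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(0.1, 1.0)
        parent.add_child(active[i])
        parent.add_child(active[j])
        active = [n for k, n in enumerate(active) if k not in (i, j)] + [parent]
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=active[0])
    tree.is_rooted = True
    return PhyloTree(tree)


def test_two_leaves_single_edge():
    t = nj_tree(["A", "B"], np.array([[0.0, 6.0], [6.0, 0.0]]))
    total = sum(e.length for e in t.tree.preorder_edge_iter()
                if e.length is not None)
    assert total == pytest.approx(6.0)


def test_three_leaves_closed_form():
    d = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
    t = nj_tree(["A", "B", "C"], d)
    lengths = {lf.taxon.label: lf.edge.length
               for lf in t.tree.leaf_node_iter()}
    # x+y=5, x+z=9, y+z=8 -> x=3, y=2, z=6
    assert lengths == pytest.approx({"A": 3.0, "B": 2.0, "C": 6.0})


def test_four_taxon_additive_recovery():
    # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
    labels = ["A", "B", "C", "D"]
    d = np.array([[0, 5, 7, 8],
                  [5, 0, 8, 9],
                  [7, 8, 0, 9],
                  [8, 9, 9, 0]], dtype=float)
    t = nj_tree(labels, d)
    assert t.bipartitions() == {frozenset({"C", "D"})}
    got_labels, got = t.patristic_distances()
    assert got_labels == labels
    assert np.allclose(got, d, atol=1e-9)


def test_nj_input_validation():
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(["A", "B", "C"], np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]]))
    with pytest.raises(ValueError, match="negative"):
        nj_tree(["A", "B"], np.array([[0, -1], [-1, 0.0]]))


@pytest.mark.parametrize("seed", range(1, 11))
def test_nj_recovers_random_additive_trees(seed):
    """Exact topology and branch lengths from additive matrices of random
    binary trees (n up to 12)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    truth = random_binary_tree(n, rng)
    labels, d = truth.patristic_distances()
    recon = nj_tree(labels, d)
    assert recon.bipartitions() == truth.bipartitions()
    labels2, d2 = recon.patristic_distances()
    assert labels2 == labels
    assert np.allclose(d2, d, atol=1e-8)


def test_newick_round_trip():
    rng = np.random.default_rng(3)
    t = random_binary_tree(7, rng)
    s1 = t.to_newick()
    t2 = PhyloTree.from_newick(s1)
    assert t2.bipartitions() == t.bipartitions()
    _, d1 = t.patristic_distances()
    _, d2 = t2.patristic_distances()
    assert np.allclose(d1, d2, atol=1e-9)
    assert PhyloTree.from_newick(t2.to_newick()).to_newick() == t2.to_newick()


def test_underscores_in_labels_survive():
    t = PhyloTree.from_newick("((g1_s1:1,g1_s2:1):1,g2_s1:2);")
    assert set(t.leaf_labels()) == {"g1_s1", "g1_s2", "g2_s1"}


def test_outgroup_rooting_preserves_ingroup():
    t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    rooted = t.root_with_outgroup({"A"})
    assert rooted.rooted
    assert rooted.is_monophyletic({"B", "C", "D"})
    assert rooted.bipartitions() == t.bipartitions()
    with pytest.raises(ValueError, match="not a clan"):
        t.root_with_outgroup({"A", "C"})
    with pytest.raises(ValueError):
        t.root_with_outgroup(set(t.leaf_labels()))


def test_rooting_on_simulated_outgroup_clade():
    from cpaai_delimit.simdata import simulate_tree

    truth, genus = simulate_tree(4, 3, seed=9)
    outgroup = {s for s, g in genus.items() if g == "Genus4"}
    labels, d = truth.patristic_distances()
    recon = nj_tree(labels, d).root_with_outgroup(outgroup)
    assert recon.bipartitions() == truth.bipartitions()
    for g in ("Genus1", "Genus2", "Genus3"):
        assert recon.is_monophyletic({s for s, gg in genus.items() if gg == g})


def test_monophyly_examples():
    t = PhyloTree.from_newick("(((A:1,B:1):1,(C:1,D:1):1):1,O:3);")
    t.tree.is_rooted = True
    assert t.is_monophyletic({"A", "B"})
    assert t.is_monophyletic({"A", "B", "C", "D"})
    assert not t.is_monophyletic({"A", "C"})
    assert t.is_monophyletic(set(t.leaf_labels()))
    assert t.is_monophyletic({"O"})
    with pytest.raises(ValueError, match="unknown"):
        t.is_monophyletic({"Z"})
    with pytest.raises(ValueError):
        t.is_monophyletic(set())


def test_monophyly_requires_rooted_tree():
    t = nj_tree(["A", "B", "C"],
                np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]]))
    with pytest.raises(ValueError, match="rooted"):
        t.is_monophyletic({"A", "B"})


@pytest.mark.parametrize("seed", range(1, 6))
def test_monophyly_agrees_with_clade_enumeration(seed):
    """Brute-force oracle: a set is monophyletic iff it is the exact leaf
    set of some node of the rooted tree. Checked on every subset."""
    from itertools import combinations

    rng = np.random.default_rng(seed)
    t = random_binary_tree(int(rng.integers(4, 9)), rng)
    leaves = sorted(t.leaf_labels())
    clades = {frozenset(lf.taxon.label for lf in node.leaf_iter())
              for node in t.tree.preorder_node_iter()}
    for r in range(1, len(leaves) + 1):
        for subset in combinations(leaves, r):
            assert t.is_monophyletic(set(subset)) == \
                (frozenset(subset) in clades)
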