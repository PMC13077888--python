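"""Threshold clustering, monophyly reconciliation and proposed actions."""
import numpy as np
import pandas as pd
import pytest

from cpaai_delimit.cpaai import CpaaiMatrix
from cpaai_delimit.delimit import (cluster_by_cpaai, propose_actions,
                                   reconcile_with_tree)
from cpaai_delimit.phylo import PhyloTree


def matrix(strains, values):
    values = np.asarray(values, dtype=float)
    return CpaaiMatrix(strain_order=list(strains), values=values,
                       compared_sites=np.full_like(values, 1000, dtype=int))


def block_matrix(within=90.0, between=80.0):
    strains = ["a1", "a2", "b1", "b2"]
    v = np.full((4, 4), between)
    v[:2, :2] = within
    v[2:, 2:] = within
    np.fill_diagonal(v, 100.0)
    return matrix(strains, v)


def test_cluster_trivial_thresholds():
    m = block_matrix()
    assert cluster_by_cpaai(m, 0.0) == [["a1", "a2", "b1", "b2"]]
    assert cluster_by_cpaai(m, 100.5) == [["a1"], ["a2"], ["b1"], ["b2"]]


def test_cluster_planted_blocks():
    assert cluster_by_cpaai(block_matrix(), 86.5) == [["a1", "a2"],
                                                      ["b1", "b2"]]


def test_clusters_refine_monotonically():
    rng = np.random.default_rng(7)
    n = 8
    v = rng.uniform(75, 95, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 100.0)
    m = matrix([f"s{i}" for i in range(n)], v)
    prev = None
    for tau in np.arange(75, 96, 1.0):
        clusters = cluster_by_cpaai(m, tau)
        if prev is not None:
            # every new cluster is contained in exactly one previous cluster
            for c in clusters:
                assert any(set(c) <= set(p) for p in prev)
        prev = clusters


ROOTED = "(((a1:1,a2:1):2,((b1:1,b2:1):1,(c1:1,c2:1):1):1):1,og:5);"


def _tree():
    t = PhyloTree.from_newick(ROOTED)
    t.tree.is_rooted = True
    return t


def test_monophyletic_partition_passes_through():
    m = block_matrix()
    tree = PhyloTree.from_newick("(((a1:1,a2:1):2,(b1:1,b2:1):2):1,og:4);")
    tree.tree.is_rooted = True
    gp = reconcile_with_tree(cluster_by_cpaai(m, 86.5), tree, m, 86.5)
    assert [c.status for c in gp.clusters] == ["resolved", "resolved"]
    assert gp.as_sets() == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}
    assert all(c.threshold_used == 86.5 for c in gp.clusters)


def test_local_threshold_raising_splits_non_monophyletic_cluster():
    """Two clades linked at 87.9% cpAAI but separated in the tree by a third
    clade: re-clustering locally at 88.0% restores monophyly."""
    strains = ["a1", "a2", "b1", "b2", "c1", "c2"]
    v = np.full((6, 6), 80.0)
    for i in (0, 2, 4):
        v[i:i + 2, i:i + 2] = 92.0
    v[0:2, 2:4] = v[2:4, 0:2] = 87.9   # a-b bridge above the 86.5 threshold
    np.fill_diagonal(v, 100.0)
    m = matrix(strains, v)
    clusters = cluster_by_cpaai(m, 86.5)
    assert ["a1", "a2", "b1", "b2"] in clusters  # bridged, but not a clade
    gp = reconcile_with_tree(clusters, _tree(), m, 86.5, tau_max=89.0, step=0.1)
    raised = [c for c in gp.clusters if c.status == "raised_threshold"]
    assert {frozenset(c.members) for c in raised} == \
        {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}
    assert all(c.threshold_used == pytest.approx(88.0) for c in raised)
    assert not [c for c in gp.clusters if c.status == "manual_review"]


def test_inseparable_cluster_goes_to_manual_review():
    """If members of two clades are mutually above any threshold <= tau_max,
    no local raise can separate them."""
    strains = ["a1", "a2", "b1", "b2", "c1", "c2"]
    v = np.full((6, 6), 80.0)
    for i in (0, 2, 4):
        v[i:i + 2, i:i + 2] = 92.0
    v[0:2, 2:4] = v[2:4, 0:2] = 91.0   # bridge above tau_max
    np.fill_diagonal(v, 100.0)
    m = matrix(strains, v)
    gp = reconcile_with_tree(cluster_by_cpaai(m, 86.5), _tree(), m,
                             86.5, tau_max=89.0, step=0.1)
    review = [c for c in gp.clusters if c.status == "manual_review"]
    assert len(review) == 1
    assert set(review[0].members) == {"a1", "a2", "b1", "b2"}
    assert not review[0].is_monophyletic
    # output still partitions the strain set
    all_members = sorted(s for c in gp.clusters for s in c.members)
    assert all_members == sorted(strains)


def test_reconcile_requires_rooted_tree():
    m = block_matrix()
    unrooted = PhyloTree.from_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
    unrooted.tree.is_rooted = False
    with pytest.raises(ValueError, match="rooted"):
        reconcile_with_tree(cluster_by_cpaai(m, 86.5), unrooted, m, 86.5)


def _metadata(rows):
    return pd.DataFrame(rows, columns=["strain_id", "genus", "species",
                                       "is_type_strain", "is_type_species"])


def test_actions_transfer_and_none():
    m = block_matrix()
    tree = PhyloTree.from_newick("(((a1:1,a2:1):2,(b1:1,b2:1):2):1,og:4);")
    tree.tree.is_rooted = True
    gp = reconcile_with_tree(cluster_by_cpaai(m, 86.5), tree, m, 86.5)
    md = _metadata([
        ("a1", "GenA", "alpha", True, True),
        ("a2", "GenH", "hopper", True, False),  # labelled H, clusters with A
        ("b1", "GenB", "beta", True, True),
        ("b2", "GenB", "bravo", False, False),
    ])
    actions = propose_actions(gp, md, m)
    kinds = {(a.kind, a.subject) for a in actions}
    assert ("transfer", "GenH hopper") in kinds
    assert ("none", "GenB") in kinds
    transfer = next(a for a in actions if a.kind == "transfer")
    assert transfer.target_genus == "GenA"
    assert "cpAAI" in transfer.justification
    assert "monophyletic" in transfer.justification


def test_actions_novel_merge_and_paraphyly():
    strains = ["a1", "a2", "b1", "b2", "c1", "c2"]
    v = np.full((6, 6), 80.0)
    for i in (0, 2, 4):
        v[i:i + 2, i:i + 2] = 92.0
    np.fill_diagonal(v, 100.0)
    m = matrix(strains, v)
    gp = reconcile_with_tree(cluster_by_cpaai(m, 86.5), _tree(), m, 86.5)
    md = _metadata([
        ("a1", "GenA", "alpha", True, True),
        ("a2", "GenC", "gamma2", False, False),  # GenC split over 2 clusters
        ("b1", "GenB", "beta", True, True),
        ("b2", "GenD", "delta", True, True),     # second type species in b
        ("c1", "GenC", "gamma", False, False),   # no type species here
        ("c2", "GenC", "gamma3", False, False),
    ])
    actions = propose_actions(gp, md, m)
    kinds = {(a.kind, a.subject) for a in actions}
    assert ("merge_flag", "GenB") in kinds and ("merge_flag", "GenD") in kinds
    assert any(a.kind == "novel_genus" and a.target_genus.startswith("NOVEL-")
               for a in actions)
    assert ("paraphyly_flag", "GenC") in kinds


def test_actions_reject_duplicate_type_species():
    m = block_matrix()
    tree = PhyloTree.from_newick("(((a1:1,a2:1):2,(b1:1,b2:1):2):1,og:4);")
    tree.tree.is_rooted = True
    gp = reconcile_with_tree(cluster_by_cpaai(m, 86.5), tree, m, 86.5)
    md = _metadata([
        ("a1", "GenA", "alpha", True, True),
        ("a2", "GenA", "alt", True, True),   # two type species for GenA
        ("b1", "GenB", "beta", True, True),
        ("b2", "GenB", "bravo", False, False),
    ])
    with pytest.raises(ValueError, match="type species"):
        propose_actions(gp, md, m)
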