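"""Distance trees, Newick I/O, outgroup rooting and monophyly testing.

The built-in tree is a neighbor-joining tree on 100 - cpAAI percent
differences; an externally inferred tree (e.g. a maximum-likelihood tree) can
be ingested from Newick and used interchangeably by the delimitation stage,
which only needs topology and rooting. Trees are dendropy trees under the
hood.
"""
from __future__ import annotations

import logging
from pathlib import Path

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


class PhyloTree:
    """A phylogeny over a set of strain-labelled leaves."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels")

    # -- construction / serialization ------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "PhyloTree":
        try:
            is_file = Path(str(source)).is_file()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True,
                                   suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def as_ascii(self) -> str:
        if len(self.leaf_labels()) < 2:
            return "\n".join(self.leaf_labels())
        return self.tree.as_ascii_plot(plot_metric="length")

    # -- basic queries ----------------------------------------------------

    @property
    def rooted(self) -> bool:
        return bool(self.tree.is_rooted)

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each as the side not containing the reference
        (lexicographically smallest) leaf — a rooting-free canonical form."""
        leaves = set(self.leaf_labels())
        ref = min(leaves)
        splits: set[frozenset[str]] = set()
        for node in self.tree.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            side = below if ref not in below else frozenset(leaves - below)
            if 1 < len(side) < len(leaves) - 1:
                splits.add(side)
        return splits

    def patristic_distances(self) -> tuple[list[str], np.ndarray]:
        labels = sorted(self.leaf_labels())
        pdm = self.tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]],
                                                           taxa[labels[j]])
        return labels, d

    # -- rooting and monophyly --------------------------------------------

    def root_with_outgroup(self, outgroup: set[str]) -> "PhyloTree":
        """Root on the edge separating the outgroup from everything else.

        The outgroup must be a clan (one side of some edge of the unrooted
        tree); the root lands at the midpoint of that edge.
        """
        leaves = set(self.leaf_labels())
        outgroup = set(outgroup)
        if not outgroup or not outgroup < leaves:
            raise ValueError("outgroup must be a non-empty proper subset of leaves")
        tree = self.tree.clone(depth=1)
        tree.is_rooted = True  # required before reroot for dendropy
        target = None
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            below = {lf.taxon.label for lf in node.leaf_iter()}
            if below == outgroup or (leaves - below) == outgroup:
                target = node
                break
        if target is None:
            closest = min(
                ({lf.taxon.label for lf in n.leaf_iter()}
                 for n in tree.postorder_node_iter() if n.parent_node is not None),
                key=lambda s: len(s ^ outgroup))
            raise ValueError(
                f"outgroup {sorted(outgroup)} is not a clan; closest split side "
                f"is {sorted(closest)}")
        elen = target.edge.length or 0.0
        tree.reroot_at_edge(target.edge, length1=elen / 2, length2=elen / 2)
        tree.is_rooted = True
        return PhyloTree(tree)

    def is_monophyletic(self, leaf_set: set[str]) -> bool:
        """True iff the leaves under MRCA(leaf_set) are exactly leaf_set."""
        if not self.rooted:
            raise ValueError("monophyly is defined on a rooted tree; root first")
        leaf_set = set(leaf_set)
        if not leaf_set:
            raise ValueError("empty leaf set")
        unknown = leaf_set - set(self.leaf_labels())
        if unknown:
            raise ValueError(f"unknown leaves: {sorted(unknown)}")
        if len(leaf_set) == 1:
            return True
        taxa = [t for t in self.tree.taxon_namespace if t.label in leaf_set]
        mrca = self.tree.mrca(taxa=taxa)
        under = {lf.taxon.label for lf in mrca.leaf_iter()}
        return under == leaf_set


def nj_tree(labels: list[str], d: np.ndarray) -> PhyloTree:
    """Neighbor-joining on a symmetric distance matrix (e.g. 100 - cpAAI).

    Deterministic: ties in the Q criterion are broken by the smallest (i, j)
    pair of current node indices. Negative branch lengths are clamped to zero
    and the clamped deficit logged.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("matrix/label size mismatch")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValueError("negative distances")
    if n < 2:
        raise ValueError("need at least 2 leaves")

    tns = dendropy.TaxonNamespace(labels)

    def leaf(lbl: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = tns.get_taxon(lbl)
        return node

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.info("NJ: clamped negative branch length %.6g at %s", x, context)
            return 0.0
        return x

    nodes = [leaf(lbl) for lbl in labels]
    if n == 2:
        root = dendropy.Node()
        for node, ln in zip(nodes, (d[0, 1] / 2, d[0, 1] / 2)):
            node.edge.length = ln
            root.add_child(node)
        tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
        tree.is_rooted = False
        return PhyloTree(tree)

    dm = d.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = dm[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                q = (r - 2) * sub[ai, aj] - row_sums[ai] - row_sums[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = dm[i, j]
        li = dij / 2 + (row_sums[ai] - row_sums[aj]) / (2 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = clamp(li, f"join({labels_safe(labels, i)})")
        nodes[j].edge.length = clamp(lj, f"join({labels_safe(labels, j)})")
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # new node reuses slot i
        new_d = 0.5 * (dm[i, :] + dm[j, :] - dij)
        dm[i, :] = new_d
        dm[:, i] = new_d
        dm[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = dendropy.Node()
    x = (dm[i, j] + dm[i, k] - dm[j, k]) / 2
    y = dm[i, j] - x
    z = dm[i, k] - x
    for node, ln in zip((nodes[i], nodes[j], nodes[k]), (x, y, z)):
        node.edge.length = clamp(ln, "final join")
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return PhyloTree(tree)


def labels_safe(labels: list[str], idx: int) -> str:
    return labels[idx] if idx < len(labels) else f"internal#{idx}"


def tree_from_cpaai(cm) -> PhyloTree:
    """NJ tree on percent difference (100 - cpAAI)."""
    return nj_tree(cm.strain_order, 100.0 - cm.values)
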