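"""Genus delimitation: threshold clustering of cpAAI reconciled with the tree.

Strains are clustered by single linkage at a cpAAI threshold (~86.5% by
default). Because a genus must be monophyletic, any cluster that is not a
clade in the rooted phylogeny is re-clustered among its own members at
progressively higher thresholds (up to a cap, 89% by default, echoing the
88.0-88.5% boundary observed in practice for recalcitrant clades); a cluster
that cannot be cleanly separated is surfaced for manual review rather than
silently split. Proposed taxonomic actions are then derived from where the
type species fall.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .cpaai import CpaaiMatrix
from .phylo import PhyloTree
from .records import GenusCluster, GenusPartition, TaxonomicAction


def cluster_by_cpaai(m: CpaaiMatrix, tau: float) -> list[list[str]]:
    """Single-linkage clusters: connected components of the graph with an
    edge wherever cpAAI >= tau. Clusters are ordered by their smallest
    member id; members are sorted within each cluster."""
    adj = csr_matrix(m.values >= tau)
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for strain, lab in zip(m.strain_order, labels):
        groups.setdefault(lab, []).append(strain)
    clusters = [sorted(g) for g in groups.values()]
    clusters.sort(key=lambda g: g[0])
    return clusters


def _sub_matrix(m: CpaaiMatrix, members: list[str]) -> CpaaiMatrix:
    idx = [m.strain_order.index(s) for s in members]
    return CpaaiMatrix(strain_order=list(members),
                       values=m.values[np.ix_(idx, idx)],
                       compared_sites=m.compared_sites[np.ix_(idx, idx)])


def reconcile_with_tree(partition: list[list[str]], tree: PhyloTree,
                        m: CpaaiMatrix, tau: float, tau_max: float = 89.0,
                        step: float = 0.1) -> GenusPartition:
    """Enforce monophyly by local threshold raising.

    Each non-monophyletic cluster is re-clustered among its own members at
    the smallest tau' in (tau, tau_max] (grid of `step`) at which every
    resulting sub-cluster is monophyletic. If no tau' works the cluster is
    kept whole with status manual_review. The raise is local: other clusters
    are never affected.
    """
    if not tree.rooted:
        raise ValueError("reconciliation needs a rooted tree; root with an "
                         "outgroup first")
    if tau > tau_max:
        raise ValueError("tau must be <= tau_max")
    n_steps = int(round((tau_max - tau) / step))
    final: list[GenusCluster] = []
    for members in partition:
        if len(members) == 1 or tree.is_monophyletic(set(members)):
            final.append(GenusCluster("", list(members), tau, True, "resolved"))
            continue
        sub = _sub_matrix(m, members)
        placed = False
        for k in range(1, n_steps + 1):
            tau_k = round(tau + k * step, 10)
            if tau_k > tau_max + 1e-9:
                break
            subclusters = cluster_by_cpaai(sub, tau_k)
            if all(len(c) == 1 or tree.is_monophyletic(set(c))
                   for c in subclusters):
                for c in subclusters:
                    final.append(GenusCluster("", c, tau_k, True,
                                              "raised_threshold"))
                placed = True
                break
        if not placed:
            final.append(GenusCluster("", list(members), tau, False,
                                      "manual_review"))
    final.sort(key=lambda c: c.members[0])
    for i, c in enumerate(final, start=1):
        c.cluster_id = f"C{i}"
    return GenusPartition(clusters=final)


@dataclass
class _Meta:
    genus: str
    species: str
    is_type_strain: bool
    is_type_species: bool


def _metadata_map(metadata: pd.DataFrame) -> dict[str, _Meta]:
    out = {}
    for r in metadata.itertuples():
        out[str(r.strain_id)] = _Meta(str(r.genus), str(r.species),
                                      bool(r.is_type_strain),
                                      bool(r.is_type_species))
    # a genus may anchor only one type species
    ts = metadata[metadata["is_type_species"].astype(bool)]
    dup = ts["genus"][ts["genus"].duplicated()]
    if len(dup):
        raise ValueError(f"multiple type species flagged for genus "
                         f"{sorted(set(dup))}")
    return out


def _cpaai_evidence(m: CpaaiMatrix, members: list[str]) -> str:
    idx = [m.strain_order.index(s) for s in members]
    rest = [i for i in range(len(m.strain_order)) if i not in idx]
    parts = []
    if len(idx) > 1:
        sub = m.values[np.ix_(idx, idx)]
        tri = sub[np.triu_indices(len(idx), k=1)]
        parts.append(f"min within-cluster cpAAI {tri.min():.2f}%")
    if rest:
        between = m.values[np.ix_(idx, rest)]
        parts.append(f"max cpAAI to any other cluster {between.max():.2f}%")
    return "; ".join(parts) if parts else "single strain, no comparisons"


def propose_actions(gp: GenusPartition, metadata: pd.DataFrame,
                    m: CpaaiMatrix) -> list[TaxonomicAction]:
    """Turn a reconciled partition into proposed taxonomic actions.

    A cluster containing exactly one genus type species keeps that genus
    name and pulls in differently-labelled members as transfers; a cluster
    with several type species flags a merge; one with none is a candidate
    novel genus. A named genus scattered over several clusters is flagged
    paraphyletic. Every action cites the cpAAI evidence and the cluster's
    monophyly status.
    """
    meta = _metadata_map(metadata)
    for c in gp.clusters:
        missing = [s for s in c.members if s not in meta]
        if missing:
            raise ValueError(f"no metadata for strains {missing}")
    actions: list[TaxonomicAction] = []
    novel_counter = 0
    for c in gp.clusters:
        evidence = (f"{_cpaai_evidence(m, c.members)}; cluster is "
                    f"{'monophyletic' if c.is_monophyletic else 'NOT monophyletic'}"
                    f" in the rooted tree (threshold {c.threshold_used:g}%)")
        type_species = [s for s in c.members if meta[s].is_type_species]
        if len(type_species) == 1:
            genus = meta[type_species[0]].genus
            movers = [s for s in c.members if meta[s].genus != genus]
            if not movers:
                actions.append(TaxonomicAction(
                    kind="none", subject=genus,
                    justification=f"cluster {c.cluster_id} matches genus "
                                  f"{genus}; {evidence}"))
            for s in movers:
                actions.append(TaxonomicAction(
                    kind="transfer", subject=f"{meta[s].genus} {meta[s].species}",
                    target_genus=genus,
                    justification=f"{s} clusters with the {genus} type species "
                                  f"{type_species[0]} in {c.cluster_id}; {evidence}"))
        elif len(type_species) >= 2:
            for s in type_species:
                actions.append(TaxonomicAction(
                    kind="merge_flag", subject=meta[s].genus,
                    justification=f"type species of {meta[s].genus} shares "
                                  f"cluster {c.cluster_id} with "
                                  f"{len(type_species) - 1} other type species; "
                                  f"{evidence}"))
        else:
            novel_counter += 1
            actions.append(TaxonomicAction(
                kind="novel_genus", subject=c.cluster_id,
                target_genus=f"NOVEL-{novel_counter}",
                justification=f"cluster {c.cluster_id} "
                              f"({', '.join(c.members)}) contains no genus "
                              f"type species; {evidence}"))
    # genera split across clusters
    by_genus: dict[str, set[str]] = {}
    for c in gp.clusters:
        for s in c.members:
            g = meta[s].genus
            if g:
                by_genus.setdefault(g, set()).add(c.cluster_id)
    for genus in sorted(by_genus):
        cids = sorted(by_genus[genus])
        if len(cids) >= 2:
            members = [s for s in meta if meta[s].genus == genus]
            actions.append(TaxonomicAction(
                kind="paraphyly_flag", subject=genus,
                justification=f"genus {genus} spans clusters "
                              f"{', '.join(cids)}; "
                              f"{_cpaai_evidence(m, members)}; its members do "
                              f"not form a single clade-compatible cluster"))
    return actions


def partition_table(gp: GenusPartition) -> pd.DataFrame:
    rows = [(s, c.cluster_id, c.threshold_used, c.status)
            for c in gp.clusters for s in c.members]
    return pd.DataFrame(rows, columns=["strain_id", "cluster",
                                       "threshold_used", "status"])


def actions_table(actions: list[TaxonomicAction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.kind, a.subject, a.target_genus, a.justification) for a in actions],
        columns=["kind", "subject", "target_genus", "justification"])


def narrative_report(gp: GenusPartition, actions: list[TaxonomicAction],
                     tau: float, tau_max: float, step: float) -> str:
    lines = [f"Genus delimitation report (tau {tau:g}%, local raise up to "
             f"{tau_max:g}% in {step:g}% steps)", ""]
    for c in gp.clusters:
        lines.append(f"{c.cluster_id} [{c.status}, threshold "
                     f"{c.threshold_used:g}%, "
                     f"{'monophyletic' if c.is_monophyletic else 'not monophyletic'}]: "
                     f"{', '.join(c.members)}")
    lines.append("")
    lines.append("Proposed actions:")
    for a in actions:
        target = f" -> {a.target_genus}" if a.target_genus else ""
        lines.append(f"  [{a.kind}] {a.subject}{target}: {a.justification}")
    if not actions:
        lines.append("  (none)")
    return "\n".join(lines) + "\n"
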