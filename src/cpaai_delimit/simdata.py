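"""Synthetic genomes with planted marker truth for end-to-end validation.

The generator produces an ultrametric genus-structured tree, evolves marker
proteins along it under a uniform-replacement substitution model, and packs
reverse-translated markers with random spacers into nucleotide genomes. The
substitution model gives a closed-form expected identity between two leaves
at path length l: id = exp(-r*l) + (1 - exp(-r*l))/20, so divergence depths
can be chosen to target specific cpAAI levels. Defaults target ~92% cpAAI
within genera and ~80% between, the regime in which genus boundaries sit
near the mid-80s threshold.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .markers import _CODON_TABLE, reverse_complement
from .phylo import PhyloTree
from .records import AA_LETTERS, GenomeRecord, MarkerPanel

_AA_ARR = np.array(list(AA_LETTERS))
_CODONS_FOR = {}
for _codon, _aa in _CODON_TABLE.items():
    if _aa != "*":
        _CODONS_FOR.setdefault(_aa, []).append(_codon)
_CODONS_FOR = {aa: sorted(cs) for aa, cs in _CODONS_FOR.items()}

DEFAULT_WITHIN_DEPTH = 0.044
DEFAULT_BETWEEN_DEPTH = 0.118
DEFAULT_RATE = 1.0


def expected_identity(path_length: float, rate: float = DEFAULT_RATE) -> float:
    """Closed-form expected fraction identity between two leaves at the given
    patristic path length under uniform replacement over 20 letters."""
    q = math.exp(-rate * path_length)
    return q + (1.0 - q) / 20.0


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    true_tree: PhyloTree
    genus_assignment: dict[str, str]
    marker_locations: dict[str, dict[str, tuple[str, int, int, str]]]
    dropped_markers: dict[str, set[str]]
    divergence_params: dict[str, float]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "true_tree_newick": self.true_tree.to_newick(),
            "genus_assignment": self.genus_assignment,
            "marker_locations": {
                s: {m: list(loc) for m, loc in locs.items()}
                for s, locs in self.marker_locations.items()},
            "dropped_markers": {s: sorted(v)
                                for s, v in self.dropped_markers.items()},
            "divergence_params": self.divergence_params,
            "seed": self.seed,
        }


def _join_ultrametric(children: list[tuple[dendropy.Node, float]],
                      heights: list[float],
                      rng: np.random.Generator) -> tuple[dendropy.Node, float]:
    """Randomly agglomerate (node, height) pairs at the given sorted merge
    heights; returns the final (root node, height)."""
    active = list(children)
    for h in heights:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        (na, ha), (nb, hb) = active[i], active[j]
        parent = dendropy.Node()
        na.edge.length = h - ha
        nb.edge.length = h - hb
        parent.add_child(na)
        parent.add_child(nb)
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append((parent, h))
    assert len(active) == 1
    return active[0]


def simulate_tree(n_genera: int, strains_per_genus: int,
                  within_depth: float = DEFAULT_WITHIN_DEPTH,
                  between_depth: float = DEFAULT_BETWEEN_DEPTH,
                  seed: int = 0) -> tuple[PhyloTree, dict[str, str]]:
    """Ultrametric rooted tree in which each genus is a clade.

    Within-genus coalescences happen below `within_depth` (the genus crown is
    exactly at `within_depth`); genus-level joins are confined to the deepest
    5% of the tree so that every between-genus path is close to
    2*between_depth and genera are cleanly separated.
    """
    if n_genera < 1 or strains_per_genus < 1:
        raise ValueError("counts must be >= 1")
    if not (0 < within_depth < between_depth):
        raise ValueError("need 0 < within_depth < between_depth")
    rng = np.random.default_rng(seed)
    labels = [f"g{g + 1}_s{s + 1}" for g in range(n_genera)
              for s in range(strains_per_genus)]
    tns = dendropy.TaxonNamespace(labels)
    genus_assignment: dict[str, str] = {}
    genus_roots: list[tuple[dendropy.Node, float]] = []
    for g in range(n_genera):
        leaves = []
        for s in range(strains_per_genus):
            lbl = f"g{g + 1}_s{s + 1}"
            genus_assignment[lbl] = f"Genus{g + 1}"
            node = dendropy.Node()
            node.taxon = tns.get_taxon(lbl)
            leaves.append((node, 0.0))
        if strains_per_genus == 1:
            genus_roots.append(leaves[0])
        else:
            hs = np.sort(rng.uniform(0, within_depth, strains_per_genus - 1))
            hs[-1] = within_depth
            root, _ = _join_ultrametric(leaves, list(hs), rng)
            genus_roots.append((root, within_depth))
    if n_genera == 1:
        root, _ = genus_roots[0]
    else:
        hs = np.sort(rng.uniform(0.95 * between_depth, between_depth,
                                 n_genera - 1))
        hs[-1] = between_depth
        root, _ = _join_ultrametric(genus_roots, list(hs), rng)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = True
    return PhyloTree(tree), genus_assignment


def evolve_markers(tree: PhyloTree, marker_lengths: list[int],
                   rate: float = DEFAULT_RATE,
                   seed: int = 0) -> tuple[MarkerPanel, dict[str, dict[str, str]]]:
    """Evolve marker proteins along the tree under uniform replacement.

    Root sequences are i.i.d. uniform over the 20 amino acids and double as
    the reference panel. On a branch of length l each site is resampled
    (uniformly over all 20 letters) with probability 1 - exp(-rate*l).
    Returns (panel of root sequences, per-leaf marker sequences).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    marker_ids = [f"marker_{i + 1}" for i in range(len(marker_lengths))]
    total = int(np.sum(marker_lengths))
    bounds = np.concatenate([[0], np.cumsum(marker_lengths)])
    root_seq = rng.integers(0, 20, size=total)

    leaf_seqs: dict[str, np.ndarray] = {}

    def descend(node: dendropy.Node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            l = child.edge.length or 0.0
            p = 1.0 - math.exp(-rate * l)
            child_seq = seq.copy()
            hit = rng.random(total) < p
            child_seq[hit] = rng.integers(0, 20, size=int(hit.sum()))
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    root = tree.tree.seed_node
    if root.is_leaf():
        leaf_seqs[root.taxon.label] = root_seq
    else:
        descend(root, root_seq)

    def split(seq: np.ndarray) -> dict[str, str]:
        text = "".join(_AA_ARR[seq])
        return {mid: text[bounds[i]:bounds[i + 1]]
                for i, mid in enumerate(marker_ids)}

    panel = MarkerPanel(markers=list(split(root_seq).items()),
                        panel_name="simulated")
    return panel, {leaf: split(s) for leaf, s in leaf_seqs.items()}


def _reverse_translate(aa_seq: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_FOR[aa][rng.integers(0, len(_CODONS_FOR[aa]))]
                   for aa in aa_seq)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def build_genomes(marker_sets: dict[str, dict[str, str]],
                  genus_assignment: dict[str, str] | None = None,
                  true_tree: PhyloTree | None = None,
                  spacer_len_range: tuple[int, int] = (50, 150),
                  dropout: float = 0.0, shuffle: bool = True,
                  seed: int = 0,
                  divergence_params: dict[str, float] | None = None,
                  ) -> tuple[list[GenomeRecord], SimTruth]:
    """Pack each strain's markers into a single-contig genome.

    Retained markers are reverse-translated with uniform synonymous codon
    choice, placed in random order on random strands with random intergenic
    spacers; each marker is independently dropped with probability `dropout`
    (simulating incomplete assemblies). True coordinates (0-based half-open,
    forward strand) are recorded in the returned SimTruth.
    """
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    locations: dict[str, dict[str, tuple[str, int, int, str]]] = {}
    dropped: dict[str, set[str]] = {}
    lo, hi = spacer_len_range
    for strain in sorted(marker_sets):
        markers = marker_sets[strain]
        order = sorted(markers)
        if shuffle:
            order = [order[i] for i in rng.permutation(len(order))]
        drop = {mid for mid in order if rng.random() < dropout}
        contig_id = f"{strain}_contig1"
        parts: list[str] = [_random_nt(rng, int(rng.integers(lo, hi + 1)))]
        pos = len(parts[0])
        locs: dict[str, tuple[str, int, int, str]] = {}
        for mid in order:
            if mid in drop:
                continue
            nt = _reverse_translate(markers[mid], rng)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = nt if strand == "+" else reverse_complement(nt)
            parts.append(placed)
            locs[mid] = (contig_id, pos, pos + len(placed), strand)
            pos += len(placed)
            spacer = _random_nt(rng, int(rng.integers(lo, hi + 1)))
            parts.append(spacer)
            pos += len(spacer)
        genus = (genus_assignment or {}).get(strain, "")
        genomes.append(GenomeRecord(
            strain_id=strain, contigs=[(contig_id, "".join(parts))],
            genus_label=genus, species_label=f"sp-{strain}"))
        locations[strain] = locs
        dropped[strain] = drop
    truth = SimTruth(
        true_tree=true_tree,
        genus_assignment=dict(genus_assignment or {}),
        marker_locations=locations, dropped_markers=dropped,
        divergence_params=dict(divergence_params or {}), seed=seed)
    return genomes, truth


def mutate_genome(genome: GenomeRecord, per_site_rate: float,
                  seed: int = 0) -> GenomeRecord:
    """Independent substitution of each site (to a different uniform base)
    with probability per_site_rate. Used to calibrate the ANI estimator."""
    if not (0 <= per_site_rate < 0.75):
        raise ValueError("per_site_rate must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    contigs = []
    for cid, seq in genome.contigs:
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = np.nonzero(rng.random(len(arr)) < per_site_rate)[0]
        for i in hit:
            choices = bases[bases != arr[i]]
            arr[i] = choices[rng.integers(0, len(choices))]
        contigs.append((cid, arr.tobytes().decode()))
    return GenomeRecord(strain_id=genome.strain_id + "_mut", contigs=contigs,
                        genus_label=genome.genus_label,
                        species_label=genome.species_label)


@dataclass
class SimulatedDataset:
    genomes: list[GenomeRecord]
    panel: MarkerPanel
    metadata: pd.DataFrame
    truth: SimTruth
    marker_sets: dict[str, dict[str, str]] = field(default_factory=dict)


def simulate_dataset(n_genera: int = 5, strains_per_genus: int = 4,
                     n_markers: int = 170,
                     marker_length_range: tuple[int, int] = (60, 140),
                     within_depth: float = DEFAULT_WITHIN_DEPTH,
                     between_depth: float = DEFAULT_BETWEEN_DEPTH,
                     rate: float = DEFAULT_RATE, dropout: float = 0.0,
                     seed: int = 0) -> SimulatedDataset:
    """One-call bundle: tree, markers, genomes, metadata and truth.

    The first strain of each genus is flagged as the type strain of the genus
    type species, so a correct delimitation maps every cluster onto exactly
    one named genus.
    """
    rng = np.random.default_rng(seed)
    tree, genus = simulate_tree(n_genera, strains_per_genus, within_depth,
                                between_depth, seed=int(rng.integers(2**31)))
    lengths = list(rng.integers(marker_length_range[0],
                                marker_length_range[1] + 1, size=n_markers))
    panel, marker_sets = evolve_markers(tree, [int(x) for x in lengths],
                                        rate=rate,
                                        seed=int(rng.integers(2**31)))
    genomes, truth = build_genomes(
        marker_sets, genus_assignment=genus, true_tree=tree,
        dropout=dropout, seed=int(rng.integers(2**31)),
        divergence_params={"rate": rate, "within_depth": within_depth,
                           "between_depth": between_depth,
                           "dropout": dropout})
    truth.seed = seed
    rows = []
    for strain in sorted(marker_sets):
        is_first = strain.endswith("_s1")
        rows.append((strain, genus[strain], f"sp-{strain}", is_first, is_first))
    metadata = pd.DataFrame(rows, columns=["strain_id", "genus", "species",
                                           "is_type_strain", "is_type_species"])
    return SimulatedDataset(genomes=genomes, panel=panel, metadata=metadata,
                            truth=truth, marker_sets=marker_sets)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    import json

    from .io import write_fasta, write_metadata

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gdir = outdir / "genomes"
    gdir.mkdir(exist_ok=True)
    for g in ds.genomes:
        write_fasta(gdir / f"{g.strain_id}.fasta", g.contigs)
    write_fasta(outdir / "panel.fasta", ds.panel.markers)
    write_metadata(outdir / "metadata.tsv", ds.metadata)
    ds.truth.true_tree.write_newick(outdir / "true_tree.nwk")
    (outdir / "truth.json").write_text(
        json.dumps(ds.truth.to_json_dict(), indent=1))
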