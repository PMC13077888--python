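"""End-to-end pipeline: genomes in, genus partition and reports out.

Stages: marker extraction -> per-marker alignment + trimming -> concatenation
-> cpAAI -> distance tree (or ingested external tree) -> rooting -> genus
delimitation -> proposed actions. Every run writes a manifest recording the
inputs, thresholds, seed and a checksum for each output file, so a taxonomic
decision can be traced to a frozen parameter set.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cpaai import cpaai_matrix
from .delimit import (actions_table, cluster_by_cpaai, narrative_report,
                      partition_table, propose_actions, reconcile_with_tree)
from .io import (read_genome_fasta, read_metadata, read_panel_fasta,
                 write_fasta, write_marker_hits, write_supermatrix)
from .markers import SearchParams, fill_missing_markers, find_marker_hits
from .msa import align_marker, concatenate, trim_alignment
from .phylo import PhyloTree, tree_from_cpaai

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Frozen parameter record for one pipeline run."""

    genomes_dir: str
    panel_file: str
    metadata_file: str
    out_dir: str
    tau: float = 86.5
    tau_max: float = 89.0
    step: float = 0.1
    ani_screen: float = 95.0
    ani_species: float = 96.0
    dddh: float = 70.0
    max_gap_fraction: float = 0.9
    min_score: float = 50.0
    min_coverage: float = 0.5
    outgroup: list[str] = field(default_factory=list)
    tree_file: str = ""       # ingest an externally built Newick tree
    aligner_cmd: str = ""     # external aligner template with {in}/{out}
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau", "tau_max", "ani_screen", "ani_species", "dddh"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.tau > self.tau_max:
            raise ValueError("tau must be <= tau_max")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def validate_paths(self) -> None:
        for name in ("genomes_dir", "panel_file", "metadata_file"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.tree_file and not Path(self.tree_file).exists():
            raise FileNotFoundError(f"tree_file: {self.tree_file} does not exist")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_times: dict[str, float] = {}

    def timed(stage):
        t0 = time.time()

        def done():
            stage_times[stage] = round(time.time() - t0, 3)
            logger.info("stage %s: %.2fs", stage, stage_times[stage])
        return done

    # ---- load inputs ----
    stage = "load"
    try:
        fin = timed(stage)
        metadata = read_metadata(config.metadata_file)
        panel = read_panel_fasta(config.panel_file)
        genome_files = sorted(Path(config.genomes_dir).glob("*.fasta")) + \
            sorted(Path(config.genomes_dir).glob("*.fa"))
        genomes = []
        meta_by_id = {r.strain_id: r for r in metadata.itertuples()}
        for gf in genome_files:
            row = meta_by_id.get(gf.stem)
            genomes.append(read_genome_fasta(
                gf, strain_id=gf.stem,
                genus_label=str(row.genus) if row else "",
                species_label=str(row.species) if row else "",
                is_type_strain=bool(row.is_type_strain) if row else False,
                is_type_species=bool(row.is_type_species) if row else False))
        if len(genomes) < 3:
            raise ValueError(f"need at least 3 genomes, found {len(genomes)} "
                             f"in {config.genomes_dir} (a tree over fewer "
                             f"strains is not informative)")
        missing_meta = [g.strain_id for g in genomes
                        if g.strain_id not in meta_by_id]
        if missing_meta:
            raise ValueError(f"strains without metadata: {missing_meta}")
        fin()
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    strain_order = [g.strain_id for g in genomes]
    outputs: list[Path] = []

    # ---- marker extraction ----
    stage = "markers"
    try:
        fin = timed(stage)
        params = SearchParams(min_score=config.min_score,
                              min_coverage=config.min_coverage)
        per_strain = {}
        markers_dir = out / "markers"
        markers_dir.mkdir(exist_ok=True)
        for g in genomes:
            hits = find_marker_hits(g, panel, params)
            full = fill_missing_markers(hits, panel, g.strain_id)
            per_strain[g.strain_id] = full
            tsv = markers_dir / f"{g.strain_id}.hits.tsv"
            write_marker_hits(tsv, full)
            fasta = markers_dir / f"{g.strain_id}.markers.fasta"
            write_fasta(fasta, [(h.marker_id, h.aa_sequence) for h in full])
            outputs += [tsv, fasta]
        fin()
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- alignment, trimming, concatenation ----
    stage = "supermatrix"
    try:
        fin = timed(stage)
        alignments = []
        for i, (marker_id, _) in enumerate(panel.markers):
            seqs = [(s, per_strain[s][i].aa_sequence) for s in strain_order]
            aln = align_marker(seqs, marker_id=marker_id,
                               aligner_cmd=config.aligner_cmd or None)
            alignments.append(trim_alignment(aln, config.max_gap_fraction))
        sm = concatenate(alignments, strain_order)
        fa, parts = write_supermatrix(out / "supermatrix", sm)
        outputs += [fa, parts]
        fin()
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- cpAAI ----
    stage = "cpaai"
    try:
        fin = timed(stage)
        cm = cpaai_matrix(sm)
        cm.write(out / "cpaai")
        outputs += [out / "cpaai.csv", out / "cpaai.long.tsv"]
        fin()
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- tree ----
    stage = "tree"
    try:
        fin = timed(stage)
        if config.tree_file:
            tree = PhyloTree.from_newick(Path(config.tree_file))
        else:
            tree = tree_from_cpaai(cm)
        if config.outgroup:
            rooted = tree.root_with_outgroup(set(config.outgroup))
        else:
            t = tree.tree.clone(depth=1)
            t.is_rooted = True
            t.reroot_at_midpoint()
            rooted = PhyloTree(t)
        rooted.write_newick(out / "tree.nwk")
        (out / "tree.txt").write_text(rooted.as_ascii() + "\n")
        outputs += [out / "tree.nwk", out / "tree.txt"]
        fin()
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # ---- delimitation ----
    stage = "delimit"
    try:
        fin = timed(stage)
        ingroup = [s for s in cm.strain_order if s not in set(config.outgroup)]
        if config.outgroup:
            from .delimit import _sub_matrix
            cm_in = _sub_matrix(cm, ingroup)
        else:
            cm_in = cm
        clusters = cluster_by_cpaai(cm_in, config.tau)
        gp = reconcile_with_tree(clusters, rooted, cm_in, config.tau,
                                 config.tau_max, config.step)
        actions = propose_actions(gp, metadata, cm_in)
        header = (f"# thresholds: tau={config.tau} tau_max={config.tau_max} "
                  f"step={config.step} ani_screen={config.ani_screen} "
                  f"ani_species={config.ani_species} dddh={config.dddh} "
                  f"seed={config.seed}\n")
        ptab = out / "partition.tsv"
        with open(ptab, "w") as fh:
            fh.write(header)
            partition_table(gp).to_csv(fh, sep="\t", index=False)
        atab = out / "actions.tsv"
        with open(atab, "w") as fh:
            fh.write(header)
            actions_table(actions).to_csv(fh, sep="\t", index=False)
        report = out / "report.txt"
        report.write_text(header + narrative_report(
            gp, actions, config.tau, config.tau_max, config.step))
        outputs += [ptab, atab, report]
        fin()
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    manifest = {
        "tool_version": __version__,
        "config": asdict(config),
        "stage_seconds": stage_times,
        "external_tools": {"aligner_cmd": config.aligner_cmd or None,
                           "deterministic": not config.aligner_cmd},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
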