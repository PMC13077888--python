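"""Readers and writers for the standard formats the pipeline touches.

Genomes and marker panels are FASTA (Biopython), metadata and OGRI tables are
TSV (pandas). A published table of ANI/dDDH values for ten Rhizobiaceae
type-strain pairs ships as a packaged fixture for the synonymy stage.
"""
from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .records import GenomeRecord, MarkerHit, MarkerPanel, OgriRecord, SuperMatrix


def read_genome_fasta(path: str | Path, strain_id: str | None = None,
                      **metadata) -> GenomeRecord:
    """Read a (possibly multi-contig) nucleotide FASTA as one strain."""
    path = Path(path)
    contigs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return GenomeRecord(strain_id=strain_id or path.stem, contigs=contigs, **metadata)


def read_panel_fasta(path: str | Path, panel_name: str | None = None) -> MarkerPanel:
    """Read a protein FASTA as an ordered marker panel."""
    path = Path(path)
    markers = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not markers:
        raise ValueError(f"no markers in {path}")
    return MarkerPanel(markers=markers, panel_name=panel_name or path.stem)


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


METADATA_COLUMNS = ["strain_id", "genus", "species", "is_type_strain", "is_type_species"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Strain metadata TSV: strain_id, genus, species, type flags."""
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    for col in ("is_type_strain", "is_type_species"):
        df[col] = df[col].astype(bool)
    if df["strain_id"].duplicated().any():
        raise ValueError("duplicate strain_id in metadata")
    return df


def write_metadata(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_marker_hits(path: str | Path, hits: list[MarkerHit]) -> None:
    """Per-strain marker hit table; coordinates reported 1-based inclusive."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["strain_id", "marker_id", "contig", "start", "end", "strand",
                    "frame", "score", "identity_pct", "coverage", "is_placeholder"])
        for h in hits:
            if h.is_placeholder:
                w.writerow([h.strain_id, h.marker_id, "", "", "", "", "", "", "", "",
                            "true"])
            else:
                w.writerow([h.strain_id, h.marker_id, h.contig_id,
                            h.start + 1, h.end, h.strand, h.frame,
                            f"{h.score:.1f}", f"{h.identity_pct:.2f}",
                            f"{h.coverage_frac:.3f}", "false"])


def write_supermatrix(prefix: str | Path, sm: SuperMatrix) -> tuple[Path, Path]:
    """Write aligned FASTA plus a partition TSV (marker_id, start, end)."""
    prefix = Path(prefix)
    fasta = prefix.with_suffix(".fasta")
    parts = prefix.with_suffix(".partitions.tsv")
    write_fasta(fasta, list(zip(sm.strain_order, sm.rows)))
    with open(parts, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["marker_id", "start", "end"])
        for mid, (a, b) in sm.partition_map.items():
            w.writerow([mid, a, b])
    return fasta, parts


def read_supermatrix(fasta: str | Path, partitions: str | Path | None = None) -> SuperMatrix:
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(fasta), "fasta")]
    if not rows:
        raise ValueError(f"no rows in {fasta}")
    width = len(rows[0][1])
    if partitions is not None:
        pdf = pd.read_csv(partitions, sep="\t")
        pmap = {r.marker_id: (int(r.start), int(r.end)) for r in pdf.itertuples()}
    else:
        pmap = {"all": (0, width)}
    return SuperMatrix(strain_order=[s for s, _ in rows],
                       rows=[r for _, r in rows], partition_map=pmap)


def read_ogri_table(path: str | Path) -> list[OgriRecord]:
    """OGRI TSV: strain_a, strain_b, ani, then optional dddh, dddh_ci_lo/hi."""
    df = pd.read_csv(path, sep="\t")
    for col in ("strain_a", "strain_b", "ani"):
        if col not in df.columns:
            raise ValueError(f"OGRI table missing column {col!r}")
    records = []
    for r in df.itertuples():
        dddh = getattr(r, "dddh", None)
        dddh = None if dddh is None or pd.isna(dddh) else float(dddh)
        lo = getattr(r, "dddh_ci_lo", None)
        hi = getattr(r, "dddh_ci_hi", None)
        ci = None
        if lo is not None and hi is not None and not (pd.isna(lo) or pd.isna(hi)):
            ci = (float(lo), float(hi))
        records.append(OgriRecord(
            strain_a=str(r.strain_a), strain_b=str(r.strain_b),
            ani_pct=None if pd.isna(r.ani) else float(r.ani),
            dddh_pct=dddh, dddh_ci=ci, source="table",
            note=str(getattr(r, "note", "") or ""),
        ))
    return records


def load_rhizobiaceae_ogri_fixture() -> list[OgriRecord]:
    """The packaged published ANI/dDDH table for Rhizobiaceae type-strain
    pairs with ANI >= 95% (dDDH from genome-to-genome distance, formula 2)."""
    ref = resources.files("cpaai_delimit").joinpath("data/rhizobiaceae_ani_dddh.tsv")
    with resources.as_file(ref) as p:
        return read_ogri_table(p)
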