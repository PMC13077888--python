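"""Core domain records shared across the pipeline stages.

Everything here is a plain dataclass: genomes and marker panels on the input
side, marker hits / alignments / the concatenated supermatrix in the middle,
and relatedness matrices, partitions and taxonomic actions on the output side.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
NT_LETTERS = "ACGTN"

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass
class GenomeRecord:
    """One strain: its nucleotide contigs plus taxonomic metadata."""

    strain_id: str
    contigs: list[tuple[str, str]]
    genus_label: str = ""
    species_label: str = ""
    is_type_strain: bool = False
    is_type_species: bool = False

    def __post_init__(self) -> None:
        if not self.strain_id:
            raise ValueError("strain_id must be non-empty")
        cleaned = []
        for contig_id, seq in self.contigs:
            if not seq:
                raise ValueError(
                    f"empty contig {contig_id!r} in strain {self.strain_id!r}"
                )
            seq = seq.upper()
            if _NON_ACGTN.search(seq):
                n_bad = len(_NON_ACGTN.findall(seq))
                logger.warning(
                    "strain %s contig %s: %d non-ACGTN letters mapped to N",
                    self.strain_id, contig_id, n_bad,
                )
                seq = _NON_ACGTN.sub("N", seq)
            cleaned.append((contig_id, seq))
        self.contigs = cleaned

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


@dataclass
class MarkerPanel:
    """An ordered panel of reference marker proteins.

    The order is fixed and defines the concatenation order of the supermatrix.
    """

    markers: list[tuple[str, str]]
    panel_name: str = "custom"

    def __post_init__(self) -> None:
        ids = [m for m, _ in self.markers]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate marker_id in panel")
        for mid, seq in self.markers:
            if not seq:
                raise ValueError(f"empty reference sequence for marker {mid!r}")
            bad = set(seq.upper()) - set(AA_LETTERS)
            if bad:
                raise ValueError(
                    f"marker {mid!r} reference contains non-amino-acid letters {bad}"
                )
        self.markers = [(m, s.upper()) for m, s in self.markers]

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m for m, _ in self.markers]

    def reference(self, marker_id: str) -> str:
        for mid, seq in self.markers:
            if mid == marker_id:
                return seq
        raise KeyError(marker_id)


@dataclass
class MarkerHit:
    """Best translated match of one marker in one genome (or a placeholder).

    Coordinates are 0-based half-open on the forward strand of the contig.
    A placeholder hit stands in for a marker absent from the genome: its
    sequence is all X at the reference length, so that it carries no signal
    under pairwise deletion downstream.
    """

    strain_id: str
    marker_id: str
    aa_sequence: str
    score: float = 0.0
    identity_pct: float = 0.0
    coverage_frac: float = 0.0
    contig_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    frame: int | None = None
    is_placeholder: bool = False

    def __post_init__(self) -> None:
        if self.is_placeholder:
            if set(self.aa_sequence) != {"X"}:
                raise ValueError("placeholder aa_sequence must be all X")
            if self.start is not None or self.end is not None:
                raise ValueError("placeholder hits carry no coordinates")
        else:
            if self.start is None or self.end is None or self.start >= self.end:
                raise ValueError("real hits need start < end")
            if self.coverage_frac <= 0:
                raise ValueError("real hits need coverage_frac > 0")
            if "*" in self.aa_sequence:
                raise ValueError("stop codon inside reported hit sequence")

    @classmethod
    def placeholder(cls, strain_id: str, marker_id: str, ref_len: int) -> "MarkerHit":
        return cls(
            strain_id=strain_id,
            marker_id=marker_id,
            aa_sequence="X" * ref_len,
            is_placeholder=True,
        )


@dataclass
class MarkerAlignment:
    """One marker aligned across strains ('-' gaps, X allowed)."""

    marker_id: str
    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        widths = {len(s) for _, s in self.rows}
        if len(widths) > 1:
            raise ValueError(f"ragged alignment for marker {self.marker_id!r}")
        ids = [s for s, _ in self.rows]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate strain in alignment {self.marker_id!r}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def strain_ids(self) -> list[str]:
        return [s for s, _ in self.rows]

    def row(self, strain_id: str) -> str:
        for sid, seq in self.rows:
            if sid == strain_id:
                return seq
        raise KeyError(strain_id)


@dataclass
class SuperMatrix:
    """Trimmed, concatenated amino-acid alignment with a partition map."""

    strain_order: list[str]
    rows: list[str]
    partition_map: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("ragged supermatrix rows")
        if len(self.strain_order) != len(self.rows):
            raise ValueError("strain_order/rows length mismatch")
        # partition ranges must tile [0, width) contiguously, in order
        pos = 0
        for mid, (a, b) in self.partition_map.items():
            if a != pos or b < a:
                raise ValueError(f"partition map not contiguous at {mid!r}")
            pos = b
        if self.rows and pos != self.width:
            raise ValueError("partition map does not cover the matrix")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, strain_id: str) -> str:
        return self.rows[self.strain_order.index(strain_id)]

    def extract(self, marker_id: str) -> MarkerAlignment:
        a, b = self.partition_map[marker_id]
        return MarkerAlignment(
            marker_id=marker_id,
            rows=[(sid, row[a:b]) for sid, row in zip(self.strain_order, self.rows)],
        )


@dataclass
class OgriRecord:
    """ANI/dDDH figures for one unordered strain pair."""

    strain_a: str
    strain_b: str
    ani_pct: float | None = None
    aligned_fragment_count: int | None = None
    dddh_pct: float | None = None
    dddh_ci: tuple[float, float] | None = None
    source: str = "computed"
    note: str = ""

    def __post_init__(self) -> None:
        for v, name in ((self.ani_pct, "ani_pct"), (self.dddh_pct, "dddh_pct")):
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.dddh_ci is not None:
            lo, hi = self.dddh_ci
            if self.dddh_pct is not None and not (lo <= self.dddh_pct <= hi):
                raise ValueError("dDDH outside its confidence interval")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.strain_a, self.strain_b)))  # type: ignore[return-value]


@dataclass
class SynonymyCall:
    """Verdict on whether two species names denote the same species."""

    pair: tuple[str, str]
    verdict: str  # distinct | synonym | needs_dddh | conflict
    rule_trace: list[tuple[str, float | None, str, bool]] = field(default_factory=list)


@dataclass
class GenusCluster:
    cluster_id: str
    members: list[str]
    threshold_used: float
    is_monophyletic: bool
    status: str  # resolved | raised_threshold | manual_review


@dataclass
class GenusPartition:
    """Clustering of strains into putative genera with monophyly status."""

    clusters: list[GenusCluster]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & set(c.members):
                raise ValueError("clusters overlap")
            seen.update(c.members)
            if c.status != "manual_review" and not c.is_monophyletic:
                raise ValueError(
                    f"cluster {c.cluster_id} not monophyletic but status {c.status}"
                )

    @property
    def strain_to_cluster(self) -> dict[str, str]:
        return {m: c.cluster_id for c in self.clusters for m in c.members}

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(c.members) for c in self.clusters}


@dataclass
class TaxonomicAction:
    """A proposed nomenclatural action for one species/genus."""

    kind: str  # none | transfer | novel_genus | merge_flag | paraphyly_flag
    subject: str
    target_genus: str = ""
    justification: str = ""
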