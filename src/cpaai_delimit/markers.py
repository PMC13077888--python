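"""Translated homology search: locate marker proteins in nucleotide genomes.

Each genome is translated in all six reading frames; frames are split at stop
codons into open segments, and each marker protein is aligned locally
(BLOSUM62, affine gaps) against candidate segments selected by exact 4-mer
seeds. The single best qualifying hit per marker is reported; markers with no
qualifying hit are later padded with all-X "gap proteins" so that they carry
no signal under pairwise deletion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .records import GenomeRecord, MarkerHit, MarkerPanel

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# codon -> amino acid, stops as '*'; any codon containing N translates to X
_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate(seq: str, offset: int) -> str:
    out = []
    for i in range(offset, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(out)


def translate_six_frames(seq: str) -> list[str]:
    """Translate in frames +1, +2, +3, -1, -2, -3 (in that order).

    Stops are emitted as '*', codons containing N as 'X'. Frame k has length
    floor((len - offset) / 3). An empty input yields six empty frames.
    """
    if not seq:
        logger.warning("translate_six_frames called on empty sequence")
        return [""] * 6
    seq = seq.upper()
    rc = reverse_complement(seq)
    return [_translate(seq, 0), _translate(seq, 1), _translate(seq, 2),
            _translate(rc, 0), _translate(rc, 1), _translate(rc, 2)]


@dataclass(frozen=True)
class SearchParams:
    """Settings for the built-in translated search.

    min_score/min_coverage gate hit acceptance (matrix units / fraction of the
    reference length); seed_len is the exact amino-acid k-mer used to select
    candidate segments before dynamic programming.
    """

    min_score: float = 50.0
    min_coverage: float = 0.5
    seed_len: int = 4
    gap_open: float = 11.0
    gap_extend: float = 1.0


@lru_cache(maxsize=None)
def _scoring_matrix():
    # BLOSUM62 with X neutral (scores 0 against everything)
    m = substitution_matrices.load("BLOSUM62").copy()
    xi = m.alphabet.index("X")
    m[xi, :] = 0.0
    m[:, xi] = 0.0
    return m


def make_aligner(mode: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _scoring_matrix()
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class _Segment:
    """A stop-free stretch of one translated frame."""

    contig_id: str
    contig_len: int
    frame: int          # 0-2
    strand: str         # '+' or '-'
    aa_offset: int      # position of segment start within the frame translation
    seq: str


def _frame_segments(genome: GenomeRecord) -> list[_Segment]:
    segments = []
    for contig_id, seq in genome.contigs:
        frames = translate_six_frames(seq)
        for idx, frame_aa in enumerate(frames):
            strand = "+" if idx < 3 else "-"
            offset_in_frame = 0
            for chunk in frame_aa.split("*"):
                if chunk:
                    segments.append(_Segment(
                        contig_id=contig_id, contig_len=len(seq),
                        frame=idx % 3, strand=strand,
                        aa_offset=offset_in_frame, seq=chunk,
                    ))
                offset_in_frame += len(chunk) + 1
    return segments


def _kmer_index(segments: list[_Segment], k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for si, seg in enumerate(segments):
        seen: set[str] = set()
        for i in range(len(seg.seq) - k + 1):
            kmer = seg.seq[i:i + k]
            if kmer not in seen:
                seen.add(kmer)
                index.setdefault(kmer, []).append(si)
    return index


def _nt_coords(seg: _Segment, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map an aa interval within a segment to forward-strand nt coordinates."""
    p0 = seg.aa_offset + aa_start
    p1 = seg.aa_offset + aa_end
    if seg.strand == "+":
        return seg.frame + 3 * p0, seg.frame + 3 * p1
    return seg.contig_len - (seg.frame + 3 * p1), seg.contig_len - (seg.frame + 3 * p0)


def _evaluate(ref: str, seg: _Segment, aligner: PairwiseAligner):
    """Best local alignment of ref against one segment, with statistics."""
    alignment = aligner.align(ref, seg.seq)[0]
    ref_blocks, seg_blocks = alignment.aligned
    if len(ref_blocks) == 0:
        return None
    ref_cov = sum(b - a for a, b in ref_blocks)
    matches = 0
    columns = 0
    for (ra, rb), (sa, sb) in zip(ref_blocks, seg_blocks):
        columns += rb - ra
        matches += sum(1 for x, y in zip(ref[ra:rb], seg.seq[sa:sb]) if x == y)
    # gap columns between blocks
    for i in range(1, len(ref_blocks)):
        columns += (ref_blocks[i][0] - ref_blocks[i - 1][1]) + \
                   (seg_blocks[i][0] - seg_blocks[i - 1][1])
    seg_a, seg_b = int(seg_blocks[0][0]), int(seg_blocks[-1][1])
    start, end = _nt_coords(seg, seg_a, seg_b)
    start, end = int(start), int(end)
    return {
        "score": float(alignment.score),
        "identity_pct": 100.0 * matches / columns if columns else 0.0,
        "coverage_frac": ref_cov / len(ref),
        "aa_sequence": seg.seq[seg_a:seg_b],
        "start": start, "end": end,
    }


def find_marker_hits(genome: GenomeRecord, panel: MarkerPanel,
                     params: SearchParams = SearchParams()) -> list[MarkerHit]:
    """Best qualifying hit per marker (at most one); unfound markers absent.

    Ties on score are broken by contig id, then start coordinate, then '+'
    strand, so results are reproducible regardless of search order.
    """
    segments = _frame_segments(genome)
    index = _kmer_index(segments, params.seed_len)
    aligner = make_aligner("local", params.gap_open, params.gap_extend)
    hits: list[MarkerHit] = []
    for marker_id, ref in panel.markers:
        min_seg = max(params.seed_len, int(params.min_coverage * len(ref) * 0.8))
        cand: set[int] = set()
        for i in range(len(ref) - params.seed_len + 1):
            cand.update(index.get(ref[i:i + params.seed_len], ()))
        cand = {si for si in cand if len(segments[si].seq) >= min_seg}
        best = None
        best_key = None
        for si in sorted(cand):
            seg = segments[si]
            score = aligner.score(ref, seg.seq)
            if score < params.min_score:
                continue
            if best is not None and score < best["score"]:
                continue
            ev = _evaluate(ref, seg, aligner)
            if ev is None or ev["coverage_frac"] < params.min_coverage:
                continue
            key = (-ev["score"], seg.contig_id, ev["start"], 0 if seg.strand == "+" else 1)
            if best is None or key < best_key:
                best = ev | {"contig_id": seg.contig_id, "strand": seg.strand,
                             "frame": seg.frame}
                best_key = key
        if best is not None and best["score"] >= params.min_score:
            hits.append(MarkerHit(strain_id=genome.strain_id, marker_id=marker_id,
                                  **best))
    return hits


def fill_missing_markers(hits: list[MarkerHit], panel: MarkerPanel,
                         strain_id: str) -> list[MarkerHit]:
    """Return exactly one hit per panel marker, in panel order, padding the
    missing ones with all-X placeholders of reference length."""
    by_marker: dict[str, MarkerHit] = {}
    for h in hits:
        if h.marker_id in by_marker:
            raise ValueError(f"duplicate hit for marker {h.marker_id!r}")
        if h.marker_id not in panel.marker_ids:
            raise ValueError(f"hit for unknown marker {h.marker_id!r}")
        by_marker[h.marker_id] = h
    out = []
    for marker_id, ref in panel.markers:
        out.append(by_marker.get(marker_id) or
                   MarkerHit.placeholder(strain_id, marker_id, len(ref)))
    return out
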