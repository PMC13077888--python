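"""Per-marker multiple alignment, column trimming and concatenation.

The built-in aligner is a deterministic center-star progressive alignment
(center = sequence with the highest summed pairwise score); an external
aligner such as MAFFT can be plugged in as a command template. Trimming is a
transparent gap-fraction rule: only '-' counts as a gap, so all-X placeholder
columns survive and keep their pairwise-deletion semantics downstream.
"""
from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

from .markers import make_aligner
from .records import MarkerAlignment, SuperMatrix


def _gap_profile(center_aligned: str, n_res: int) -> list[int]:
    """Gaps in each of the n_res+1 inter-residue slots of the center row."""
    slots = [0] * (n_res + 1)
    seen = 0
    for ch in center_aligned:
        if ch == "-":
            slots[seen] += 1
        else:
            seen += 1
    return slots


def _expand_row(s_aligned: str, c_aligned: str, master: list[int]) -> str:
    """Re-pad one pairwise-aligned row onto the merged master gap profile."""
    out: list[str] = []
    buffer: list[str] = []
    seen = 0
    for s_ch, c_ch in zip(s_aligned, c_aligned):
        if c_ch == "-":
            buffer.append(s_ch)
        else:
            out.extend(buffer)
            out.append("-" * (master[seen] - len(buffer)))
            out.append(s_ch)
            buffer = []
            seen += 1
    out.extend(buffer)
    out.append("-" * (master[seen] - len(buffer)))
    return "".join(out)


def _center_row(center: str, master: list[int]) -> str:
    out = []
    for i, ch in enumerate(center):
        out.append("-" * master[i])
        out.append(ch)
    out.append("-" * master[-1])
    return "".join(out)


def align_marker(seqs: list[tuple[str, str]], marker_id: str = "",
                 aligner_cmd: str | None = None) -> MarkerAlignment:
    """Align one marker across strains.

    seqs is an ordered list of (strain_id, amino-acid sequence); placeholders
    (all-X) participate like ordinary sequences. With aligner_cmd set, the
    command template (with {in} and {out} FASTA placeholders) is run instead
    of the built-in center-star procedure.
    """
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if aligner_cmd:
        return _align_external(seqs, marker_id, aligner_cmd)
    if len({s for _, s in seqs}) == 1:
        return MarkerAlignment(marker_id=marker_id, rows=list(seqs))

    pw = make_aligner("global")
    n = len(seqs)
    scores = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            scores[i][j] = scores[j][i] = pw.score(seqs[i][1], seqs[j][1])
    sums = [sum(row) for row in scores]
    center_idx = max(range(n), key=lambda i: (sums[i], -i))
    center = seqs[center_idx][1]

    pairwise = []  # (index, center_aligned, other_aligned)
    master = [0] * (len(center) + 1)
    for i in range(n):
        if i == center_idx:
            continue
        aln = pw.align(center, seqs[i][1])[0]
        c_aln, s_aln = str(aln[0]), str(aln[1])
        prof = _gap_profile(c_aln, len(center))
        master = [max(a, b) for a, b in zip(master, prof)]
        pairwise.append((i, c_aln, s_aln))

    rows: list[tuple[str, str] | None] = [None] * n
    rows[center_idx] = (seqs[center_idx][0], _center_row(center, master))
    for i, c_aln, s_aln in pairwise:
        rows[i] = (seqs[i][0], _expand_row(s_aln, c_aln, master))
    return MarkerAlignment(marker_id=marker_id, rows=[r for r in rows if r])


def _align_external(seqs, marker_id, cmd_template):
    from .io import write_fasta
    from Bio import SeqIO

    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out.fasta"
        write_fasta(fin, seqs)
        cmd = cmd_template.format(**{"in": str(fin), "out": str(fout)})
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external aligner failed for marker {marker_id!r}: {proc.stderr[-500:]}")
        aligned = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fout), "fasta")}
        rows = []
        for sid, seq in seqs:
            if sid not in aligned:
                raise RuntimeError(f"external aligner dropped {sid!r} (marker {marker_id!r})")
            if aligned[sid].replace("-", "") != seq.upper():
                raise RuntimeError(
                    f"external aligner altered sequence {sid!r} (marker {marker_id!r})")
            rows.append((sid, aligned[sid]))
        return MarkerAlignment(marker_id=marker_id, rows=rows)


def trim_alignment(aln: MarkerAlignment, max_gap_fraction: float = 0.9) -> MarkerAlignment:
    """Drop columns whose '-' fraction exceeds max_gap_fraction.

    X counts as a residue here (it is missing data, not a gap): placeholder
    columns must survive trimming so pairwise deletion can ignore them later.
    """
    n = len(aln.rows)
    keep = []
    for col in range(aln.width):
        gaps = sum(1 for _, seq in aln.rows if seq[col] == "-")
        if gaps / n <= max_gap_fraction:
            keep.append(col)
    if not keep and aln.width:
        raise ValueError(
            f"trimming removed every column of marker {aln.marker_id!r}; "
            f"raise max_gap_fraction (was {max_gap_fraction})")
    rows = [(sid, "".join(seq[c] for c in keep)) for sid, seq in aln.rows]
    return MarkerAlignment(marker_id=aln.marker_id, rows=rows)


def concatenate(alignments: list[MarkerAlignment],
                strain_order: list[str]) -> SuperMatrix:
    """Join trimmed marker alignments into a supermatrix, in the given order."""
    parts: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {s: [] for s in strain_order}
    pos = 0
    for aln in alignments:
        present = set(aln.strain_ids)
        for s in strain_order:
            if s not in present:
                raise ValueError(f"strain {s!r} missing from marker {aln.marker_id!r}")
            chunks[s].append(aln.row(s))
        parts[aln.marker_id] = (pos, pos + aln.width)
        pos += aln.width
    return SuperMatrix(
        strain_order=list(strain_order),
        rows=["".join(chunks[s]) for s in strain_order],
        partition_map=parts,
    )


def sum_of_pairs_score(aln: MarkerAlignment, gap_open: float = 11.0,
                       gap_extend: float = 1.0) -> float:
    """Sum over row pairs of the induced pairwise alignment score (affine
    gaps; columns gapped in both rows are skipped). Used to compare
    alternative alignments of the same sequences."""
    from .markers import _scoring_matrix

    m = _scoring_matrix()
    alpha = m.alphabet
    total = 0.0
    rows = [seq for _, seq in aln.rows]
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            in_gap = False
            for a, b in zip(rows[i], rows[j]):
                if a == "-" and b == "-":
                    continue
                if a == "-" or b == "-":
                    total -= gap_open if not in_gap else gap_extend
                    in_gap = True
                else:
                    total += m[alpha.index(a), alpha.index(b)]
                    in_gap = False
    return total
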