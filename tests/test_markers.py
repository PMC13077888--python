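"""Six-frame translation and marker extraction against planted ground truth."""
import numpy as np
import pytest

from cpaai_delimit.markers import (SearchParams, fill_missing_markers,
                                   find_marker_hits, reverse_complement,
                                   translate_six_frames)
from cpaai_delimit.records import GenomeRecord, MarkerHit, MarkerPanel
from cpaai_delimit.simdata import build_genomes, simulate_dataset


@pytest.mark.parametrize("seq,frame,expected", [
    ("ATGGCC", 0, "MA"),
    ("GGCCAT", 3, "MA"),     # reverse complement of ATGGCC, frame -1
    ("ATGTAA", 0, "M*"),     # stop emitted as '*'
])
def test_translate_known_codons(seq, frame, expected):
    assert translate_six_frames(seq)[frame] == expected


def test_translate_frame_lengths_and_n_codons():
    frames = translate_six_frames("ATGNCCGT")  # 8 nt
    for offset, frame in zip((0, 1, 2, 0, 1, 2), frames):
        assert len(frame) == (8 - offset) // 3
    assert frames[1][0] == "X"  # TGN codon contains N -> X


def test_translate_empty_sequence():
    assert translate_six_frames("") == [""] * 6


def test_planted_markers_recovered_with_exact_coordinates():
    """On synthetic genomes every non-dropped marker is found at its true
    location, strand and frame-consistent coordinates (seeds 1-5)."""
    for seed in range(1, 6):
        ds = simulate_dataset(n_genera=2, strains_per_genus=2, n_markers=8,
                              dropout=0.1, seed=seed)
        for g in ds.genomes:
            hits = find_marker_hits(g, ds.panel)
            truth = ds.truth.marker_locations[g.strain_id]
            dropped = ds.truth.dropped_markers[g.strain_id]
            found = {h.marker_id for h in hits}
            assert found == set(truth), f"seed {seed} strain {g.strain_id}"
            assert not (found & dropped)
            for h in hits:
                contig, start, end, strand = truth[h.marker_id]
                assert (h.contig_id, h.strand) == (contig, strand)
                # local alignment may shave a mismatched terminal residue,
                # so the hit sits inside the true extent and nearly fills it
                assert start <= h.start < h.end <= end
                assert (h.end - h.start) >= 0.9 * (end - start)
                assert "*" not in h.aa_sequence
                assert h.coverage_frac >= 0.9


def test_random_genomes_yield_no_hits():
    """i.i.d. random nucleotides contain no credible marker at default
    thresholds (score null distribution sits below min_score)."""
    panel = MarkerPanel(markers=[("m1", "MKLVINREWQACDEFGHIKLMNPQRSTVWYAD" * 3)])
    for seed in range(1, 6):
        rng = np.random.default_rng(seed)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30_000)])
        g = GenomeRecord(f"rand{seed}", [("c1", seq)])
        assert find_marker_hits(g, panel) == []


def test_search_is_deterministic(small_dataset):
    g = small_dataset.genomes[0]
    h1 = find_marker_hits(g, small_dataset.panel)
    h2 = find_marker_hits(g, small_dataset.panel)
    assert h1 == h2


def test_reverse_complement_symmetry(small_dataset):
    """Reverse-complementing every contig flips strand and mirrors
    coordinates but leaves sequence, score and identity unchanged."""
    ds = small_dataset
    g = ds.genomes[0]
    flipped = GenomeRecord(g.strain_id,
                           [(cid, reverse_complement(s)) for cid, s in g.contigs])
    fwd = {h.marker_id: h for h in find_marker_hits(g, ds.panel)}
    rev = {h.marker_id: h for h in find_marker_hits(flipped, ds.panel)}
    assert set(fwd) == set(rev)
    lengths = dict(g.contigs)
    for mid, h in fwd.items():
        r = rev[mid]
        assert r.aa_sequence == h.aa_sequence
        assert r.score == h.score
        assert r.identity_pct == h.identity_pct
        assert r.strand != h.strand
        L = len(lengths[h.contig_id])
        assert (r.start, r.end) == (L - h.end, L - h.start)


def test_fill_missing_markers_pads_and_conserves():
    panel = MarkerPanel(markers=[(f"m{i}", "ACDEFGHIKL") for i in range(5)])
    hits = [MarkerHit("s", "m1", "ACDEFGHIKL", score=60, identity_pct=100,
                      coverage_frac=1.0, contig_id="c", start=0, end=30,
                      strand="+", frame=0),
            MarkerHit("s", "m3", "ACDEFGHIKL", score=60, identity_pct=100,
                      coverage_frac=1.0, contig_id="c", start=40, end=70,
                      strand="+", frame=0)]
    full = fill_missing_markers(hits, panel, "s")
    assert [h.marker_id for h in full] == [f"m{i}" for i in range(5)]
    placeholders = [h for h in full if h.is_placeholder]
    assert len(placeholders) == 3
    assert all(set(h.aa_sequence) == {"X"} and len(h.aa_sequence) == 10
               for h in placeholders)
    # identity case and degenerate case
    assert fill_missing_markers(full, panel, "s") == full
    assert all(h.is_placeholder for h in fill_missing_markers([], panel, "s"))


def test_fill_missing_markers_rejects_duplicates():
    panel = MarkerPanel(markers=[("m1", "ACDEFGHIKL")])
    h = MarkerHit("s", "m1", "ACDEFGHIKL", score=60, identity_pct=100,
                  coverage_frac=1.0, contig_id="c", start=0, end=30,
                  strand="+", frame=0)
    with pytest.raises(ValueError, match="duplicate"):
        fill_missing_markers([h, h], panel, "s")


def test_strains_missing_markers_get_placeholders():
    """A genome lacking 2 of the panel's markers yields exactly 2 all-X
    placeholders after padding."""
    ds = simulate_dataset(n_genera=1, strains_per_genus=1, n_markers=10,
                          seed=3)
    strain = ds.genomes[0].strain_id
    sets = {strain: {m: s for m, s in ds.marker_sets[strain].items()
                     if m not in ("marker_4", "marker_7")}}
    genomes, _ = build_genomes(sets, seed=3)
    hits = find_marker_hits(genomes[0], ds.panel)
    full = fill_missing_markers(hits, ds.panel, genomes[0].strain_id)
    assert sum(h.is_placeholder for h in full) == 2
    assert {h.marker_id for h in full if h.is_placeholder} == \
        {"marker_4", "marker_7"}
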