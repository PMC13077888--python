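import pytest

from cpaai_delimit.simdata import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """3 genera x 2 strains, 20 markers: big enough to exercise every stage,
    small enough to run in seconds."""
    return simulate_dataset(n_genera=3, strains_per_genus=2, n_markers=20,
                            seed=1)


@pytest.fixture(scope="session")
def small_supermatrix(small_dataset):
    from cpaai_delimit.markers import fill_missing_markers, find_marker_hits
    from cpaai_delimit.msa import align_marker, concatenate, trim_alignment

    ds = small_dataset
    per = {}
    for g in ds.genomes:
        per[g.strain_id] = fill_missing_markers(
            find_marker_hits(g, ds.panel), ds.panel, g.strain_id)
    strains = sorted(per)
    alns = []
    for i, (mid, _) in enumerate(ds.panel.markers):
        aln = align_marker([(s, per[s][i].aa_sequence) for s in strains],
                           marker_id=mid)
        alns.append(trim_alignment(aln))
    return concatenate(alns, strains)
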