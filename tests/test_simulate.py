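"""The synthetic-data generator: genome, clone array, pooled reads, truth."""

from __future__ import annotations

import numpy as np
import pytest

from capss.pool_design import build_index_table, build_layout
from capss.seq import HINDIII, revcomp
from capss.simulate import (
    CloneSource,
    VectorModel,
    build_truth_tables,
    clone_insert_seq,
    default_vector,
    hindiii_sites,
    place_clones,
    simulate_genome,
    simulate_pool_reads,
)


def test_genome_has_requested_gap_structure():
    g = simulate_genome(1, 200_000, 3, 500, 0, 0, 0.46, seed=1)
    assert set(g.sequences) == {"chr01"}
    assert len(g.gap_truth) == 3
    for chrom, start, end in g.gap_truth:
        seq = g.sequences[chrom]
        assert end - start == 500
        assert set(seq[start:end]) == {"N"}
        assert seq[start - 1] != "N" and seq[end] != "N"


def test_genome_is_deterministic_per_seed():
    a = simulate_genome(2, 50_000, 2, 100, 200, 3, seed=9)
    b = simulate_genome(2, 50_000, 2, 100, 200, 3, seed=9)
    assert a.sequences == b.sequences
    assert a.gap_truth == b.gap_truth and a.repeat_truth == b.repeat_truth
    c = simulate_genome(2, 50_000, 2, 100, 200, 3, seed=10)
    assert c.sequences != a.sequences


def test_planted_repeats_are_near_identical_copies():
    g = simulate_genome(1, 100_000, 0, 0, 300, 4, seed=3)
    assert len(g.repeat_truth) == 4
    copies = [g.sequences[c][s:e] for c, s, e in g.repeat_truth]
    ref = copies[0]
    for other in copies[1:]:
        ident = sum(a == b for a, b in zip(ref, other)) / len(ref)
        assert ident > 0.95


def test_site_spacing_injects_hindiii_lattice():
    dense = simulate_genome(1, 100_000, 0, 0, seed=4, site_spacing=1000)
    sparse = simulate_genome(1, 100_000, 0, 0, seed=4, site_spacing=None)
    assert len(hindiii_sites(dense.sequences["chr01"])) > 60
    assert len(hindiii_sites(dense.sequences["chr01"])) > len(
        hindiii_sites(sparse.sequences["chr01"])
    )


def test_vector_flanks_must_avoid_cloning_site():
    v = default_vector()
    assert HINDIII not in v.left_flank and HINDIII not in v.right_flank
    with pytest.raises(ValueError):
        VectorModel(left_flank="A" * 99, right_flank="C" * 500)
    with pytest.raises(ValueError):
        VectorModel(left_flank="G" * 200 + HINDIII + "G" * 200, right_flank="C" * 500)


@pytest.fixture(scope="module")
def toy_world():
    layout = build_layout(2, 2, 4, 6)
    genome = simulate_genome(2, 150_000, 3, 300, seed=21, site_spacing=900)
    clones = place_clones(
        genome, layout, 4000, 600, 2000, 8000, seed=22, unique_ends=True
    )
    return layout, genome, clones


def test_clone_inserts_are_hindiii_bounded_both_strands(toy_world):
    layout, genome, clones = toy_world
    assert len(clones) == layout.n_wells
    for c in clones:
        ins = clone_insert_seq(c, genome.sequences)
        assert ins.startswith(HINDIII) and ins.endswith(HINDIII)
        raw = genome.sequences[c.chrom][c.start : c.end]
        assert raw.startswith(HINDIII) and raw.endswith(HINDIII)
    assert {c.strand for c in clones} == {"+", "-"}


def test_clone_ends_are_pairwise_distinct(toy_world):
    _, _, clones = toy_world
    starts = [(c.chrom, c.start) for c in clones]
    ends = [(c.chrom, c.end) for c in clones]
    assert len(set(starts)) == len(starts)
    assert len(set(ends)) == len(ends)


def test_insert_length_recovers_target_mean():
    layout = build_layout(4, 4, 4, 6)  # 384 clones
    genome = simulate_genome(2, 400_000, 0, 0, seed=31, site_spacing=900)
    clones = place_clones(genome, layout, 4000, 600, 2000, 8000, seed=32)
    spans = np.array([c.end - c.start for c in clones], dtype=float)
    se = spans.std(ddof=1) / np.sqrt(len(spans))
    assert abs(spans.mean() - 4000) < 3 * se + 1e-9


def test_organelle_fraction_zero_means_no_organelle_clones(toy_world):
    _, _, clones = toy_world
    assert all(c.source is CloneSource.NUCLEAR for c in clones)


def test_organelle_clones_created_at_requested_fraction():
    layout = build_layout(2, 2, 4, 6)
    genome = simulate_genome(1, 150_000, 0, 0, seed=41, site_spacing=900)
    org = simulate_genome(1, 30_000, 0, 0, seed=42, site_spacing=900).sequences
    organelle = {"chloroplast": org["chr01"]}
    clones = place_clones(
        genome, layout, 4000, 600, 2000, 8000,
        organelle_fraction=0.25, organelle_genome=organelle, seed=43,
    )
    n_org = sum(c.source is CloneSource.CHLOROPLAST for c in clones)
    assert n_org == round(0.25 * layout.n_wells)
    assert all(c.chrom == "chloroplast" for c in clones if c.source is CloneSource.CHLOROPLAST)


def test_truth_bes_are_terminal_insert_segments(toy_world):
    _, genome, clones = toy_world
    truth = build_truth_tables(clones, genome.sequences, bes_len=500)
    for c in clones:
        fwd, rev = truth.expected_bes[c.clone_id]
        ins = clone_insert_seq(c, genome.sequences)
        assert fwd == ins[:500] and rev == revcomp(ins)[:500]
        assert fwd.startswith(HINDIII) and rev.startswith(HINDIII)


@pytest.fixture(scope="module")
def world():
    layout = build_layout(1, 1, 3, 4)
    genome = simulate_genome(1, 100_000, 0, 0, seed=51, site_spacing=700)
    clones = place_clones(genome, layout, 3000, 400, 1500, 6000, seed=52)
    vector = default_vector(seed=53)
    table = build_index_table(layout)
    reads = simulate_pool_reads(
        genome.sequences, clones, layout, vector, table,
        read_len=100, frag_mean=300, frag_sd=30, depth_per_pool=25.0,
        error_rate=0.0, seed=54,
    )
    return layout, genome, clones, vector, table, reads


def test_error_free_reads_are_exact_molecule_substrings(world):
    layout, genome, clones, vector, table, reads = world
    molecules = {
        c.clone_id: vector.left_flank
        + clone_insert_seq(c, genome.sequences)
        + vector.right_flank
        for c in clones
    }
    sample = reads.reads["X"][::50] + reads.reads["Y"][::50]
    for rp in sample:
        src = rp.id.split(":")[2]
        mol = molecules[src]
        core1 = rp.seq1[7:]  # strip the prepended index
        assert core1 in mol or revcomp(core1) in mol
        assert rp.seq2 in mol or revcomp(rp.seq2) in mol


def test_realized_depth_matches_target(world):
    layout, genome, clones, vector, table, reads = world
    by_well = {c.well: c for c in clones}
    from capss.pool_design import member_wells

    for pool, n_frag in reads.per_pool_fragments.items():
        total = sum(
            len(vector.left_flank)
            + (by_well[w].end - by_well[w].start)
            + len(vector.right_flank)
            for w in member_wells(layout, pool)
        )
        realized = n_frag * 2 * 100 / total
        assert abs(realized - 25.0) / 25.0 < 0.1


def test_junction_spanning_fragments_exist_for_nearly_every_end(world):
    layout, genome, clones, vector, table, reads = world
    # a fragment supports an end when one of its reads spans the
    # junction with >= 20 bp vector anchor and >= 26 bp insert side
    counts: dict[tuple[str, str], int] = {}
    flank = len(vector.left_flank)
    insert_lens = {c.clone_id: c.end - c.start for c in clones}
    for lib in ("X", "Y"):
        for rp in reads.reads[lib]:
            _, _, src, st, en, _, _ = rp.id.split(":")
            if src == "host":
                continue
            st, en = int(st), int(en)
            left_j = flank
            right_j = flank + insert_lens[src]
            for rs, re_ in ((st, st + 100), (en - 100, en)):
                if rs <= left_j - 20 and re_ >= left_j + 26:
                    counts[(src, "F")] = counts.get((src, "F"), 0) + 1
                if rs <= right_j - 26 and re_ >= right_j + 20:
                    counts[(src, "R")] = counts.get((src, "R"), 0) + 1
    clone_ends = [(c.clone_id, e) for c in clones for e in ("F", "R")]
    ok = sum(counts.get(key, 0) >= 3 for key in clone_ends)
    assert ok / len(clone_ends) >= 0.95


def test_same_seed_reproduces_reads_exactly(world):
    layout, genome, clones, vector, table, _ = world
    kwargs = dict(
        read_len=100, frag_mean=300, frag_sd=30, depth_per_pool=25.0,
        error_rate=0.0, seed=54,
    )
    a = simulate_pool_reads(genome.sequences, clones, layout, vector, table, **kwargs)
    b = simulate_pool_reads(genome.sequences, clones, layout, vector, table, **kwargs)
    assert a.reads == b.reads


def test_duplicate_barcodes_rejected(world):
    layout, genome, clones, vector, table, _ = world
    bad = dict(table)
    pools = list(bad)
    bad[pools[0]] = bad[pools[1]]
    with pytest.raises(ValueError):
        simulate_pool_reads(
            genome.sequences, clones, layout, vector, bad,
            read_len=100, frag_mean=300, seed=1,
        )
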