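"""Genome anchoring: alignment contract, culling, pairing, integration,
organelle screening and GFF3 emission."""

from __future__ import annotations

import numpy as np
import pytest

from capss.assign import Source, Status, WellBes
from capss.bes_short import End
from capss.genmap import (
    AlignmentHit,
    Evidence,
    GenomeIndex,
    HitClassification,
    MappedClone,
    OrganelleKind,
    align_bes,
    cull_and_classify,
    integrate,
    mask_repeats,
    pair_and_place,
    read_gff3,
    screen_organelle,
    write_gff3,
)
from capss.pool_design import WellAddress, build_layout
from capss.seq import HINDIII, random_dna, revcomp

from oracles import sliding_hits

RNG = np.random.default_rng(7)
LAYOUT = build_layout(2, 2, 4, 6)
W0, W1 = WellAddress(0, 0, 0), WellAddress(0, 1, 1)


@pytest.fixture(scope="module")
def genome():
    return {"chrA": random_dna(np.random.default_rng(70), 40_000, 0.46),
            "chrB": random_dna(np.random.default_rng(71), 30_000, 0.46)}


@pytest.fixture(scope="module")
def index(genome):
    return GenomeIndex(genome, k=21)


def _mutate(seq: str, n: int, rng) -> str:
    out = bytearray(seq.encode())
    for pos in rng.choice(len(seq), size=n, replace=False):
        old = chr(out[pos])
        out[pos] = ord(next(b for b in "ACGT" if b != old))
    return out.decode()


class TestAlign:
    def test_exact_substring_gives_one_perfect_hit(self, genome, index):
        q = genome["chrA"][5000:5400]
        hits = align_bes(q, index)
        assert len(hits) == 1
        h = hits[0]
        assert (h.chrom, h.strand, h.t_start, h.t_end) == ("chrA", "+", 5000, 5400)
        assert h.identity == 1.0 and h.q_cov == 1.0

    def test_reverse_strand_hit_reported_with_target_coordinates(self, genome, index):
        q = revcomp(genome["chrB"][1000:1350])
        hits = align_bes(q, index)
        assert len(hits) == 1
        assert (hits[0].chrom, hits[0].strand, hits[0].t_start) == ("chrB", "-", 1000)

    def test_two_percent_divergence_fails_the_identity_contract(self, genome, index):
        q = genome["chrA"][8000:8400]
        q = _mutate(q, 8, np.random.default_rng(3))  # 2% substitutions
        assert align_bes(q, index, min_identity=0.99) == []

    def test_short_or_masked_queries_are_not_aligned(self, genome, index):
        assert align_bes(genome["chrA"][100:140], index) == []
        q = genome["chrA"][5000:5400].lower()
        assert align_bes(q, index) == []

    def test_agreement_with_sliding_window_oracle(self, index, genome):
        """Hit sets equal the exhaustive sliding-window computation on
        random queries: exact copies, lightly mutated copies, heavily
        mutated copies and unrelated sequence."""
        rng = np.random.default_rng(99)
        for trial in range(30):
            qlen = int(rng.integers(60, 500))
            kind = trial % 4
            if kind == 3:
                q = random_dna(rng, qlen, 0.46)
            else:
                chrom = "chrA" if rng.integers(2) else "chrB"
                start = int(rng.integers(0, len(genome[chrom]) - qlen))
                q = genome[chrom][start : start + qlen]
                if kind == 1:
                    q = _mutate(q, max(1, qlen // 200), rng)
                elif kind == 2:
                    q = _mutate(q, qlen // 20, rng)
                if rng.integers(2):
                    q = revcomp(q)
            got = {
                (h.chrom, h.strand, h.t_start, h.score)
                for h in align_bes(q, index, min_identity=0.99)
            }
            assert got == sliding_hits(q, genome, 0.99)


class TestMask:
    def test_planted_high_copy_repeat_is_masked(self):
        rng = np.random.default_rng(4)
        unit = random_dna(rng, 400, 0.46)
        genome = {"c": "".join(random_dna(rng, 200, 0.46) + unit for _ in range(8))}
        index = GenomeIndex(genome, k=21)
        masked = mask_repeats(unit, index, max_freq=4)
        frac = sum(c.islower() for c in masked) / len(masked)
        assert frac >= 0.9

    def test_unique_sequence_untouched_and_idempotent(self, genome, index):
        q = genome["chrA"][2000:2400]
        once = mask_repeats(q, index, max_freq=4)
        assert once == q
        rng = np.random.default_rng(5)
        unit = random_dna(rng, 300, 0.46)
        rep_genome = {"c": "".join(random_dna(rng, 100, 0.46) + unit for _ in range(10))}
        rep_index = GenomeIndex(rep_genome, k=21)
        m1 = mask_repeats(unit, rep_index, max_freq=4)
        assert mask_repeats(m1, rep_index, max_freq=4) == m1

    def test_masked_bases_excluded_from_alignment(self):
        rng = np.random.default_rng(6)
        unit = random_dna(rng, 300, 0.46)
        flank = random_dna(rng, 300, 0.46)
        genome = {"c": flank + "".join(unit for _ in range(10)) + random_dna(rng, 300, 0.46)}
        index = GenomeIndex(genome, k=21)
        q = mask_repeats(flank[-200:] + unit, index, max_freq=4)
        hits = align_bes(q, index)
        # unmasked flank part still anchors a unique placement
        assert len(hits) == 1
        assert hits[0].t_start == 100


def _hit(chrom="chr1", t=(100, 400), strand="+", score=300, qlen=300):
    return AlignmentHit(
        query_id="q", chrom=chrom, q_start=0, q_end=qlen,
        t_start=t[0], t_end=t[1], strand=strand,
        identity=1.0, q_cov=1.0, score=score,
    )


class TestCull:
    def test_single_hit_classifies_single(self):
        hc = cull_and_classify([_hit()])
        assert hc.classification is HitClassification.SINGLE

    def test_equal_score_hits_at_two_loci_are_multi(self):
        hc = cull_and_classify([_hit(t=(100, 400)), _hit(t=(9000, 9300))])
        assert hc.classification is HitClassification.MULTI
        assert len(hc.hits) == 2

    def test_dominated_hit_is_culled(self):
        strong = _hit(score=300)
        weak = _hit(t=(5000, 5300), score=298)
        hc = cull_and_classify([weak, strong])
        assert hc.classification is HitClassification.SINGLE
        assert hc.hits == [strong]

    def test_diverged_repeat_copies_align_multiply_but_cull_to_best(self, toy_result):
        """A query from a planted repeat copy aligns to several loci at a
        relaxed identity; culling keeps the best-scoring (own) locus, so
        slightly diverged repeats stay single-hit while identical copies
        (previous test) are multi-hit."""
        index = GenomeIndex.from_genome(toy_result.sim.genome, 21)
        chrom, s, e = toy_result.sim.genome.repeat_truth[0]
        q = toy_result.sim.genome.sequences[chrom][s:e]
        raw = align_bes(q, index, min_identity=0.95)
        assert len(raw) >= 2
        hc = cull_and_classify(raw)
        assert hc.classification is HitClassification.SINGLE
        assert hc.hits[0].t_start == s and hc.hits[0].chrom == chrom


class TestPairing:
    def test_inward_pair_under_span_limit_is_paired(self):
        f = _hit(t=(100_000, 100_400), strand="+", qlen=400, score=400)
        r = _hit(t=(220_000, 220_350), strand="-", qlen=350, score=350)
        placed, discards = pair_and_place(
            {W0: {End.FORWARD: [("A" * 400, f)], End.REVERSE: [("C" * 350, r)]}}
        )
        (mc,) = placed[W0]
        assert mc.evidence is Evidence.PAIRED
        assert (mc.start, mc.end, mc.span) == (100_000, 220_350, 120_350)
        assert not discards

    def test_span_at_or_over_limit_falls_back_to_single(self):
        f = _hit(t=(100_000, 100_400), strand="+", qlen=400)
        r = _hit(t=(480_000, 480_350), strand="-", qlen=350)
        placed, discards = pair_and_place(
            {W0: {End.FORWARD: [("A" * 400, f)], End.REVERSE: [("C" * 350, r)]}}
        )
        assert discards["SPAN_EXCEEDED"] == 1
        (mc,) = placed[W0]
        assert mc.evidence is Evidence.SINGLE_FORWARD
        assert (mc.start, mc.end) == (100_000, 100_400)

    def test_same_strand_ends_conflict(self):
        f = _hit(t=(100_000, 100_400), strand="+")
        r = _hit(t=(150_000, 150_300), strand="+")
        _, discards = pair_and_place(
            {W0: {End.FORWARD: [("A" * 300, f)], End.REVERSE: [("C" * 300, r)]}}
        )
        assert discards["STRAND_CONFLICT"] == 1

    def test_outward_facing_opposite_strands_conflict(self):
        # minus-strand hit left of the plus-strand hit: facing away
        f = _hit(t=(200_000, 200_400), strand="+")
        r = _hit(t=(100_000, 100_300), strand="-")
        _, discards = pair_and_place(
            {W0: {End.FORWARD: [("A" * 300, f)], End.REVERSE: [("C" * 300, r)]}}
        )
        assert discards["STRAND_CONFLICT"] == 1

    def test_lone_reverse_end_places_single_reverse(self):
        r = _hit(t=(100_000, 100_300), strand="-")
        placed, _ = pair_and_place({W0: {End.REVERSE: [("C" * 300, r)]}})
        (mc,) = placed[W0]
        assert mc.evidence is Evidence.SINGLE_REVERSE


def _clone(well, chrom, start, end, evidence, source, f_strand="+", seqs=None):
    placements = {}
    seqs = seqs or {}
    if evidence in (Evidence.PAIRED, Evidence.SINGLE_FORWARD):
        placements[End.FORWARD] = _hit(
            chrom=chrom,
            t=(start, start + 300) if f_strand == "+" else (end - 300, end),
            strand=f_strand,
        )
    if evidence in (Evidence.PAIRED, Evidence.SINGLE_REVERSE):
        placements[End.REVERSE] = _hit(
            chrom=chrom,
            t=(end - 300, end) if f_strand == "+" else (start, start + 300),
            strand="-" if f_strand == "+" else "+",
        )
    return MappedClone(
        well=well, chrom=chrom, start=start, end=end,
        evidence=evidence, source=source,
        end_placements=placements, end_seqs=seqs,
    )


class TestIntegrate:
    def test_long_only_well_taken_as_is(self):
        lc = _clone(W0, "chr1", 1000, 6000, Evidence.PAIRED, Source.LONG)
        final, discards = integrate({}, {W0: [lc]})
        assert final == [lc] and not discards

    def test_agreeing_sources_keep_long_coordinates_as_integrated(self):
        sc = _clone(W0, "chr1", 1000, 6020, Evidence.PAIRED, Source.SHORT)
        lc = _clone(W0, "chr1", 1000, 6000, Evidence.PAIRED, Source.LONG)
        final, _ = integrate({W0: [sc]}, {W0: [lc]})
        (mc,) = final
        assert mc.source is Source.INTEGRATED
        assert (mc.start, mc.end) == (1000, 6000)

    def test_single_end_short_agrees_with_paired_long(self):
        sc = _clone(W0, "chr1", 1000, 1300, Evidence.SINGLE_FORWARD, Source.SHORT)
        lc = _clone(W0, "chr1", 1000, 6000, Evidence.PAIRED, Source.LONG)
        final, _ = integrate({W0: [sc]}, {W0: [lc]})
        (mc,) = final
        assert mc.evidence is Evidence.PAIRED
        assert (mc.start, mc.end) == (1000, 6000)

    def test_ambiguous_long_candidates_resolved_by_short_sequence(self):
        """The 32G16-style rescue: two long forward candidates, only the
        one whose sequence matches the short forward BES survives."""
        seq_true = HINDIII + random_dna(np.random.default_rng(12), 2000, 0.46)
        seq_other = HINDIII + random_dna(np.random.default_rng(13), 2000, 0.46)
        a = _clone(W0, "chr1", 1000, 1301, Evidence.SINGLE_FORWARD, Source.LONG,
                   seqs={End.FORWARD: seq_true})
        b = _clone(W0, "chr2", 8000, 8301, Evidence.SINGLE_FORWARD, Source.LONG,
                   seqs={End.FORWARD: seq_other})
        short_seqs = {W0: {End.FORWARD: [seq_true[:400]]}}
        final, discards = integrate({}, {W0: [a, b]}, short_seqs, {})
        (mc,) = final
        assert mc.chrom == "chr1" and mc.source is Source.INTEGRATED
        assert not discards

    def test_irreconcilable_conflict_dropped_and_counted(self):
        sc = _clone(W0, "chr1", 1000, 6000, Evidence.PAIRED, Source.SHORT,
                    seqs={End.FORWARD: "AAGCTT" + "A" * 100})
        lc = _clone(W0, "chr2", 9000, 14_000, Evidence.PAIRED, Source.LONG,
                    seqs={End.FORWARD: "AAGCTT" + "C" * 100})
        final, discards = integrate({W0: [sc]}, {W0: [lc]})
        assert final == []
        assert discards["INTEGRATION_CONFLICT"] == 1


def _wb(well, seq, end=End.FORWARD):
    return WellBes(well=well, end=end, source=Source.SHORT, seq=seq,
                   status=Status.UNIQUE, bes_id="x")


@pytest.fixture(scope="module")
def organelle():
    """A plastid-like genome with HindIII sites planted so that genuine
    insert end sequences (starting with AAGCTT) can be cut from it."""
    rng = np.random.default_rng(20)
    parts = [random_dna(rng, 5000, 0.38) for _ in range(3)]
    seq = parts[0] + HINDIII + parts[1] + HINDIII + parts[2]
    return {"chloroplast": seq}


class TestOrganelle:
    def test_organelle_clone_called_with_paired_evidence(self, organelle):
        org = organelle["chloroplast"]
        site1 = 5000
        site2 = 5000 + 6 + 5000
        insert = org[site1 : site2 + 6]  # AAGCTT ... AAGCTT
        fwd = insert[:400]
        rev = revcomp(insert)[:400]
        calls = screen_organelle(
            {W0: [_wb(W0, fwd), _wb(W0, rev, End.REVERSE)]}, organelle
        )
        (call,) = calls
        assert call.target is OrganelleKind.CHLOROPLAST
        assert call.paired and not call.nuclear_also

    def test_nuclear_clone_not_called(self, organelle, genome):
        q = HINDIII + genome["chrA"][3000:3400]
        assert screen_organelle({W0: [_wb(W0, q)]}, organelle) == []

    def test_transfer_segment_flagged_nuclear_also(self, organelle):
        org = organelle["chloroplast"]
        q = org[5000:5400]  # starts at the planted site: AAGCTT + plastid DNA
        nuclear = {"chrA": random_dna(np.random.default_rng(21), 10_000, 0.46) + org[5000:5600]}
        nuclear_index = GenomeIndex(nuclear, 21)
        calls = screen_organelle(
            {W0: [_wb(W0, q)]}, organelle, nuclear_index=nuclear_index
        )
        (call,) = calls
        assert call.target is OrganelleKind.NUCLEAR_ALSO
        assert call.nuclear_also


class TestGff3:
    @pytest.fixture()
    def clones(self):
        return [
            _clone(W0, "chr1", 1000, 6000, Evidence.PAIRED, Source.INTEGRATED),
            _clone(W1, "chr1", 2000, 2300, Evidence.SINGLE_FORWARD, Source.SHORT),
            _clone(WellAddress(1, 0, 0), "chr0", 500, 5500, Evidence.PAIRED, Source.LONG),
        ]

    def test_line_counts_three_for_paired_two_for_single(self, clones, tmp_path):
        out = tmp_path / "clones.gff3"
        write_gff3(clones, out, LAYOUT)
        lines = [l for l in out.read_text().splitlines() if l and not l.startswith("#")]
        assert len(lines) == 3 + 2 + 3
        paired_block = [l for l in lines if "bac-01A01" in l]
        assert len(paired_block) == 3

    def test_output_sorted_with_parents_first(self, clones, tmp_path):
        out = tmp_path / "clones.gff3"
        write_gff3(clones, out, LAYOUT)
        rows = [
            l.split("\t")
            for l in out.read_text().splitlines()
            if l and not l.startswith("#")
        ]
        parent_keys = [
            (r[0], int(r[3])) for r in rows if r[2] == "BAC_clone"
        ]
        assert parent_keys == sorted(parent_keys)
        seen_parents = set()
        for r in rows:
            attrs = dict(kv.split("=", 1) for kv in r[8].split(";"))
            if r[2] == "BAC_clone":
                seen_parents.add(attrs["ID"])
            else:
                assert attrs["Parent"] in seen_parents

    def test_round_trip_preserves_intervals(self, clones, tmp_path):
        out = tmp_path / "clones.gff3"
        write_gff3(clones, out, LAYOUT)
        recs = read_gff3(out)
        got = {(r["Name"], r["chrom"], r["start"], r["end"]) for r in recs}
        want = {
            (LAYOUT.well_label(c.well), c.chrom, c.start, c.end) for c in clones
        }
        assert got == want
        for rec in recs:
            n_children = len(rec["children"])
            assert n_children == (2 if rec["evidence"] == "PAIRED" else 1)
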