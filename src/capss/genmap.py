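"""Anchoring well-assigned end sequences on a reference genome.

The alignment contract mirrors stringent blastn-style mapping: a hit must
cover the (unmasked part of the) whole query at >= 99% identity, near-
identical hits are culled so each query is classified as single-hit or
multi-hit, and clones are placed from their ends — paired when forward
and reverse land on one chromosome, on opposite strands facing inward,
within a 250 kb span (three GFF3 lines), single otherwise (two lines).

Because the upstream error model is substitution-only, alignment is
ungapped: every candidate placement aligns the full query on one
diagonal, which keeps the hit set exactly reproducible by an exhaustive
sliding-window computation.  Coordinates are 0-based half-open
throughout; the GFF3 writer is the only 1-based surface.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from .assign import Source, WellBes
from .bes_short import End
from .pool_design import SuperpoolLayout, WellAddress
from .seq import canonical_kmer, revcomp, seq_array
from .simulate import SyntheticGenome


class HitClassification(str, Enum):
    NONE = "NONE"
    SINGLE = "SINGLE"
    MULTI = "MULTI"


class Evidence(str, Enum):
    PAIRED = "PAIRED"
    SINGLE_FORWARD = "SINGLE_FORWARD"
    SINGLE_REVERSE = "SINGLE_REVERSE"


class OrganelleKind(str, Enum):
    CHLOROPLAST = "CHLOROPLAST"
    MITOCHONDRION = "MITOCHONDRION"
    NUCLEAR_ALSO = "NUCLEAR_ALSO"


@dataclass(frozen=True)
class AlignmentHit:
    """One placement of a query on the target: full-query, one diagonal."""

    query_id: str
    chrom: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    identity: float
    q_cov: float
    score: int


@dataclass
class HitClass:
    query_id: str
    classification: HitClassification
    hits: list[AlignmentHit]


@dataclass
class MappedClone:
    """A clone anchored on a chromosome interval by one or both ends."""

    well: WellAddress
    chrom: str
    start: int
    end: int
    evidence: Evidence
    source: Source
    end_placements: dict[End, AlignmentHit] = field(default_factory=dict)
    end_seqs: dict[End, str] = field(default_factory=dict)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class OrganelleCall:
    well: WellAddress
    target: OrganelleKind
    organelle: str
    ends: list[End]
    paired: bool
    nuclear_also: bool


class GenomeIndex:
    """Exact k-mer seed index over a set of target sequences.

    Holds byte arrays for fast ungapped verification, seed positions for
    every k-mer not containing N, and genome-wide canonical k-mer counts
    (used by repeat masking).
    """

    def __init__(self, sequences: dict[str, str], k: int = 21):
        if not sequences:
            raise ValueError("empty target sequence set")
        self.k = k
        self.names = sorted(sequences)
        self.seqs = {name: sequences[name].upper() for name in self.names}
        self.arrays = {name: seq_array(self.seqs[name]) for name in self.names}
        self.lengths = {name: len(self.seqs[name]) for name in self.names}
        self.positions: dict[str, list[tuple[str, int]]] = {}
        self.counts: Counter[str] = Counter()
        for name in self.names:
            seq = self.seqs[name]
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if "N" in km:
                    continue
                self.positions.setdefault(km, []).append((name, i))
                self.counts[canonical_kmer(km)] += 1

    @classmethod
    def from_genome(cls, genome: SyntheticGenome | dict[str, str], k: int = 21) -> "GenomeIndex":
        seqs = genome.sequences if isinstance(genome, SyntheticGenome) else genome
        return cls(seqs, k)


def mask_repeats(bes_seq: str, genome_index: GenomeIndex, max_freq: int = 4) -> str:
    """Lowercase bases supported only by high-frequency genome k-mers.

    A base is masked when every k-mer of the query covering it occurs
    more than ``max_freq`` times in the genome (counting both strands);
    a single covering low-frequency k-mer rescues the base.  Masked bases
    are excluded from alignment seeding and from both the numerator and
    denominator of identity.  Idempotent.
    """
    k = genome_index.k
    seq = bes_seq.upper()
    n = len(seq)
    if n < k:
        return seq
    repetitive = np.zeros(n - k + 1, dtype=bool)
    for i in range(n - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        repetitive[i] = genome_index.counts.get(canonical_kmer(km), 0) > max_freq
    masked = np.zeros(n, dtype=bool)
    covered = np.zeros(n, dtype=bool)
    low = np.zeros(n, dtype=bool)
    for i, rep in enumerate(repetitive):
        covered[i : i + k] = True
        if not rep:
            low[i : i + k] = True
    masked = covered & ~low
    out = "".join(c.lower() if m else c for c, m in zip(seq, masked))
    return out


def align_bes(
    query: str,
    genome: GenomeIndex | SyntheticGenome | dict[str, str],
    min_identity: float = 0.99,
    min_qcov: float = 0.99,
    seed_k: int = 21,
    query_id: str = "query",
    min_unmasked: int = 50,
) -> list[AlignmentHit]:
    """All qualifying placements of a query on the target sequences.

    Exact ``seed_k``-mer seeds on both strands propose diagonals; every
    distinct diagonal placing the full query inside a target sequence is
    verified ungapped.  Identity is computed over unmasked (uppercase,
    non-N) query positions only, and a hit is reported when identity >=
    ``min_identity`` and the aligned unmasked fraction >= ``min_qcov``.
    Queries with fewer than ``min_unmasked`` unmasked bases are not
    aligned.  Hits come back sorted by descending score.
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex.from_genome(genome, seed_k)
    k = index.k
    qlen = len(query)
    hits: list[AlignmentHit] = []
    for strand in ("+", "-"):
        q = query if strand == "+" else revcomp(query)
        q_upper = q.upper()
        q_arr = seq_array(q_upper)
        unmasked = np.array([c.isupper() and c != "N" for c in q], dtype=bool)
        denom = int(unmasked.sum())
        if denom < min_unmasked:
            continue
        diagonals: set[tuple[str, int]] = set()
        for i in range(qlen - k + 1):
            if not unmasked[i : i + k].all():
                continue
            for chrom, pos in index.positions.get(q_upper[i : i + k], ()):
                diagonals.add((chrom, pos - i))
        for chrom, t_start in sorted(diagonals):
            if t_start < 0 or t_start + qlen > index.lengths[chrom]:
                continue
            window = index.arrays[chrom][t_start : t_start + qlen]
            agree = (window == q_arr) & unmasked
            score = int(agree.sum())
            identity = score / denom
            q_cov = 1.0  # full-query diagonal placement; masked bases excluded
            if identity >= min_identity and q_cov >= min_qcov:
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        chrom=chrom,
                        q_start=0,
                        q_end=qlen,
                        t_start=t_start,
                        t_end=t_start + qlen,
                        strand=strand,
                        identity=identity,
                        q_cov=q_cov,
                        score=score,
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.chrom, h.t_start, h.strand))
    return hits


def cull_and_classify(hits: list[AlignmentHit], culling_overlap: float = 0.5) -> HitClass:
    """Remove query-interval-dominated hits; classify by survivor count.

    A hit is culled when a strictly higher-scoring kept hit overlaps at
    least ``culling_overlap`` of its query interval (with full-query
    hits, any strictly better hit dominates); co-optimal hits survive
    together and make the query multi-hit.
    """
    ordered = sorted(hits, key=lambda h: (-h.score, h.chrom, h.t_start, h.strand))
    kept: list[AlignmentHit] = []
    for h in ordered:
        span = h.q_end - h.q_start
        dominated = False
        for k_hit in kept:
            if k_hit.score <= h.score:
                continue
            ov = min(h.q_end, k_hit.q_end) - max(h.q_start, k_hit.q_start)
            if span > 0 and ov / span >= culling_overlap:
                dominated = True
                break
        if not dominated:
            kept.append(h)
    if not kept:
        cls = HitClassification.NONE
    elif len(kept) == 1:
        cls = HitClassification.SINGLE
    else:
        cls = HitClassification.MULTI
    qid = hits[0].query_id if hits else ""
    return HitClass(query_id=qid, classification=cls, hits=kept)


EndCandidate = tuple[str, AlignmentHit]  # (bes sequence, its unique placement)


def _valid_pair(
    f: AlignmentHit, r: AlignmentHit, max_span: int
) -> tuple[bool, str]:
    """Apply the paired-placement rule; on failure name the reason."""
    if f.chrom != r.chrom:
        return False, "CHROM_CONFLICT"
    if f.strand == r.strand:
        return False, "STRAND_CONFLICT"
    plus, minus = (f, r) if f.strand == "+" else (r, f)
    if plus.t_start > minus.t_start:
        return False, "STRAND_CONFLICT"  # opposite strands but facing outward
    span = minus.t_end - plus.t_start
    if span >= max_span:
        return False, "SPAN_EXCEEDED"
    return True, ""


def pair_and_place(
    well_hits: dict[WellAddress, dict[End, list[EndCandidate]]],
    max_span: int = 250_000,
    source: Source = Source.SHORT,
    fallback_single: bool = True,
) -> tuple[dict[WellAddress, list[MappedClone]], Counter]:
    """Candidate clone placements per well from uniquely mapped ends.

    Candidates must already be single-hit placements.  A forward/reverse
    combination placed on one chromosome, opposite strands facing inward
    and spanning less than ``max_span`` gives a PAIRED clone interval;
    when no combination pairs, a uniquely-placed lone end gives a SINGLE
    placement (preferring the forward end when both ends exist but
    conflict, if ``fallback_single``).  Wells may return several
    candidates when their assigned end sequences were ambiguous;
    downstream integration or finalization resolves or drops them.
    """
    out: dict[WellAddress, list[MappedClone]] = {}
    discards: Counter = Counter()
    for well in sorted(well_hits):
        ends = well_hits[well]
        fwd = ends.get(End.FORWARD, [])
        rev = ends.get(End.REVERSE, [])
        candidates: list[MappedClone] = []
        fail_reasons: set[str] = set()
        for f_seq, f_hit in fwd:
            for r_seq, r_hit in rev:
                ok, reason = _valid_pair(f_hit, r_hit, max_span)
                if not ok:
                    fail_reasons.add(reason)
                    continue
                plus, minus = (f_hit, r_hit) if f_hit.strand == "+" else (r_hit, f_hit)
                candidates.append(
                    MappedClone(
                        well=well,
                        chrom=f_hit.chrom,
                        start=plus.t_start,
                        end=minus.t_end,
                        evidence=Evidence.PAIRED,
                        source=source,
                        end_placements={End.FORWARD: f_hit, End.REVERSE: r_hit},
                        end_seqs={End.FORWARD: f_seq, End.REVERSE: r_seq},
                    )
                )
        if not candidates:
            for reason in fail_reasons:
                discards[reason] += 1
            single_pool: list[tuple[End, EndCandidate]] = []
            if fwd and not rev:
                single_pool = [(End.FORWARD, c) for c in fwd]
            elif rev and not fwd:
                single_pool = [(End.REVERSE, c) for c in rev]
            elif fwd and rev and fallback_single:
                # both ends mapped but irreconcilable: demote, forward first
                if len(fwd) == 1:
                    single_pool = [(End.FORWARD, fwd[0])]
                elif len(rev) == 1:
                    single_pool = [(End.REVERSE, rev[0])]
            for end, (seq, hit) in single_pool:
                candidates.append(
                    MappedClone(
                        well=well,
                        chrom=hit.chrom,
                        start=hit.t_start,
                        end=hit.t_end,
                        evidence=(
                            Evidence.SINGLE_FORWARD
                            if end is End.FORWARD
                            else Evidence.SINGLE_REVERSE
                        ),
                        source=source,
                        end_placements={end: hit},
                        end_seqs={end: seq},
                    )
                )
        if candidates:
            out[well] = candidates
    return out, discards


def _placements_agree(a: MappedClone, b: MappedClone, tol: int = 1000) -> bool:
    """Agreement is judged on the ends both placements actually anchor:
    same chromosome, same strand and start within ``tol`` for every shared
    end (so a single-end placement agrees with the paired placement that
    contains it)."""
    if a.chrom != b.chrom:
        return False
    shared = set(a.end_placements) & set(b.end_placements)
    if not shared:
        return False
    for end in shared:
        ha, hb = a.end_placements[end], b.end_placements[end]
        if ha.strand != hb.strand:
            return False
        # the junction-anchored coordinate: a hit's t_start on + strand,
        # its t_end on - strand (hits of different lengths share it)
        ja = ha.t_start if ha.strand == "+" else ha.t_end
        jb = hb.t_start if hb.strand == "+" else hb.t_end
        if abs(ja - jb) > tol:
            return False
    return True


def _informativeness(c: MappedClone) -> tuple:
    """Ranking used when agreeing placements must be collapsed to one:
    paired evidence beats single-end, long-source coordinates beat short."""
    return (
        c.evidence is Evidence.PAIRED,
        c.source is Source.LONG,
        c.span,
        c.chrom,
        -c.start,
    )


def _seq_agrees(a: str, b: str, min_identity: float) -> bool:
    from .seq import anchored_identity

    return anchored_identity(a, b) >= min_identity


def _cross_validated(
    cand: MappedClone, other_seqs: dict[End, list[str]], min_identity: float
) -> bool:
    for end, seq in cand.end_seqs.items():
        if any(_seq_agrees(seq, o, min_identity) for o in other_seqs.get(end, [])):
            return True
    return False


def integrate(
    short_candidates: dict[WellAddress, list[MappedClone]],
    long_candidates: dict[WellAddress, list[MappedClone]],
    short_seqs: dict[WellAddress, dict[End, list[str]]] | None = None,
    long_seqs: dict[WellAddress, dict[End, list[str]]] | None = None,
    min_agreement_identity: float = 0.99,
) -> tuple[list[MappedClone], Counter]:
    """Merge short-source and long-source placements per well.

    Wells seen by one source only are taken as-is (a unique candidate is
    required).  Wells seen by both keep the long-source coordinates when
    the placements agree (same chromosome and strands, boundaries within
    1 kb).  When they conflict — or when one source offers several
    ambiguous candidates — cross-evidence decides: a candidate whose end
    sequence matches the other source's sequence for that end (anchored
    identity >= ``min_agreement_identity`` over the shorter) wins if it
    is the only validated one; irreconcilable wells are dropped and
    counted.  ``short_seqs``/``long_seqs`` supply assigned-but-unplaced
    end sequences so sequence evidence can rescue wells whose other
    source never produced a placement.
    """
    short_seqs = short_seqs or {}
    long_seqs = long_seqs or {}
    final: list[MappedClone] = []
    discards: Counter = Counter()

    def as_integrated(c: MappedClone) -> MappedClone:
        return MappedClone(
            well=c.well,
            chrom=c.chrom,
            start=c.start,
            end=c.end,
            evidence=c.evidence,
            source=Source.INTEGRATED,
            end_placements=dict(c.end_placements),
            end_seqs=dict(c.end_seqs),
        )

    for well in sorted(set(short_candidates) | set(long_candidates)):
        s_cands = short_candidates.get(well, [])
        l_cands = long_candidates.get(well, [])
        if s_cands and l_cands:
            agreeing: list[MappedClone] = []
            for s in s_cands:
                for l in l_cands:
                    if _placements_agree(s, l):
                        agreeing.extend((s, l))
            if agreeing:
                final.append(as_integrated(max(agreeing, key=_informativeness)))
                continue
            pool = s_cands + l_cands
            validated = []
            for c in pool:
                other = short_seqs.get(well, {}) if c.source is Source.LONG else long_seqs.get(well, {})
                if _cross_validated(c, other, min_agreement_identity):
                    validated.append(c)
            if len(validated) == 1:
                final.append(as_integrated(validated[0]))
            else:
                discards["INTEGRATION_CONFLICT"] += 1
        else:
            cands = s_cands or l_cands
            if len(cands) == 1:
                final.append(cands[0])
                continue
            # single-source ambiguity: sequence evidence from the other
            # source's assignments may still single out one candidate
            other = short_seqs.get(well, {}) if cands is l_cands else long_seqs.get(well, {})
            validated = [
                c for c in cands if _cross_validated(c, other, min_agreement_identity)
            ]
            if len(validated) == 1:
                final.append(as_integrated(validated[0]))
            else:
                discards["INTEGRATION_CONFLICT"] += 1
    return final, discards


def screen_organelle(
    assignments: dict[WellAddress, list[WellBes]],
    organelle_genomes: dict[str, str],
    min_identity: float = 0.99,
    min_qcov: float = 0.99,
    seed_k: int = 21,
    kinds: dict[str, OrganelleKind] | None = None,
    nuclear_index: GenomeIndex | None = None,
) -> list[OrganelleCall]:
    """Identify wells whose end sequences trace to organelle genomes.

    Uses the same stringent alignment contract as nuclear anchoring.
    Wells with hits from both ends are flagged as paired evidence; an
    end sequence that also places on the nuclear genome marks the call
    NUCLEAR_ALSO (organelle-to-nucleus transfer or coincidental
    similarity).  Organelle kind is inferred from the sequence name
    unless ``kinds`` says otherwise.
    """
    if not organelle_genomes:
        raise ValueError("no organelle genomes provided")

    def kind_of(name: str) -> OrganelleKind:
        if kinds and name in kinds:
            return kinds[name]
        low = name.lower()
        if "mito" in low:
            return OrganelleKind.MITOCHONDRION
        return OrganelleKind.CHLOROPLAST

    index = GenomeIndex(organelle_genomes, seed_k)
    calls: list[OrganelleCall] = []
    for well in sorted(assignments):
        per_org: dict[str, set[End]] = {}
        nuclear_also = False
        for bes in assignments[well]:
            hits = align_bes(
                bes.seq, index, min_identity=min_identity, min_qcov=min_qcov,
                query_id=bes.bes_id,
            )
            for h in hits:
                per_org.setdefault(h.chrom, set()).add(bes.end)
            if hits and nuclear_index is not None:
                if align_bes(
                    bes.seq, nuclear_index, min_identity=min_identity,
                    min_qcov=min_qcov, query_id=bes.bes_id,
                ):
                    nuclear_also = True
        for org in sorted(per_org):
            ends = sorted(per_org[org], key=lambda e: e.value)
            calls.append(
                OrganelleCall(
                    well=well,
                    target=OrganelleKind.NUCLEAR_ALSO if nuclear_also else kind_of(org),
                    organelle=org,
                    ends=ends,
                    paired=len(ends) == 2,
                    nuclear_also=nuclear_also,
                )
            )
    return calls


# --- GFF3 emission -------------------------------------------------------


def write_gff3(
    mapped_clones: list[MappedClone],
    out: str | Path,
    layout: SuperpoolLayout,
    source: str = "capss",
) -> None:
    """Write placed clones as sorted GFF3: 3 lines per paired clone
    (parent interval + one line per end), 2 per single-end clone.

    GFF3 is 1-based inclusive; this writer is the only place the
    internal half-open coordinates are converted.  Output is sorted by
    chromosome then start, parents before their children.
    """
    blocks = []
    for mc in sorted(mapped_clones, key=lambda m: (m.chrom, m.start, m.well)):
        label = layout.well_label(mc.well)
        parent_id = f"bac-{label}"
        lines = [
            "\t".join(
                [
                    mc.chrom,
                    source,
                    "BAC_clone",
                    str(mc.start + 1),
                    str(mc.end),
                    ".",
                    ".",
                    ".",
                    f"ID={parent_id};Name={label};evidence={mc.evidence.value};"
                    f"source_set={mc.source.value}",
                ]
            )
        ]
        for end in (End.FORWARD, End.REVERSE):
            hit = mc.end_placements.get(end)
            if hit is None:
                continue
            suffix = "F" if end is End.FORWARD else "R"
            lines.append(
                "\t".join(
                    [
                        mc.chrom,
                        source,
                        "BAC_end",
                        str(hit.t_start + 1),
                        str(hit.t_end),
                        ".",
                        hit.strand,
                        ".",
                        f"ID={parent_id}.{suffix};Parent={parent_id};"
                        f"Name={label}/{end.value.lower()}",
                    ]
                )
            )
        blocks.append(lines)
    with open(out, "w") as f:
        f.write("##gff-version 3\n")
        for lines in blocks:
            f.write("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[dict]:
    """Parse a clone GFF3 back into parent/child records (1-based converted
    back to 0-based half-open), for round-trip checks."""
    parents: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as f:
        for line in f:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            rec = {
                "chrom": chrom,
                "type": ftype,
                "start": int(start) - 1,
                "end": int(end),
                "strand": strand,
                **fields,
            }
            if ftype == "BAC_clone":
                rec["children"] = []
                parents[rec["ID"]] = rec
                order.append(rec["ID"])
            else:
                parents[rec["Parent"]]["children"].append(rec)
    return [parents[i] for i in order]
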