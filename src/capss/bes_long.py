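"""Long BES pathway: per-pool assembly and junction-contig trimming.

Pool reads are assembled into contigs by iterative unambiguous
suffix-prefix merging; contigs that run through a vector border are
trimmed to the insert side of the HindIII junction, yielding end
sequences on the kilobase scale (versus the fragment-scale short BESs).

The built-in assembler is a greedy overlap merger intended for
simulated/desk-scale pools: substitution-tolerant, deterministic, and
honest about branches (any disagreeing extension stops a contig, so
repeat boundaries and vector junctions truncate rather than chimerize).
Externally assembled contig FASTA per pool is accepted in its place for
production-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pool_design import PoolRef
from .preprocess import PoolReadSet
from .seq import HINDIII, anchored_identity, matches, revcomp
from .simulate import VectorModel
from .bes_short import End, junction_anchors


@dataclass
class Contig:
    pool: PoolRef
    contig_id: str
    seq: str
    n_reads: int


@dataclass
class LongBes:
    """A vector-trimmed contig end sequence (starts with AAGCTT).

    ``both_ends`` flags contigs that spanned a whole insert and carried
    the junction of each vector border.
    """

    pool: PoolRef
    end: End
    seq: str
    contig_id: str
    both_ends: bool = False

    def __post_init__(self):
        if not self.seq.startswith(HINDIII):
            raise ValueError("long BES must start with the HindIII site")


class _Assembler:
    """Greedy unambiguous overlap-merge assembly of one pool's reads."""

    def __init__(self, seqs: list[str], min_overlap: int, min_identity: float):
        self.min_overlap = min_overlap
        self.min_identity = min_identity
        self.reads = seqs
        self.rc = [revcomp(s) for s in seqs]
        self.used = [False] * len(seqs)
        self.max_len = max((len(s) for s in seqs), default=0)
        self.prefix_index: dict[str, list[tuple[int, bool]]] = {}
        for i, s in enumerate(seqs):
            if len(s) >= min_overlap:
                self.prefix_index.setdefault(s[:min_overlap], []).append((i, False))
                self.prefix_index.setdefault(self.rc[i][:min_overlap], []).append((i, True))

    def _oriented(self, idx: int, is_rc: bool) -> str:
        return self.rc[idx] if is_rc else self.reads[idx]

    def _extend_right(self, contig: str) -> tuple[str, int]:
        """Extend while exactly one (consistent) continuation exists.

        At each step every unused read whose prefix seed matches a suffix
        window of the contig is checked over its full overlap; reads fully
        contained in the contig are consumed, and the longest verified
        extension is applied unless another candidate extension disagrees
        with it beyond the error tolerance (a branch), which stops the
        contig.  Returns the extended contig and the number of reads consumed.
        """
        consumed = 0
        k = self.min_overlap
        while True:
            L = len(contig)
            ext_cands: list[tuple[str, int]] = []
            for w in range(max(0, L - self.max_len + 1), L - k + 1):
                for idx, is_rc in self.prefix_index.get(contig[w : w + k], ()):
                    if self.used[idx]:
                        continue
                    s = self._oriented(idx, is_rc)
                    ov = min(len(s), L - w)
                    if ov < k:
                        continue
                    if matches(contig[w : w + ov], s[:ov]) / ov < self.min_identity:
                        continue
                    if w + len(s) <= L:
                        self.used[idx] = True  # contained
                        consumed += 1
                    else:
                        ext_cands.append((s[ov:], idx))
            if not ext_cands:
                return contig, consumed
            ext_cands.sort(key=lambda c: (-len(c[0]), c[0], c[1]))
            best_ext, best_idx = ext_cands[0]
            for ext, _ in ext_cands[1:]:
                n = min(len(ext), len(best_ext))
                mm = n - matches(ext[:n], best_ext[:n])
                if mm >= 2 and (n - mm) / n < self.min_identity:
                    return contig, consumed  # ambiguous branch
            contig += best_ext
            self.used[best_idx] = True
            consumed += 1

    def _containment_sweep(self, contig: str) -> int:
        """Consume leftover reads that map inside a finished contig.

        Reads whose seed landed on an embedded error never matched during
        extension; three probe k-mers per orientation recover them so they
        cannot seed redundant copies of the same region.
        """
        k = self.min_overlap
        if len(contig) < k:
            return 0
        pos_index: dict[str, int] = {}
        for p in range(len(contig) - k + 1):
            pos_index.setdefault(contig[p : p + k], p)
        consumed = 0
        for idx in range(len(self.reads)):
            if self.used[idx]:
                continue
            for is_rc in (False, True):
                s = self._oriented(idx, is_rc)
                if len(s) < k:
                    continue
                offsets = {0, (len(s) - k) // 2, len(s) - k}
                placed = False
                for off in offsets:
                    p = pos_index.get(s[off : off + k])
                    if p is None:
                        continue
                    start = p - off
                    if start < 0 or start + len(s) > len(contig):
                        continue
                    region = contig[start : start + len(s)]
                    if matches(region, s) / len(s) >= self.min_identity:
                        self.used[idx] = True
                        consumed += 1
                        placed = True
                        break
                if placed:
                    break
        return consumed

    def run(self, pool: PoolRef) -> list[Contig]:
        contigs: list[Contig] = []
        order = sorted(range(len(self.reads)), key=lambda i: self.reads[i])
        for i in order:
            if self.used[i]:
                continue
            self.used[i] = True
            n_reads = 1
            contig, c = self._extend_right(self.reads[i])
            n_reads += c
            contig, c = self._extend_right(revcomp(contig))
            n_reads += c
            contig = revcomp(contig)
            n_reads += self._containment_sweep(contig)
            contigs.append(
                Contig(
                    pool=pool,
                    contig_id=f"{pool.axis.value}{pool.index:03d}.c{len(contigs):04d}",
                    seq=contig,
                    n_reads=n_reads,
                )
            )
        return contigs


def assemble_pool(
    pool_read_set: PoolReadSet, min_overlap: int = 40, min_identity: float = 0.98
) -> list[Contig]:
    """Assemble one pool's valid reads into contigs by greedy overlap merging.

    Reads (both mates, both strands) are merged iteratively wherever a
    suffix-prefix overlap of at least ``min_overlap`` bases at
    ``min_identity`` identity extends a contig unambiguously; branches
    stop extension.  Input reads are sorted first, so the result is
    deterministic.  Reads containing N (gap-spanning) are unusable and
    dropped.
    """
    seqs = sorted(
        s
        for rp in pool_read_set.pairs
        for s in (rp.seq1, rp.seq2)
        if len(s) >= min_overlap and "N" not in s
    )
    return _Assembler(seqs, min_overlap, min_identity).run(pool_read_set.pool)


def extract_long_bes(
    contigs: list[Contig],
    vector: VectorModel,
    min_vector_anchor: int = 20,
    dedupe_identity: float = 0.99,
) -> list[LongBes]:
    """Trim junction-bearing contigs to long end sequences.

    A contig qualifies when (in either orientation) it contains at least
    ``min_vector_anchor`` bases of a vector border immediately followed
    by AAGCTT; vector bases are removed on both sides, the orientation is
    normalized vector -> insert, and a contig carrying both junctions is
    emitted once per end and flagged.  Near-duplicate end sequences from
    redundant contigs of one pool are collapsed onto the longest.
    """
    anchors = junction_anchors(vector, min_vector_anchor)
    leading = {end: anchor + HINDIII for end, anchor in anchors.items()}
    trailing = {
        End.FORWARD: HINDIII + vector.right_flank[:min_vector_anchor],
        End.REVERSE: HINDIII + revcomp(vector.left_flank[-min_vector_anchor:]),
    }
    raw: list[LongBes] = []
    for contig in contigs:
        found: list[tuple[End, str]] = []
        for oriented in (contig.seq, revcomp(contig.seq)):
            for end, probe in leading.items():
                p = oriented.find(probe)
                if p == -1:
                    continue
                bes = oriented[p + min_vector_anchor :]
                q = bes.find(trailing[end], 1)
                if q != -1:
                    bes = bes[: q + len(HINDIII)]
                if len(bes) >= len(HINDIII) and (end, bes) not in found:
                    found.append((end, bes))
        for end, bes in found:
            raw.append(
                LongBes(
                    pool=contig.pool,
                    end=end,
                    seq=bes,
                    contig_id=contig.contig_id,
                    both_ends=len({e for e, _ in found}) == 2,
                )
            )
    # collapse redundant near-identical end sequences per (pool, end)
    out: list[LongBes] = []
    groups: dict[tuple[PoolRef, End], list[LongBes]] = {}
    for lb in raw:
        groups.setdefault((lb.pool, lb.end), []).append(lb)
    for _, group in sorted(groups.items(), key=lambda kv: kv[0]):
        group.sort(key=lambda lb: (-len(lb.seq), lb.seq))
        kept: list[LongBes] = []
        for lb in group:
            if any(
                anchored_identity(lb.seq, k.seq) >= dedupe_identity for k in kept
            ):
                continue
            kept.append(lb)
        out.extend(kept)
    return out


def n50(lengths: list[int]) -> int:
    """The largest L such that pieces of length >= L sum to at least half
    the total assembled length."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if 2 * acc >= total:
            return x
    raise AssertionError("unreachable")
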