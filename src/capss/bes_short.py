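"""Short BES pathway: vector-junction reads to consensus end sequences.

A clone's end sequence begins exactly at the HindIII site where the
insert meets the vector, so any read spanning a vector border into the
insert pins the end sequence precisely.  Per pool and per end, junction
reads are clustered on their insert-side prefixes (which all share the
AAGCTT anchor), a majority-vote consensus is called on every cluster
with enough support, and mates of the clustered reads extend the
consensus beyond single-read reach — giving end sequences on the scale
of the sequencing-library fragment size.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .pool_design import PoolRef
from .preprocess import PoolReadSet
from .seq import HINDIII, anchored_identity, revcomp, seq_array
from .simulate import VectorModel


class End(str, Enum):
    FORWARD = "FORWARD"
    REVERSE = "REVERSE"


@dataclass
class JunctionRead:
    """A read spanning a vector border into the insert, reoriented
    vector -> insert; ``insert_seq`` begins with AAGCTT and ``mate_seq``
    is the raw mate (orientation resolved later, during extension)."""

    pool: PoolRef
    end: End
    vector_len: int
    insert_seq: str
    mate_seq: str


@dataclass
class Consensus:
    """Majority-vote consensus of one junction-read cluster."""

    pool: PoolRef
    end: End
    seq: str
    support: int


@dataclass
class ShortBes:
    """A vector-trimmed short end sequence (starts with AAGCTT)."""

    pool: PoolRef
    end: End
    seq: str
    support: int

    def __post_init__(self):
        if not self.seq.startswith(HINDIII):
            raise ValueError("short BES must start with the HindIII site")


def junction_anchors(vector: VectorModel, min_vector_anchor: int) -> dict[End, str]:
    """The vector-side search strings immediately preceding each junction,
    read in vector -> insert orientation."""
    return {
        End.FORWARD: vector.left_flank[-min_vector_anchor:],
        End.REVERSE: revcomp(vector.right_flank[:min_vector_anchor]),
    }


def find_junction_reads(
    pool_read_set: PoolReadSet,
    vector: VectorModel,
    min_vector_anchor: int = 20,
) -> list[JunctionRead]:
    """Extract reads spanning a vector border into the insert.

    A read (in either orientation) qualifies for the FORWARD end when it
    contains at least ``min_vector_anchor`` terminal bases of the left
    vector flank immediately followed by AAGCTT, and symmetrically for
    the REVERSE end with the right flank.  The qualifying orientation is
    vector -> insert; the mate is carried along for consensus extension.
    """
    anchors = junction_anchors(vector, min_vector_anchor)
    probes = {end: anchor + HINDIII for end, anchor in anchors.items()}
    out: list[JunctionRead] = []
    for rp in pool_read_set.pairs:
        for seq, mate in ((rp.seq1, rp.seq2), (rp.seq2, rp.seq1)):
            for oriented in (seq, revcomp(seq)):
                hit = None
                for end, probe in probes.items():
                    p = oriented.find(probe)
                    if p != -1:
                        hit = (end, p)
                        break
                if hit is None:
                    continue
                end, p = hit
                junction = p + min_vector_anchor
                insert_seq = oriented[junction:]
                if len(insert_seq) >= len(HINDIII):
                    out.append(
                        JunctionRead(
                            pool=pool_read_set.pool,
                            end=end,
                            vector_len=junction,
                            insert_seq=insert_seq,
                            mate_seq=mate,
                        )
                    )
                break  # one qualifying orientation per mate
    return out


def _majority_consensus(seqs: list[str], min_depth: int) -> str:
    """Column-wise majority over AAGCTT-anchored sequences, extended as far
    as at least ``min_depth`` sequences cover each column.  Ties break to
    the lexicographically smallest base."""
    width = max(len(s) for s in seqs)
    mat = np.zeros((len(seqs), width), dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = seq_array(s)
    cons = []
    for col in range(width):
        column = mat[:, col]
        column = column[column != 0]
        if len(column) < min_depth:
            break
        values, counts = np.unique(column, return_counts=True)
        cons.append(chr(int(values[np.argmax(counts)])))
    return "".join(cons)


def _extend_with_mates(
    consensus: str, mates: list[str], min_mate_overlap: int = 30
) -> str:
    """Greedy extension of the consensus by mates that overlap its tail
    exactly.  Mates are placed (in whichever orientation fits) where at
    least ``min_mate_overlap`` bases match the consensus suffix exactly;
    the longest resulting extension is applied first and placement
    repeats until no mate extends further."""
    remaining = sorted(set(mates), reverse=True)
    while True:
        best_ext = ""
        best_mate = None
        for mate in remaining:
            for oriented in (mate, revcomp(mate)):
                if len(oriented) < min_mate_overlap:
                    continue
                probe = oriented[:min_mate_overlap]
                p = consensus.find(probe, max(0, len(consensus) - len(oriented)))
                if p == -1:
                    continue
                ov = len(consensus) - p
                if consensus[p:] == oriented[:ov]:
                    ext = oriented[ov:]
                    if len(ext) > len(best_ext):
                        best_ext, best_mate = ext, mate
        if not best_ext:
            return consensus
        consensus += best_ext
        remaining.remove(best_mate)


def cluster_and_consensus(
    junction_reads: list[JunctionRead],
    min_overlap: int = 50,
    min_identity: float = 0.95,
    min_depth: int = 3,
) -> list[Consensus]:
    """Cluster junction reads per (pool, end) and call one consensus per cluster.

    Because every insert-side prefix starts at the same AAGCTT anchor,
    clustering reduces to anchored prefix comparison: reads join a
    cluster when they agree with its longest read at ``min_identity``
    over at least ``min_overlap`` bases.  Clusters below ``min_depth``
    are dropped (this is what rejects singleton chimeras); mates of the
    clustered reads then extend each consensus tail.
    """
    groups: dict[tuple[PoolRef, End], list[JunctionRead]] = {}
    for jr in junction_reads:
        groups.setdefault((jr.pool, jr.end), []).append(jr)

    out: list[Consensus] = []
    for (pool, end), reads in sorted(groups.items(), key=lambda kv: kv[0]):
        usable = [r for r in reads if len(r.insert_seq) >= min_overlap]
        usable.sort(key=lambda r: (-len(r.insert_seq), r.insert_seq))
        clusters: list[list[JunctionRead]] = []
        for jr in usable:
            for cluster in clusters:
                rep = cluster[0].insert_seq
                if (
                    min(len(rep), len(jr.insert_seq)) >= min_overlap
                    and anchored_identity(rep, jr.insert_seq) >= min_identity
                ):
                    cluster.append(jr)
                    break
            else:
                clusters.append([jr])
        for cluster in clusters:
            if len(cluster) < min_depth:
                continue
            cons = _majority_consensus([r.insert_seq for r in cluster], min_depth)
            if len(cons) < len(HINDIII):
                continue
            cons = _extend_with_mates(cons, [r.mate_seq for r in cluster])
            out.append(Consensus(pool=pool, end=end, seq=cons, support=len(cluster)))
    return out


def trim_to_bes(
    consensus: Consensus, vector: VectorModel, min_vector_anchor: int = 20
) -> ShortBes | None:
    """Remove any vector bases so the end sequence starts exactly at AAGCTT.

    Consensus sequences produced here are already junction-anchored, in
    which case this is the identity; a general consensus is searched (in
    both orientations) for a vector border followed by AAGCTT and
    truncated there.  Returns None when no junction is recognizable.
    """
    probes = {
        end: anchor + HINDIII
        for end, anchor in junction_anchors(vector, min_vector_anchor).items()
    }
    seq = consensus.seq
    if seq.startswith(HINDIII):
        return ShortBes(consensus.pool, consensus.end, seq, consensus.support)
    for oriented in (seq, revcomp(seq)):
        for end, probe in probes.items():
            p = oriented.find(probe)
            if p != -1:
                trimmed = oriented[p + min_vector_anchor :]
                if len(trimmed) >= len(HINDIII):
                    return ShortBes(consensus.pool, end, trimmed, consensus.support)
    return None
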