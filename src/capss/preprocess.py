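"""Read preprocessing: index demultiplexing, quality filtering, host screening.

Mirrors the accounting stages of a pooled-library run: raw reads per pool,
reads surviving quality control, and valid reads after removing pairs that
trace to the E. coli host genome.  Pairs are always kept or dropped whole;
downstream junction detection relies on intact mates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io import ReadPair
from .pool_design import PoolRef
from .seq import hamming, kmer_set, mean_quality, revcomp


@dataclass
class PoolReadSet:
    """Reads of one secondary pool plus the three accounting counts
    (raw >= after_qc >= valid)."""

    pool: PoolRef
    pairs: list[ReadPair] = field(default_factory=list)
    n_raw: int = 0
    n_after_qc: int = 0
    n_valid: int = 0


class IndexTableError(ValueError):
    pass


def _check_index_distances(barcodes: list[str], max_mismatch: int) -> None:
    if len(set(barcodes)) != len(barcodes):
        raise IndexTableError("index barcodes are not distinct")
    if max_mismatch <= 0:
        return
    need = 2 * max_mismatch
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if hamming(a, b) <= need:
                raise IndexTableError(
                    f"barcodes {a} and {b} are within {need} mismatches; "
                    f"demultiplexing at max_mismatch={max_mismatch} would be ambiguous"
                )


def demultiplex(
    reads: list[ReadPair],
    index_table: dict[PoolRef, str],
    max_mismatch: int = 0,
) -> tuple[dict[PoolRef, PoolReadSet], list[ReadPair]]:
    """Partition read pairs by the index barcode at the start of read 1.

    Each pair goes to the unique pool whose barcode matches within
    ``max_mismatch`` substitutions (the index table must keep barcodes
    more than ``2 * max_mismatch`` apart, so the match is unambiguous);
    everything else lands in the unassigned bin.  The barcode is stripped
    from the assigned read.  The partition is exhaustive and disjoint.
    """
    barcodes = list(index_table.values())
    _check_index_distances(barcodes, max_mismatch)
    bc_len = len(barcodes[0])
    if any(len(b) != bc_len for b in barcodes):
        raise IndexTableError("index barcodes must share one length")
    exact = {bc: pool for pool, bc in index_table.items()}
    out = {pool: PoolReadSet(pool=pool) for pool in index_table}
    unassigned: list[ReadPair] = []
    for rp in reads:
        bc = rp.seq1[:bc_len]
        pool = exact.get(bc)
        if pool is None and max_mismatch > 0 and len(bc) == bc_len:
            for cand_bc, cand_pool in exact.items():
                if hamming(bc, cand_bc) <= max_mismatch:
                    pool = cand_pool
                    break
        if pool is None:
            unassigned.append(rp)
            continue
        stripped = ReadPair(
            rp.id, rp.seq1[bc_len:], rp.qual1[bc_len:], rp.seq2, rp.qual2
        )
        prs = out[pool]
        prs.pairs.append(stripped)
    for prs in out.values():
        prs.n_raw = len(prs.pairs)
    return out, unassigned


def quality_trim(
    read_set: PoolReadSet, min_mean_q: float = 20.0, min_len: int = 100
) -> PoolReadSet:
    """Drop pairs where either mate is shorter than ``min_len`` or has mean
    Phred quality below ``min_mean_q``.  A minimal stand-in for the usual
    read-trimming tools: the contract downstream stages need is only that
    obviously bad pairs are gone."""
    kept = [
        rp
        for rp in read_set.pairs
        if len(rp.seq1) >= min_len
        and len(rp.seq2) >= min_len
        and mean_quality(rp.qual1) >= min_mean_q
        and mean_quality(rp.qual2) >= min_mean_q
    ]
    return PoolReadSet(
        pool=read_set.pool,
        pairs=kept,
        n_raw=read_set.n_raw,
        n_after_qc=len(kept),
        n_valid=read_set.n_valid,
    )


def build_host_index(host_genome: str | dict[str, str], k: int = 21) -> frozenset[str]:
    """Both-strand k-mer set of the host genome for the containment screen.

    Storing forward and reverse-complement k-mers lets read k-mers be
    looked up directly (equivalent to canonical-form containment, without
    canonicalizing millions of read k-mers).
    """
    if isinstance(host_genome, dict):
        seqs = host_genome.values()
    else:
        seqs = [host_genome]
    kmers: set[str] = set()
    for seq in seqs:
        for km in kmer_set(seq.upper(), k, canonical=False):
            kmers.add(km)
            kmers.add(revcomp(km))
    return frozenset(kmers)


def _is_host(seq: str, host: frozenset[str], k: int, hit_fraction: float) -> bool:
    """True when >= hit_fraction of the read's k-mers occur in the host set
    (either strand).  Short-circuits once the verdict is decided."""
    n = len(seq) - k + 1
    if n <= 0:
        return False
    need = max(math.ceil(hit_fraction * n), 1)
    hits = 0
    for i in range(n):
        if seq[i : i + k] in host:
            hits += 1
            if hits >= need:
                return True
        elif hits + (n - i - 1) < need:
            return False
    return hits >= need


def filter_host(
    pool_reads: PoolReadSet,
    host_genome: str | dict[str, str] | frozenset[str],
    k: int = 21,
    hit_fraction: float = 0.5,
) -> PoolReadSet:
    """Remove pairs that trace to the host genome.

    A mate is host-derived when at least ``hit_fraction`` of its canonical
    k-mers occur in the host k-mer set; a pair is removed if either mate
    is host.  A k-mer containment screen replaces full host alignment:
    what downstream needs is only that host pairs are gone, and exact
    21-mer containment separates host from insert reads sharply at any
    realistic error rate.  Idempotent.  Pass a prebuilt index from
    :func:`build_host_index` when screening many pools.
    """
    if not host_genome:
        raise ValueError("host genome must be non-empty")
    if not (15 <= k <= 31 and k % 2 == 1):
        raise ValueError("k must be odd and between 15 and 31")
    host = (
        host_genome
        if isinstance(host_genome, frozenset)
        else build_host_index(host_genome, k)
    )
    kept = [
        rp
        for rp in pool_reads.pairs
        if not _is_host(rp.seq1, host, k, hit_fraction)
        and not _is_host(rp.seq2, host, k, hit_fraction)
    ]
    return PoolReadSet(
        pool=pool_reads.pool,
        pairs=kept,
        n_raw=pool_reads.n_raw,
        n_after_qc=pool_reads.n_after_qc,
        n_valid=len(kept),
    )
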