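"""Independent brute-force oracles used to pin down expected values.

These deliberately share no code path with the package implementations
they check: the aligner oracle slides the query over every offset of
every strand, the n50 oracle walks prefixes of the sorted list, and the
coverage oracle paints a per-base bitmap.
"""

from __future__ import annotations

import numpy as np

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def sliding_hits(
    query: str, sequences: dict[str, str], min_identity: float = 0.99
) -> set[tuple[str, str, int, int]]:
    """Every (chrom, strand, t_start, matches) placing the full query with
    Hamming identity >= min_identity, by exhaustive sliding comparison."""
    out: set[tuple[str, str, int, int]] = set()
    qlen = len(query)
    for strand in ("+", "-"):
        q = query if strand == "+" else rc(query)
        q_arr = np.frombuffer(q.encode(), dtype=np.uint8)
        for chrom, seq in sequences.items():
            if len(seq) < qlen:
                continue
            g = np.frombuffer(seq.encode(), dtype=np.uint8)
            windows = np.lib.stride_tricks.sliding_window_view(g, qlen)
            match_counts = (windows == q_arr).sum(axis=1)
            for t_start in np.nonzero(match_counts >= min_identity * qlen)[0]:
                out.add((chrom, strand, int(t_start), int(match_counts[t_start])))
    return out


def n50_exhaustive(lengths: list[int]) -> int:
    """Direct transcription of the definition: the largest L among the
    lengths such that the sum of all lengths >= L reaches half the total."""
    total = sum(lengths)
    best = None
    for L in sorted(set(lengths), reverse=True):
        if sum(x for x in lengths if x >= L) * 2 >= total:
            best = L
            break
    assert best is not None
    return best


def union_length_bitmap(intervals: list[tuple[int, int]], length: int) -> int:
    """Per-base bitmap union length of 0-based half-open intervals."""
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return int(mask.sum())
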