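"""Small DNA utilities shared across the pipeline.

All sequences are plain Python strings over ``ACGTN`` (lowercase marks
masked bases where masking applies).  Heavier per-base work goes through
numpy byte arrays produced by :func:`seq_array`.
"""

from __future__ import annotations

import numpy as np

HINDIII = "AAGCTT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving case (masking survives orientation flips)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_array(seq: str) -> np.ndarray:
    """View a sequence as a uint8 array of ASCII codes (no copy of the string)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def matches(a: str, b: str) -> int:
    """Number of equal characters over the shorter of the two sequences."""
    n = min(len(a), len(b))
    if n == 0:
        return 0
    return int(np.count_nonzero(seq_array(a[:n]) == seq_array(b[:n])))


def anchored_identity(a: str, b: str) -> float:
    """Identity of two sequences compared from a common anchored start.

    The comparison runs over the length of the shorter sequence; an empty
    overlap has identity 0.
    """
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return matches(a, b) / n


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the given expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(_BASES, size=length, p=p)
    return draws.tobytes().decode("ascii")


def find_all(seq: str, motif: str) -> list[int]:
    """All (possibly overlapping) start positions of ``motif`` in ``seq``."""
    out: list[int] = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def canonical_kmer(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_set(seq: str, k: int, canonical: bool = True) -> set[str]:
    """Set of k-mers of ``seq`` (canonical by default); k-mers containing N are skipped."""
    out: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        out.add(canonical_kmer(km) if canonical else km)
    return out


def mean_quality(qual: str, offset: int = 33) -> float:
    """Mean Phred quality of a Sanger-encoded quality string."""
    if not qual:
        return 0.0
    return float(seq_array(qual).mean()) - offset


def hamming(a: str, b: str) -> int:
    """Hamming distance of two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
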