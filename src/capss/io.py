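"""Readers and writers for the plain-text formats the pipeline exchanges.

Every intermediate artifact is a standard format (FASTQ, FASTA, TSV, BED,
GFF3) so each stage can be inspected or replaced independently.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pool_design import Axis, PoolRef


class ReadPair(NamedTuple):
    """One paired-end read: id plus both mates' sequence and quality."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    pairs: list[ReadPair] = []
    with open(path1) as f1, open(path2) as f2:
        for (id1, s1, q1), (id2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            rid = id1.split()[0]
            if rid.endswith("/1"):
                rid = rid[:-2]
            pairs.append(ReadPair(rid, s1, q1, s2, q2))
    return pairs


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_index_table(index_table: dict[PoolRef, str], path: str | Path) -> None:
    """Pool -> 7-bp index barcode table (columns pool_axis, pool_index, barcode)."""
    rows = [
        {"pool_axis": pool.axis.value, "pool_index": pool.index, "barcode": bc}
        for pool, bc in index_table.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_index_table(path: str | Path) -> dict[PoolRef, str]:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
    return {
        PoolRef(Axis(row.pool_axis), int(row.pool_index)): row.barcode
        for row in df.itertuples()
    }


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    """0-based half-open intervals as 3-column BED."""
    with open(path, "w") as f:
        for chrom, start, end in intervals:
            f.write(f"{chrom}\t{start}\t{end}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as f:
        for line in f:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split()[:3]
            out.append((chrom, int(start), int(end)))
    return out
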