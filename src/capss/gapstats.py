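"""Gap detection and clone-coverage accounting on the reference genome.

A gap is a maximal run of N in the assembly.  A gap counts as covered
when a paired-placed clone interval strictly contains it: only clones
anchored by both ends bound the insert on both sides of the gap, which
is what makes them usable for gap filling.  Per-chromosome coverage is
the union of paired clone intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import Evidence, MappedClone
from .simulate import SyntheticGenome


@dataclass(frozen=True)
class GapInterval:
    chrom: str
    start: int
    end: int


@dataclass
class ChromCoverage:
    chrom: str
    length: int
    n_gaps: int
    n_clones: int
    covered_length: int
    n_gaps_covered: int


@dataclass
class CoverageReport:
    rows: list[ChromCoverage] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.rows)

    @property
    def total_covered(self) -> int:
        return sum(r.covered_length for r in self.rows)

    @property
    def total_clones(self) -> int:
        return sum(r.n_clones for r in self.rows)

    @property
    def total_gaps(self) -> int:
        return sum(r.n_gaps for r in self.rows)

    @property
    def total_gaps_covered(self) -> int:
        return sum(r.n_gaps_covered for r in self.rows)

    @property
    def coverage_fraction(self) -> float:
        return self.total_covered / self.total_length if self.total_length else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        total = {
            "chrom": "total",
            "length": self.total_length,
            "n_gaps": self.total_gaps,
            "n_clones": self.total_clones,
            "covered_length": self.total_covered,
            "n_gaps_covered": self.total_gaps_covered,
        }
        return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


@dataclass
class InsertStats:
    n: int
    mean: float
    sd: float
    hist_counts: list[int]
    hist_edges: list[float]


_N_RUN = re.compile(r"N+")


def find_gaps(genome: SyntheticGenome | dict[str, str], min_run: int = 1) -> list[GapInterval]:
    """Maximal N-runs of length >= min_run, per sequence, sorted."""
    seqs = genome.sequences if isinstance(genome, SyntheticGenome) else genome
    gaps: list[GapInterval] = []
    for chrom in sorted(seqs):
        for m in _N_RUN.finditer(seqs[chrom].upper()):
            if m.end() - m.start() >= min_run:
                gaps.append(GapInterval(chrom, m.start(), m.end()))
    return gaps


def _paired(clones: list[MappedClone]) -> list[MappedClone]:
    return [c for c in clones if c.evidence is Evidence.PAIRED]


def covered_gaps(paired_clones: list[MappedClone], gaps: list[GapInterval]) -> list[GapInterval]:
    """Gaps strictly contained in some paired clone interval
    (clone.start < gap.start and clone.end > gap.end)."""
    clones = _paired(paired_clones)
    by_chrom: dict[str, list[MappedClone]] = {}
    for c in clones:
        by_chrom.setdefault(c.chrom, []).append(c)
    out = []
    for gap in gaps:
        for c in by_chrom.get(gap.chrom, []):
            if c.start < gap.start and c.end > gap.end:
                out.append(gap)
                break
    return out


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for start, end in sorted(intervals):
        if last_end is None or start > last_end:
            total += end - start
            last_end = end
        elif end > last_end:
            total += end - last_end
            last_end = end
    return total


def chromosome_coverage(
    paired_clones: list[MappedClone],
    genome: SyntheticGenome | dict[str, str],
    gaps: list[GapInterval] | None = None,
) -> CoverageReport:
    """Per-chromosome clone counts, interval-union coverage and gap coverage."""
    seqs = genome.sequences if isinstance(genome, SyntheticGenome) else genome
    if gaps is None:
        gaps = find_gaps(seqs)
    clones = _paired(paired_clones)
    covered = set(
        (g.chrom, g.start, g.end) for g in covered_gaps(clones, gaps)
    )
    report = CoverageReport()
    for chrom in sorted(seqs):
        chrom_clones = [c for c in clones if c.chrom == chrom]
        chrom_gaps = [g for g in gaps if g.chrom == chrom]
        report.rows.append(
            ChromCoverage(
                chrom=chrom,
                length=len(seqs[chrom]),
                n_gaps=len(chrom_gaps),
                n_clones=len(chrom_clones),
                covered_length=_union_length([(c.start, c.end) for c in chrom_clones]),
                n_gaps_covered=sum(
                    (g.chrom, g.start, g.end) in covered for g in chrom_gaps
                ),
            )
        )
    return report


def insert_stats(paired_clones: list[MappedClone], n_bins: int = 20) -> InsertStats:
    """Mean, standard deviation and histogram of paired clone spans —
    the in-silico insert-size estimate."""
    spans = np.array([c.span for c in _paired(paired_clones)], dtype=float)
    if len(spans) == 0:
        raise ValueError("insert_stats needs at least one paired clone")
    counts, edges = np.histogram(spans, bins=n_bins)
    return InsertStats(
        n=len(spans),
        mean=float(spans.mean()),
        sd=float(spans.std(ddof=1)) if len(spans) > 1 else 0.0,
        hist_counts=counts.tolist(),
        hist_edges=edges.tolist(),
    )


def effective_clone_size_kb(insert_estimate_kb: float = 132.0, vector_kb: float = 7.0) -> float:
    """Effective sequenced molecule size per clone: insert estimate plus
    vector backbone — the divisor used for per-pool depth accounting."""
    return insert_estimate_kb + vector_kb
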